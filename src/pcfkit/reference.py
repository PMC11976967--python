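"""Published reference measurements for the two single-strain enrichments.

The cable bacteria studied here are *Electronema aureum* GS and *Electrothrix
communis* RB.  This module bakes in the published per-cross-section STEM-EDX
relative atomic percentages (with the per-row elemental ratios as printed),
the cross-sectional morphometry of the periplasmic conductive fibers (PCFs),
the per-fiber model areas used in the conductivity calculation, and the
natural-abundance reference for the three major nickel isotopes.

These numbers are *inputs* to the analyses (worked examples and acceptance
checks), not fitted constants.  Raw integrated Kα counts are included only
for round-trip testing of the sensitivity-factor machinery: the published
count columns are typographically ambiguous in places, so counts are never
used as numeric oracles — only percentages and ratios are.
"""

from __future__ import annotations

from .edx import RegionComposition
from .isotope import IsotopeReference
from .iv import StrainGeometry
from .morphometry import PCFShape

ELEMENT_PANEL = ("S", "Fe", "Ni")

#: Per-fiber cross-sectional areas assumed by the conductivity model, nm².
PER_FIBER_AREA_NM2 = {"GS": 850.0, "RB": 1100.0, "Rat": 850.0, "Hou": 850.0, "Hou1": 850.0}

#: Fixed PCF counts measured from cross-sections (strains without a count use
#: the diameter formula: count = 5 * pi * filament diameter in µm).
FIXED_PCF_COUNT = {"GS": 34, "RB": 15}

#: Filament diameters from cross-sectional TEM, nm (mean over n sections).
FILAMENT_DIAMETER_NM = {"GS": 1069.0, "RB": 613.0}


def strain_geometry(strain: str) -> StrainGeometry:
    """Geometry preset for a named strain (per-fiber area + optional fixed count)."""
    return StrainGeometry(
        strain_label=strain,
        per_fiber_area_nm2=PER_FIBER_AREA_NM2.get(strain, 850.0),
        fixed_pcf_count=FIXED_PCF_COUNT.get(strain),
    )


#: Measured single-PCF cross-section shapes: GS fibers are rounded, RB fibers
#: rectangular.  Dimensions in nm (means over the measured fiber populations).
PCF_SHAPES = {
    "GS": PCFShape(strain_label="GS", shape_kind="circular", diameter_nm=30.89),
    "RB": PCFShape(strain_label="RB", shape_kind="rectangular", height_nm=25.95, width_nm=43.01),
}

#: Natural abundances (percent) of the three most abundant nickel isotopes.
NI_ISOTOPE_REFERENCE = IsotopeReference(
    element="Ni",
    abundances={"58Ni": 68.08, "60Ni": 26.22, "62Ni": 3.64},
)

#: Published IMAV / CV vesicle statistics (diameters in nm).
VESICLE_REFERENCE = {
    "GS": {"imav_mean": 65.5, "imav_std": 4.6, "imav_n": 90, "cv_mean": 68.9, "cv_std": 4.6, "cv_n": 48},
    "RB": {"imav_mean": 57.6, "imav_std": 4.8, "imav_n": 69, "cv_n": 0},
}

# Published per-cross-section EDX quantification of PCF regions.  Percents are
# relative atomic percentages over the S/Fe/Ni panel; ratios are the printed
# per-row values (computed by the original authors from unrounded percents, so
# they can differ in the last digit from ratios of the rounded percents).
# GS cross-section 4 is flagged as an outlier and excluded from averages.
EDX_REFERENCE_REGIONS = [
    RegionComposition(
        section_id="GS-1", strain_label="GS",
        percents={"S": 13.0, "Fe": 86.3, "Ni": 0.7},
        ratios={("S", "Fe"): 0.15, ("S", "Ni"): 18.81, ("Fe", "Ni"): 125.12},
    ),
    RegionComposition(
        section_id="GS-2", strain_label="GS",
        percents={"S": 31.4, "Fe": 64.9, "Ni": 3.8},
        ratios={("S", "Fe"): 0.48, ("S", "Ni"): 8.35, ("Fe", "Ni"): 17.25},
    ),
    RegionComposition(
        section_id="GS-3", strain_label="GS",
        percents={"S": 30.3, "Fe": 66.8, "Ni": 2.9},
        ratios={("S", "Fe"): 0.45, ("S", "Ni"): 10.50, ("Fe", "Ni"): 23.10},
    ),
    RegionComposition(
        section_id="GS-4", strain_label="GS", outlier=True,
        percents={"S": 71.4, "Fe": 19.6, "Ni": 9.0},
        ratios={("S", "Fe"): 3.64, ("S", "Ni"): 7.90, ("Fe", "Ni"): 2.17},
    ),
    RegionComposition(
        section_id="RB-1", strain_label="RB",
        percents={"S": 77.2, "Fe": 9.8, "Ni": 13.0},
        ratios={("S", "Fe"): 7.89, ("S", "Ni"): 5.95, ("Fe", "Ni"): 0.75},
    ),
    RegionComposition(
        section_id="RB-2", strain_label="RB",
        percents={"S": 76.3, "Fe": 12.2, "Ni": 11.5},
        ratios={("S", "Fe"): 6.26, ("S", "Ni"): 6.62, ("Fe", "Ni"): 1.06},
    ),
    RegionComposition(
        section_id="RB-3", strain_label="RB",
        percents={"S": 82.4, "Fe": 10.9, "Ni": 6.8},
        ratios={("S", "Fe"): 7.59, ("S", "Ni"): 12.21, ("Fe", "Ni"): 1.61},
    ),
]

#: Integrated Kα counts for one region (the GS-1 cross-section reading used by
#: the sensitivity-factor worked example).  Used only for round-trip tests.
EDX_REFERENCE_COUNTS_GS1 = {"S": 1651, "Fe": 5302, "Ni": 40}
EDX_REFERENCE_COUNTS_RB1 = {"S": 1161, "Fe": 1802, "Ni": 2770}


def edx_regions(strain: str) -> list[RegionComposition]:
    """The reference EDX regions for one strain, in publication order."""
    return [r for r in EDX_REFERENCE_REGIONS if r.strain_label == strain]
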