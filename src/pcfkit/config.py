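"""Run configuration with every published constant baked in as a default.

A YAML file can override any subset; overrides are echoed into run summaries
for provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigError
from .heme import DEFAULT_SPHC_MAX_LENGTH, MotifSpec, ScoringScheme
from .isotope import IsotopeReference
from .iv import AnalysisConfig, StrainGeometry
from . import reference

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    strains: dict[str, StrainGeometry] = field(
        default_factory=lambda: {s: reference.strain_geometry(s) for s in reference.PER_FIBER_AREA_NM2}
    )
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    element_panel: tuple[str, ...] = reference.ELEMENT_PANEL
    ratio_pairs: tuple[tuple[str, str], ...] = (("S", "Fe"), ("S", "Ni"), ("Fe", "Ni"))
    isotope_reference: IsotopeReference = field(default_factory=lambda: reference.NI_ISOTOPE_REFERENCE)
    motif: MotifSpec = field(default_factory=MotifSpec)
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    min_rbh_score: float = 50.0
    sphc_max_length: int = DEFAULT_SPHC_MAX_LENGTH
    overrides: dict = field(default_factory=dict)

    def geometry(self, strain: str) -> StrainGeometry:
        if strain not in self.strains:
            raise ConfigError(f"strain {strain!r} not defined in configuration")
        return self.strains[strain]


def load_config(path: Optional[str | Path] = None) -> RunConfig:
    """Defaults, optionally overridden by a YAML mapping.

    Recognized top-level keys: ``strains`` (per-strain ``per_fiber_area_nm2``,
    ``fixed_pcf_count``, ``pcf_density_constant``), ``eval_voltage_v``,
    ``lod_conductance_a_per_v``, ``element_panel``, ``ratio_pairs``,
    ``isotope_abundances``, ``motif_n_internal``, ``motif_overlap_policy``,
    ``matrix_name``, ``gap_open``, ``gap_extend``, ``min_rbh_score``,
    ``sphc_max_length``.
    """
    cfg = RunConfig()
    if path is None:
        return cfg
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    cfg.overrides = data

    for strain, spec in (data.get("strains") or {}).items():
        base = cfg.strains.get(strain)
        kwargs = {
            "strain_label": strain,
            "per_fiber_area_nm2": spec.get(
                "per_fiber_area_nm2", base.per_fiber_area_nm2 if base else 850.0
            ),
            "fixed_pcf_count": spec.get(
                "fixed_pcf_count", base.fixed_pcf_count if base else None
            ),
            "pcf_density_constant": spec.get(
                "pcf_density_constant", base.pcf_density_constant if base else 5.0
            ),
        }
        cfg.strains[strain] = StrainGeometry(**kwargs)

    analysis_kwargs = {}
    if "eval_voltage_v" in data:
        analysis_kwargs["eval_voltage_v"] = float(data["eval_voltage_v"])
    if "lod_conductance_a_per_v" in data:
        analysis_kwargs["lod_conductance_a_per_v"] = float(data["lod_conductance_a_per_v"])
    if analysis_kwargs:
        cfg.analysis = dataclasses.replace(cfg.analysis, **analysis_kwargs)

    if "element_panel" in data:
        cfg.element_panel = tuple(data["element_panel"])
    if "ratio_pairs" in data:
        cfg.ratio_pairs = tuple((a, b) for a, b in data["ratio_pairs"])
    if "isotope_abundances" in data:
        cfg.isotope_reference = IsotopeReference(
            element=data.get("isotope_element", cfg.isotope_reference.element),
            abundances={str(k): float(v) for k, v in data["isotope_abundances"].items()},
        )

    motif_kwargs = {}
    if "motif_n_internal" in data:
        motif_kwargs["n_internal"] = int(data["motif_n_internal"])
    if "motif_overlap_policy" in data:
        motif_kwargs["overlap_policy"] = data["motif_overlap_policy"]
    if motif_kwargs:
        cfg.motif = dataclasses.replace(cfg.motif, **motif_kwargs)

    scoring_kwargs = {
        k: data[k] for k in ("matrix_name", "gap_open", "gap_extend") if k in data
    }
    if scoring_kwargs:
        cfg.scoring = dataclasses.replace(cfg.scoring, **scoring_kwargs)
    if "min_rbh_score" in data:
        cfg.min_rbh_score = float(data["min_rbh_score"])
    if "sphc_max_length" in data:
        cfg.sphc_max_length = int(data["sphc_max_length"])
    return cfg
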