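"""Single-filament two-probe conductivity from linear I/V sweeps.

A cable-bacterium filament is bridged between two carbon-paste electrodes and
swept from -1 to +1 V while the current is monitored.  The sweep is fitted by
ordinary least squares; the conductance (slope) is converted to the electrical
conductivity of a single periplasmic conductive fiber (PCF) through

    sigma = (I * l) / (V * A)

where I is the fitted current at the evaluation voltage V (100 mV by default),
l the electrode gap, and A the combined cross-sectional area of all PCFs in
the filament.  A is obtained from a per-strain geometry model: a fixed PCF
count where one was measured from cross-sections, otherwise the empirical
density relation  count = 5 * pi * filament diameter (µm),  times a per-fiber
area (850 nm² for most strains, 1100 nm² for RB).

Filaments whose conductance falls below the instrument detection limit
(1 pA/V) are censored: they are counted but excluded from cohort means and
box statistics, mirroring how such measurements are reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "IVSweep",
    "OhmicFit",
    "StrainGeometry",
    "AnalysisConfig",
    "ConductivityResult",
    "CohortSummary",
    "fit_iv",
    "classify_lod",
    "pcf_count_from_diameter",
    "total_pcf_area",
    "conductivity",
    "summarize_cohort",
]

#: nm² -> m²
_NM2_TO_M2 = 1e-18
#: µm -> m
_UM_TO_M = 1e-6
#: S/m -> S/cm
_S_PER_M_TO_S_PER_CM = 1e-2

ATMOSPHERES = ("vacuum", "N2", "air")


@dataclass
class IVSweep:
    """One filament's voltage/current scan.

    Voltages in volts, currents in amperes, electrode gap in micrometers.
    """

    sample_id: str
    strain_label: str
    voltages: np.ndarray
    currents: np.ndarray
    gap_length_um: float
    atmosphere: str = "vacuum"

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.voltages.shape != self.currents.shape:
            raise InvalidInputError(
                f"sweep {self.sample_id!r}: voltages ({self.voltages.size}) and "
                f"currents ({self.currents.size}) differ in length"
            )
        if self.voltages.size < 3:
            raise InvalidInputError(
                f"sweep {self.sample_id!r}: need at least 3 points, got {self.voltages.size}"
            )
        if not self.gap_length_um > 0:
            raise InvalidInputError(
                f"sweep {self.sample_id!r}: gap length must be positive, got {self.gap_length_um}"
            )
        if self.atmosphere not in ATMOSPHERES:
            raise InvalidInputError(
                f"sweep {self.sample_id!r}: unknown atmosphere {self.atmosphere!r}"
            )
        if self.voltages.min() >= 0 or self.voltages.max() <= 0:
            warnings.warn(
                f"sweep {self.sample_id!r}: voltages do not span both signs; "
                "not a full -1..1 V scan",
                stacklevel=2,
            )


@dataclass(frozen=True)
class OhmicFit:
    """Least-squares line through an I/V sweep: I = slope * V + intercept."""

    slope: float  # A/V (conductance)
    intercept: float  # A
    r_squared: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise InvalidInputError(f"r_squared out of [0, 1]: {self.r_squared}")


@dataclass(frozen=True)
class StrainGeometry:
    """Per-strain PCF geometry used to build the conduction cross-section.

    ``fixed_pcf_count`` (measured from cross-sections) takes precedence; the
    diameter-density formula is used only when no count is given.
    """

    strain_label: str
    per_fiber_area_nm2: float
    fixed_pcf_count: Optional[int] = None
    pcf_density_constant: float = 5.0  # fibers per (pi * µm of filament diameter)

    def __post_init__(self) -> None:
        if not self.per_fiber_area_nm2 > 0:
            raise InvalidInputError("per-fiber area must be positive")
        if self.fixed_pcf_count is not None and self.fixed_pcf_count <= 0:
            raise InvalidInputError("fixed PCF count must be positive when present")


@dataclass(frozen=True)
class AnalysisConfig:
    """Evaluation voltage and detection limit for the conductivity pipeline."""

    eval_voltage_v: float = 0.1
    lod_conductance_a_per_v: float = 1e-12  # 1 pA/V

    def __post_init__(self) -> None:
        if not self.eval_voltage_v > 0:
            raise InvalidInputError("eval voltage must be positive")
        if not self.lod_conductance_a_per_v > 0:
            raise InvalidInputError("LOD conductance must be positive")


@dataclass(frozen=True)
class ConductivityResult:
    sample_id: str
    conductance_a_per_v: float
    current_at_eval_a: float
    sigma_s_per_cm: Optional[float]  # None when censored
    below_lod: bool


@dataclass(frozen=True)
class CohortSummary:
    """Cohort statistics over non-censored conductivities (Tukey box convention)."""

    n_total: int
    n_below_lod: int
    mean: Optional[float]
    std: Optional[float]  # sample std (n-1)
    median: Optional[float]
    q1: Optional[float]
    q3: Optional[float]
    whisker_low: Optional[float]
    whisker_high: Optional[float]
    outliers: tuple[float, ...] = field(default_factory=tuple)


def fit_iv(sweep: IVSweep) -> OhmicFit:
    """Ordinary least-squares line through (V, I).

    Raises :class:`InvalidInputError` on a degenerate sweep (constant voltage).
    A perfectly flat current trace fits exactly, so its r² is 1.
    """
    v, i = sweep.voltages, sweep.currents
    if np.ptp(v) == 0:
        raise InvalidInputError(
            f"sweep {sweep.sample_id!r}: all voltages equal; cannot fit a line"
        )
    slope, intercept = np.polyfit(v, i, 1)
    resid = i - (slope * v + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((i - i.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0  # exact fit of a constant trace
    else:
        r2 = max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return OhmicFit(slope=float(slope), intercept=float(intercept), r_squared=r2)


def classify_lod(fit: OhmicFit, cfg: AnalysisConfig = AnalysisConfig()) -> bool:
    """True iff the conductance magnitude is strictly below the detection limit.

    A slope exactly at the limit counts as detectable.
    """
    return abs(fit.slope) < cfg.lod_conductance_a_per_v


def pcf_count_from_diameter(diameter_um: float, geometry: StrainGeometry) -> int:
    """PCF count from filament diameter: round(c * pi * d), half away from zero.

    The empirical density relation (default c = 5 fibers per pi·µm) is used
    for strains without a measured per-cross-section count.
    """
    if diameter_um < 0:
        raise InvalidInputError(f"diameter must be non-negative, got {diameter_um}")
    x = geometry.pcf_density_constant * math.pi * diameter_um
    return int(math.floor(x + 0.5))  # x >= 0, so this is half-away-from-zero


def total_pcf_area(pcf_count: int, geometry: StrainGeometry) -> float:
    """Combined PCF cross-sectional area in nm² (count x per-fiber area)."""
    if pcf_count < 1:
        raise InvalidInputError("PCF count must be >= 1: no conductive path")
    return pcf_count * geometry.per_fiber_area_nm2


def resolve_area_nm2(geometry: StrainGeometry, filament_diameter_um: Optional[float] = None) -> float:
    """Total PCF area for a filament: fixed count wins, else the diameter formula."""
    if geometry.fixed_pcf_count is not None:
        count = geometry.fixed_pcf_count
    else:
        if filament_diameter_um is None:
            raise InvalidInputError(
                f"strain {geometry.strain_label!r} has no fixed PCF count; "
                "a filament diameter is required"
            )
        count = pcf_count_from_diameter(filament_diameter_um, geometry)
    return total_pcf_area(count, geometry)


def conductivity(
    fit: OhmicFit,
    sweep: IVSweep,
    area_nm2: float,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> ConductivityResult:
    """Single-PCF conductivity sigma = (I*l)/(V*A) in S/cm.

    I is the fitted line evaluated at the evaluation voltage with the
    intercept removed, i.e. slope * V_eval, so sigma reduces to
    slope * l / A converted to S/cm.  Censored (below-LOD) sweeps get
    ``sigma_s_per_cm=None``.
    """
    if not area_nm2 > 0:
        raise InvalidInputError(f"area must be positive, got {area_nm2}")
    if not sweep.gap_length_um > 0:
        raise InvalidInputError(f"gap length must be positive, got {sweep.gap_length_um}")
    below = classify_lod(fit, cfg)
    current = fit.slope * cfg.eval_voltage_v
    if below:
        sigma = None
    else:
        sigma_s_per_m = (current * sweep.gap_length_um * _UM_TO_M) / (
            cfg.eval_voltage_v * area_nm2 * _NM2_TO_M2
        )
        sigma = sigma_s_per_m * _S_PER_M_TO_S_PER_CM
    return ConductivityResult(
        sample_id=sweep.sample_id,
        conductance_a_per_v=fit.slope,
        current_at_eval_a=current,
        sigma_s_per_cm=sigma,
        below_lod=below,
    )


def _tukey_box(values: np.ndarray) -> tuple[float, float, float, float, float, tuple[float, ...]]:
    q1, med, q3 = (float(q) for q in np.percentile(values, [25, 50, 75]))
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    outliers = tuple(float(x) for x in np.sort(values[(values < lo_fence) | (values > hi_fence)]))
    return med, q1, q3, float(inside.min()), float(inside.max()), outliers


def summarize_cohort(results: Sequence[ConductivityResult]) -> CohortSummary:
    """Cohort mean/std and Tukey box statistics over non-censored results.

    Censored measurements are excluded from every statistic but counted in
    ``n_below_lod`` and ``n_total``.  An all-censored cohort yields counts
    only, with the statistics absent.
    """
    if not results:
        raise InvalidInputError("empty cohort")
    n_below = sum(r.below_lod for r in results)
    sigmas = np.array([r.sigma_s_per_cm for r in results if not r.below_lod], dtype=float)
    n_total = len(results)
    if sigmas.size == 0:
        return CohortSummary(n_total=n_total, n_below_lod=n_below, mean=None, std=None,
                             median=None, q1=None, q3=None,
                             whisker_low=None, whisker_high=None)
    mean = float(sigmas.mean())
    std = float(sigmas.std(ddof=1)) if sigmas.size > 1 else None
    med, q1, q3, wlo, whi, outliers = _tukey_box(sigmas)
    return CohortSummary(
        n_total=n_total, n_below_lod=n_below, mean=mean, std=std,
        median=med, q1=q1, q3=q3, whisker_low=wlo, whisker_high=whi,
        outliers=outliers,
    )
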