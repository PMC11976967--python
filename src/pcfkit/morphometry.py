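"""PCF and vesicle morphometry from cross-sectional electron microscopy.

Single-fiber cross-sectional areas are computed under a per-strain shape
model assigned from configuration, never inferred from data: GS fibers are
rounded (area pi*(D/2)^2 from the diameter), RB fibers rectangular (area
H*W).  Strain comparisons are reported as percent differences, optionally
rounded to a coarse step (default 10%) because the underlying dimension
averages do not support finer statements; the unrounded value is always
available alongside.

Vesicle observations (inner membrane-attached vesicles, IMAVs, vs free
cytoplasmic vesicles, CVs) are summarized as the IMAV fraction plus
per-class diameter mean and sample standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "PCFShape",
    "FilamentMorphometry",
    "VesicleObservation",
    "VesicleSummary",
    "pcf_area",
    "compare_single_pcf_area",
    "compare_total_pcf_area",
    "summarize_vesicles",
]

VESICLE_CLASSES = ("IMAV", "CV")


@dataclass(frozen=True)
class PCFShape:
    """Single-fiber cross-section: circular (diameter) or rectangular (H x W), nm."""

    strain_label: str
    shape_kind: str  # "circular" | "rectangular"
    diameter_nm: Optional[float] = None
    height_nm: Optional[float] = None
    width_nm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.shape_kind == "circular":
            if self.diameter_nm is None or self.height_nm is not None or self.width_nm is not None:
                raise InvalidInputError("circular shape requires exactly a diameter")
            if not self.diameter_nm > 0:
                raise InvalidInputError("diameter must be positive")
        elif self.shape_kind == "rectangular":
            if self.height_nm is None or self.width_nm is None or self.diameter_nm is not None:
                raise InvalidInputError("rectangular shape requires exactly height and width")
            if not (self.height_nm > 0 and self.width_nm > 0):
                raise InvalidInputError("height and width must be positive")
        else:
            raise InvalidInputError(f"unknown shape kind {self.shape_kind!r}")


@dataclass(frozen=True)
class FilamentMorphometry:
    strain_label: str
    filament_diameter_nm: float
    pcf_count: int

    def __post_init__(self) -> None:
        if not self.filament_diameter_nm > 0:
            raise InvalidInputError("filament diameter must be positive")
        if self.pcf_count < 0:
            raise InvalidInputError("PCF count must be non-negative")


@dataclass(frozen=True)
class VesicleObservation:
    diameter_nm: float
    attachment: str  # "IMAV" | "CV"

    def __post_init__(self) -> None:
        if not self.diameter_nm > 0:
            raise InvalidInputError("vesicle diameter must be positive")
        if self.attachment not in VESICLE_CLASSES:
            raise InvalidInputError(f"unknown vesicle class {self.attachment!r}")


@dataclass(frozen=True)
class VesicleSummary:
    n_total: int
    n_imav: int
    n_cv: int
    imav_fraction: float
    imav_diameter_mean: Optional[float]
    imav_diameter_std: Optional[float]
    cv_diameter_mean: Optional[float]
    cv_diameter_std: Optional[float]


def pcf_area(shape: PCFShape) -> float:
    """Single-fiber cross-sectional area in nm² under the shape model."""
    if shape.shape_kind == "circular":
        return math.pi * (shape.diameter_nm / 2.0) ** 2
    return shape.height_nm * shape.width_nm


def _percent_difference(ref: float, other: float, rounding_step: Optional[float]) -> tuple[float, float]:
    if ref == 0:
        raise InvalidInputError("reference area is zero; percent difference undefined")
    raw = 100.0 * (other - ref) / ref
    if rounding_step:
        rounded = rounding_step * round(raw / rounding_step)
    else:
        rounded = raw
    return raw, rounded


def compare_single_pcf_area(
    a: PCFShape, b: PCFShape, rounding_step: Optional[float] = 10.0
) -> tuple[float, float]:
    """Percent difference of b's single-fiber area relative to a's.

    Returns ``(unrounded, rounded)``; the rounding step (default 10%)
    matches the coarseness of strain-level claims like "around 50% bigger".
    """
    return _percent_difference(pcf_area(a), pcf_area(b), rounding_step)


def compare_total_pcf_area(
    a: FilamentMorphometry,
    per_fiber_area_a_nm2: float,
    b: FilamentMorphometry,
    per_fiber_area_b_nm2: float,
    rounding_step: Optional[float] = 10.0,
) -> tuple[float, float]:
    """Percent difference of combined PCF areas (count x per-fiber area).

    The per-fiber areas may come from the measured shape models or the
    conduction-model presets (850/1100 nm²); callers should state which.
    """
    if a.pcf_count < 1 or b.pcf_count < 1:
        raise InvalidInputError("PCF counts must be >= 1 for a total-area comparison")
    total_a = a.pcf_count * per_fiber_area_a_nm2
    total_b = b.pcf_count * per_fiber_area_b_nm2
    return _percent_difference(total_a, total_b, rounding_step)


def summarize_vesicles(obs: Sequence[VesicleObservation]) -> VesicleSummary:
    """IMAV fraction and per-class diameter mean +/- sample std."""
    if not obs:
        raise InvalidInputError("no vesicle observations")
    imav = np.array([o.diameter_nm for o in obs if o.attachment == "IMAV"])
    cv = np.array([o.diameter_nm for o in obs if o.attachment == "CV"])

    def _stats(d: np.ndarray) -> tuple[Optional[float], Optional[float]]:
        if d.size == 0:
            return None, None
        return float(d.mean()), (float(d.std(ddof=1)) if d.size > 1 else None)

    imav_mean, imav_std = _stats(imav)
    cv_mean, cv_std = _stats(cv)
    n = len(obs)
    return VesicleSummary(
        n_total=n,
        n_imav=int(imav.size),
        n_cv=int(cv.size),
        imav_fraction=imav.size / n,
        imav_diameter_mean=imav_mean,
        imav_diameter_std=imav_std,
        cv_diameter_mean=cv_mean,
        cv_diameter_std=cv_std,
    )
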