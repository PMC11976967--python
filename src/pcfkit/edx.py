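"""STEM-EDX relative elemental quantification of PCF regions.

Each analyzed region yields integrated Kα counts per element (here the S/Fe/Ni
panel).  Counts are converted to relative atomic percentages with a single
multiplicative sensitivity factor per element (Cliff–Lorimer-style relative
quantification):

    percent_i = 100 * counts_i * f_i / sum_j counts_j * f_j

Only ratios of the factors matter, so factor sets are equivalent up to a
global rescale.  Factors are acquisition-dependent (beam current, dwell time,
map size all move the raw counts), so they are supplied or fitted per region
or per batch — there are no global defaults.

Elemental ratios (S:Fe, S:Ni, Fe:Ni) are ratios of the atomic percentages.
Cohort summaries average over regions not flagged as outliers; the default
ratio averaging is the mean of per-row ratios, matching how the published
averages were formed (the alternative — ratio of mean percents — is available
as ``ratio_mode="from_percents"``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import ConfigError, InvalidInputError

__all__ = [
    "EDXRegionCounts",
    "SensitivityFactors",
    "Composition",
    "RatioTable",
    "RegionComposition",
    "CompositionSummary",
    "relative_atomic_percent",
    "fit_sensitivity_factors",
    "elemental_ratios",
    "summarize_compositions",
]

Pair = tuple[str, str]

DEFAULT_RATIO_PAIRS: tuple[Pair, ...] = (("S", "Fe"), ("S", "Ni"), ("Fe", "Ni"))


@dataclass
class EDXRegionCounts:
    """Integrated Kα counts per element for one analyzed region."""

    section_id: str
    strain_label: str
    counts: dict[str, float]
    outlier_flag: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if len(self.counts) < 2:
            raise InvalidInputError(
                f"region {self.section_id!r}: need counts for at least 2 elements"
            )
        for el, c in self.counts.items():
            if c < 0:
                raise InvalidInputError(
                    f"region {self.section_id!r}: negative count for {el}"
                )


@dataclass(frozen=True)
class SensitivityFactors:
    """Per-element multiplicative factors; only their ratios are meaningful."""

    factors: Mapping[str, float]
    convention: str = "first element normalized to 1"

    def __post_init__(self) -> None:
        for el, f in self.factors.items():
            if not f > 0:
                raise InvalidInputError(f"sensitivity factor for {el} must be positive")


@dataclass(frozen=True)
class Composition:
    """Relative atomic percentages; sums to 100 up to rounding of the inputs."""

    percents: Mapping[str, float]

    def __post_init__(self) -> None:
        for el, p in self.percents.items():
            if p < 0:
                raise InvalidInputError(f"negative percent for {el}")
        total = sum(self.percents.values())
        if abs(total - 100.0) > 0.2:
            raise InvalidInputError(f"percents sum to {total:.3f}, expected 100 +/- 0.2")

    def rounded(self, ndigits: int = 1) -> dict[str, float]:
        return {el: round(p, ndigits) for el, p in self.percents.items()}


@dataclass(frozen=True)
class RatioTable:
    """Ordered element-pair ratios; an undefined ratio (zero denominator) is None."""

    ratios: Mapping[Pair, Optional[float]]

    def rounded(self, ndigits: int = 2) -> dict[Pair, Optional[float]]:
        return {p: (None if r is None else round(r, ndigits)) for p, r in self.ratios.items()}


@dataclass
class RegionComposition:
    """One region's quantification: percents plus (optionally) its as-printed
    per-row ratios.  Supplied ratios take precedence over ratios recomputed
    from the (possibly rounded) percents."""

    section_id: str
    strain_label: str
    percents: dict[str, float]
    ratios: Optional[dict[Pair, float]] = None
    outlier: bool = False


@dataclass(frozen=True)
class CompositionSummary:
    element_mean: dict[str, float]
    element_std: dict[str, Optional[float]]
    ratio_mean: dict[Pair, float]
    ratio_std: dict[Pair, Optional[float]]
    included_ids: tuple[str, ...]
    excluded_ids: tuple[str, ...]


def relative_atomic_percent(
    region: EDXRegionCounts, f: SensitivityFactors
) -> Composition:
    """Counts -> relative atomic percent via per-element sensitivity factors."""
    missing = [el for el in region.counts if el not in f.factors]
    if missing:
        raise ConfigError(
            f"region {region.section_id!r}: no sensitivity factor for {', '.join(missing)}"
        )
    weighted = {el: c * f.factors[el] for el, c in region.counts.items()}
    total = sum(weighted.values())
    if total == 0:
        raise InvalidInputError(f"region {region.section_id!r}: all counts are zero")
    return Composition(percents={el: 100.0 * w / total for el, w in weighted.items()})


def fit_sensitivity_factors(
    region: EDXRegionCounts, known: Composition
) -> SensitivityFactors:
    """Invert the quantification: factors f_i proportional to percent_i / counts_i.

    Normalized so the first element (in the region's count order) has factor 1.
    ``relative_atomic_percent`` with the fitted factors reproduces ``known``
    exactly up to floating arithmetic.
    """
    raw: dict[str, float] = {}
    for el, c in region.counts.items():
        p = known.percents.get(el, 0.0)
        if c == 0:
            if p > 0:
                raise InvalidInputError(
                    f"region {region.section_id!r}: zero count for {el} with "
                    f"nonzero percent {p}; factors are unsolvable"
                )
            raw[el] = 0.0  # element absent; factor irrelevant, kept positive below
        else:
            raw[el] = p / c
    first = next(iter(raw))
    scale = raw[first]
    if scale == 0:
        raise InvalidInputError(
            f"region {region.section_id!r}: first element {first!r} has zero percent; "
            "cannot normalize factors"
        )
    factors = {el: (v / scale if v > 0 else 1.0) for el, v in raw.items()}
    return SensitivityFactors(factors=factors)


def elemental_ratios(
    comp: Composition, pairs: Sequence[Pair] = DEFAULT_RATIO_PAIRS
) -> RatioTable:
    """Ratios of atomic percents for ordered element pairs.

    A zero denominator yields ``None`` (undefined), not an exception.
    """
    ratios: dict[Pair, Optional[float]] = {}
    for num, den in pairs:
        if num not in comp.percents or den not in comp.percents:
            raise InvalidInputError(f"ratio {num}:{den}: element missing from composition")
        d = comp.percents[den]
        ratios[(num, den)] = None if d == 0 else comp.percents[num] / d
    return RatioTable(ratios=ratios)


def _mean_std(values: Sequence[float]) -> tuple[float, Optional[float]]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    std = float(arr.std(ddof=1)) if arr.size > 1 else None
    return mean, std


def summarize_compositions(
    regions: Sequence[RegionComposition],
    ratio_mode: str = "from_row_ratios",
    pairs: Sequence[Pair] = DEFAULT_RATIO_PAIRS,
) -> CompositionSummary:
    """Outlier-excluded means and sample stds of percents and ratios.

    ``ratio_mode="from_row_ratios"`` averages per-row ratios (a region's
    supplied as-printed ratios win over recomputation from its percents);
    ``"from_percents"`` takes ratios of the mean percents instead.
    """
    if ratio_mode not in ("from_row_ratios", "from_percents"):
        raise ConfigError(f"unknown ratio_mode {ratio_mode!r}")
    included = [r for r in regions if not r.outlier]
    excluded = [r for r in regions if r.outlier]
    if not included:
        raise InvalidInputError("all regions excluded as outliers; nothing to summarize")

    elements = list(included[0].percents)
    element_mean: dict[str, float] = {}
    element_std: dict[str, Optional[float]] = {}
    for el in elements:
        element_mean[el], element_std[el] = _mean_std([r.percents[el] for r in included])

    ratio_mean: dict[Pair, float] = {}
    ratio_std: dict[Pair, Optional[float]] = {}
    if ratio_mode == "from_row_ratios":
        for pair in pairs:
            vals = []
            for r in included:
                if r.ratios is not None and pair in r.ratios:
                    vals.append(r.ratios[pair])
                else:
                    table = elemental_ratios(Composition(percents=r.percents), [pair])
                    v = table.ratios[pair]
                    if v is None:
                        raise InvalidInputError(
                            f"region {r.section_id!r}: ratio {pair[0]}:{pair[1]} undefined"
                        )
                    vals.append(v)
            ratio_mean[pair], ratio_std[pair] = _mean_std(vals)
    else:
        mean_comp = {el: element_mean[el] for el in elements}
        for num, den in pairs:
            d = mean_comp[den]
            if d == 0:
                raise InvalidInputError(f"mean percent of {den} is zero; ratio undefined")
            ratio_mean[(num, den)] = mean_comp[num] / d
            ratio_std[(num, den)] = None

    return CompositionSummary(
        element_mean=element_mean,
        element_std=element_std,
        ratio_mean=ratio_mean,
        ratio_std=ratio_std,
        included_ids=tuple(r.section_id for r in included),
        excluded_ids=tuple(r.section_id for r in excluded),
    )
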