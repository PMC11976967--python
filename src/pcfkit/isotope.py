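"""ToF-SIMS isotope-pattern verification of an elemental assignment.

A peak assignment (here nickel) is checked by comparing the relative counts
of its isotopes to their natural abundances.  The relative count of an
isotope is its absolute count divided by the summed counts of a fixed,
explicitly ordered isotope subset — by default the three most abundant nickel
isotopes 58Ni (68.08%), 60Ni (26.22%) and 62Ni (3.64%).  The subset is
explicit rather than "everything present" because ToF-SIMS spectra contain
interfering peaks.

The headline output is the observed-vs-expected fraction table; a Pearson
chi-square goodness-of-fit statistic is provided alongside, without any
default p-value thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence
import warnings

import numpy as np
from scipy import stats

from .errors import InvalidInputError

__all__ = [
    "IsotopePattern",
    "IsotopeReference",
    "GofResult",
    "relative_isotope_counts",
    "expected_fractions",
    "isotope_gof",
]


@dataclass
class IsotopePattern:
    """Observed isotope counts for one sample."""

    counts: dict[str, float]
    sample_id: str = ""

    def __post_init__(self) -> None:
        if len(self.counts) < 2:
            raise InvalidInputError("need counts for at least 2 isotopes")
        for iso, c in self.counts.items():
            if c < 0:
                raise InvalidInputError(f"negative count for {iso}")


@dataclass(frozen=True)
class IsotopeReference:
    """Natural abundances (percent) for an element's isotopes.

    The listed subset need not sum to 100 (58+60+62 Ni cover 97.94%).
    """

    element: str
    abundances: Mapping[str, float]

    def __post_init__(self) -> None:
        for iso, a in self.abundances.items():
            if not a > 0:
                raise InvalidInputError(f"abundance of {iso} must be positive")


@dataclass(frozen=True)
class GofResult:
    chi_square: float
    dof: int
    decision_note: str = ""


def relative_isotope_counts(
    pattern: IsotopePattern, isotopes: Sequence[str]
) -> dict[str, float]:
    """Fractions of each named isotope over the named subset's total count."""
    missing = [iso for iso in isotopes if iso not in pattern.counts]
    if missing:
        raise InvalidInputError(f"isotopes missing from pattern: {', '.join(missing)}")
    subset = np.array([pattern.counts[iso] for iso in isotopes], dtype=float)
    total = subset.sum()
    if total <= 0:
        raise InvalidInputError("summed count over the isotope subset is zero")
    return {iso: float(c / total) for iso, c in zip(isotopes, subset)}


def expected_fractions(ref: IsotopeReference, isotopes: Sequence[str]) -> dict[str, float]:
    """Natural-abundance fractions renormalized over the chosen subset."""
    if not isotopes:
        raise InvalidInputError("empty isotope subset")
    unknown = [iso for iso in isotopes if iso not in ref.abundances]
    if unknown:
        raise InvalidInputError(
            f"unknown isotope(s) for {ref.element}: {', '.join(unknown)}"
        )
    subset = np.array([ref.abundances[iso] for iso in isotopes], dtype=float)
    total = subset.sum()
    return {iso: float(a / total) for iso, a in zip(isotopes, subset)}


def isotope_gof(
    pattern: IsotopePattern, ref: IsotopeReference, isotopes: Sequence[str]
) -> GofResult:
    """Pearson chi-square of observed counts vs abundance-expected counts.

    Expected counts are total * expected fraction; dof = k - 1.  The
    asymptotic statistic is unreliable when any expected count drops
    below 5 (a warning is emitted, not an error).
    """
    observed = np.array([pattern.counts[iso] for iso in isotopes], dtype=float)
    total = observed.sum()
    if total <= 0:
        raise InvalidInputError("zero total count; goodness of fit undefined")
    exp_frac = expected_fractions(ref, isotopes)
    expected = total * np.array([exp_frac[iso] for iso in isotopes])
    if expected.min() < 5:
        warnings.warn(
            "expected count below 5 in at least one cell; chi-square asymptotics "
            "are unreliable",
            stacklevel=2,
        )
    chi2 = float(stats.chisquare(observed, f_exp=expected).statistic)
    return GofResult(
        chi_square=chi2,
        dof=len(isotopes) - 1,
        decision_note="no default pass/fail verdict; compare fractions side by side",
    )
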