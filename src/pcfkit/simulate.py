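"""Seeded synthetic data with the statistical structure of each pipeline stage.

Each generator is a pure function of its spec (same seed, byte-identical
output; the random source is numpy's PCG64 ``default_rng``) and emulates the
corresponding measurement:

* I/V sweeps — 21-point -1..1 V scans whose underlying conductance realizes a
  chosen true conductivity given the strain geometry and a drawn electrode
  gap in 100-800 µm, with Gaussian relative current noise; an optional
  fraction of filaments is generated below the detection limit (at 0.1x the
  LOD conductance, to exercise the censoring boundary).
* EDX region counts — Poisson counts whose expectations realize a planted
  composition under given sensitivity factors.
* Isotope patterns — multinomial draws at the natural-abundance fractions.
* Proteome pairs — random background proteins plus planted homolog pairs
  carrying prescribed numbers of CXXCH motifs; partners diverge by i.i.d.
  point mutation that masks motif positions and substitutes only non-C/non-H
  residues, so planted heme counts survive mutation.
* Vesicles — Bernoulli IMAV/CV labels and truncated-normal diameters.

Defaults reproduce the study conditions of the measurements they emulate
(true sigma 4.0 S/cm at 5% noise; 10^4 EDX counts; IMAV fraction 0.9 with
65.5 +/- 4.6 nm diameters; 8 planted homologs + 12 decoys at 10% mutation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .edx import EDXRegionCounts, SensitivityFactors
from .errors import InvalidInputError
from .heme import MotifSpec, ProteinRecord, annotate
from .isotope import IsotopePattern, IsotopeReference
from .iv import AnalysisConfig, IVSweep, StrainGeometry, resolve_area_nm2
from .morphometry import VesicleObservation

__all__ = [
    "IVSimSpec",
    "EDXSimSpec",
    "IsotopeSimSpec",
    "ProteomeSimSpec",
    "VesicleSimSpec",
    "gen_iv_sweeps",
    "gen_edx_counts",
    "gen_isotope_counts",
    "gen_proteome_pair",
    "gen_vesicles",
]

RNG_ALGORITHM = "numpy.random.default_rng (PCG64)"

_NON_CH_RESIDUES = "ADEFGIKLMNPQRSTVWY"  # 18 residues; excludes C and H
_ALL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

# Natural amino-acid background frequencies (Robinson & Robinson).  Random
# background/decoy sequences are drawn from these rather than uniformly:
# uniform sampling overrepresents rare residues with large self-scores
# (W, C) about fivefold and inflates spurious local-alignment scores.
_AA_BACKGROUND = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}


def _background_probs(alphabet: str) -> np.ndarray:
    p = np.array([_AA_BACKGROUND[a] for a in alphabet])
    return p / p.sum()


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise InvalidInputError(f"{name} must be in [0, 1], got {value}")


# ---------------------------------------------------------------------------
# I/V sweeps

@dataclass(frozen=True)
class IVSimSpec:
    seed: int = 0
    n: int = 200
    true_sigma_s_per_cm: float = 4.0
    noise_fraction: float = 0.05
    lod_fraction: float = 0.0
    strain_label: str = "GS"
    n_points: int = 21

    def __post_init__(self) -> None:
        if self.true_sigma_s_per_cm < 0:
            raise InvalidInputError("true sigma must be non-negative")
        _check_fraction("noise_fraction", self.noise_fraction)
        _check_fraction("lod_fraction", self.lod_fraction)


def gen_iv_sweeps(
    spec: IVSimSpec,
    geometry: StrainGeometry,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> tuple[list[IVSweep], pd.DataFrame]:
    """Synthetic sweeps plus a truth table (sample_id, gap, conductance, censored)."""
    rng = np.random.default_rng(spec.seed)
    area_nm2 = resolve_area_nm2(geometry)
    voltages = np.linspace(-1.0, 1.0, spec.n_points)
    below = np.zeros(spec.n, dtype=bool)
    n_below = int(round(spec.lod_fraction * spec.n))
    if n_below:
        below[rng.choice(spec.n, size=n_below, replace=False)] = True

    sweeps: list[IVSweep] = []
    truth_rows = []
    for k in range(spec.n):
        gap_um = rng.uniform(100.0, 800.0)
        if below[k]:
            conductance = 0.1 * cfg.lod_conductance_a_per_v
        else:
            # sigma [S/cm] -> conductance G = sigma * A / l in SI
            sigma_si = spec.true_sigma_s_per_cm * 100.0
            conductance = sigma_si * (area_nm2 * 1e-18) / (gap_um * 1e-6)
        ideal = conductance * voltages
        if spec.noise_fraction > 0:
            currents = ideal * (1.0 + spec.noise_fraction * rng.standard_normal(ideal.shape))
        else:
            currents = ideal
        sid = f"{spec.strain_label}-sim-{k:04d}"
        sweeps.append(
            IVSweep(
                sample_id=sid,
                strain_label=spec.strain_label,
                voltages=voltages.copy(),
                currents=currents,
                gap_length_um=gap_um,
            )
        )
        truth_rows.append(
            {
                "sample_id": sid,
                "gap_um": gap_um,
                "true_conductance_a_per_v": conductance,
                "true_sigma_s_per_cm": None if below[k] else spec.true_sigma_s_per_cm,
                "below_lod": bool(below[k]),
            }
        )
    return sweeps, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# EDX counts

@dataclass(frozen=True)
class EDXSimSpec:
    seed: int = 0
    n_regions: int = 50
    composition: tuple[tuple[str, float], ...] = (("S", 24.9), ("Fe", 72.7), ("Ni", 2.4))
    factors: tuple[tuple[str, float], ...] = (("S", 1.0), ("Fe", 1.0), ("Ni", 1.0))
    total_counts: float = 10_000.0
    poisson: bool = True  # False -> zero-variance expectation mode
    strain_label: str = "sim"

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.composition)
        if abs(total - 100.0) > 0.2:
            raise InvalidInputError(
                f"planted composition must lie on the 100% simplex, sums to {total}"
            )
        for el, f in self.factors:
            if not f > 0:
                raise InvalidInputError(f"factor for {el} must be positive")


def gen_edx_counts(spec: EDXSimSpec) -> tuple[list[EDXRegionCounts], SensitivityFactors]:
    """Synthetic per-region counts whose quantification recovers the planted
    composition; returns the regions and the factors to quantify them with."""
    rng = np.random.default_rng(spec.seed)
    comp = dict(spec.composition)
    factors = dict(spec.factors)
    # relative_atomic_percent weights counts by f, so expected raw counts are
    # proportional to percent/f
    weights = np.array([comp[el] / factors[el] for el in comp])
    probs = weights / weights.sum()
    regions: list[EDXRegionCounts] = []
    for k in range(spec.n_regions):
        expected = spec.total_counts * probs
        if spec.poisson:
            counts = rng.poisson(expected).astype(float)
        else:
            counts = expected
        regions.append(
            EDXRegionCounts(
                section_id=f"{spec.strain_label}-region-{k:03d}",
                strain_label=spec.strain_label,
                counts={el: float(c) for el, c in zip(comp, counts)},
            )
        )
    return regions, SensitivityFactors(factors=factors)


# ---------------------------------------------------------------------------
# Isotope counts

@dataclass(frozen=True)
class IsotopeSimSpec:
    seed: int = 0
    total_counts: int = 100_000
    expectation: bool = False  # True -> exact expected counts, no sampling
    sample_id: str = "sim"

    def __post_init__(self) -> None:
        if self.total_counts <= 0:
            raise InvalidInputError("total_counts must be positive")


def gen_isotope_counts(
    spec: IsotopeSimSpec,
    ref: IsotopeReference,
    isotopes: Optional[Sequence[str]] = None,
) -> IsotopePattern:
    """Multinomial isotope counts at the reference's subset fractions."""
    isotopes = list(isotopes) if isotopes is not None else list(ref.abundances)
    if not isotopes:
        raise InvalidInputError("empty isotope subset")
    ab = np.array([ref.abundances[i] for i in isotopes], dtype=float)
    probs = ab / ab.sum()
    if spec.expectation:
        counts = spec.total_counts * probs
    else:
        rng = np.random.default_rng(spec.seed)
        counts = rng.multinomial(spec.total_counts, probs).astype(float)
    return IsotopePattern(
        counts={iso: float(c) for iso, c in zip(isotopes, counts)},
        sample_id=spec.sample_id,
    )


# ---------------------------------------------------------------------------
# Proteome pairs

@dataclass(frozen=True)
class ProteomeSimSpec:
    seed: int = 42
    n_planted: int = 8
    n_decoys: int = 12
    mutation_rate: float = 0.10
    heme_counts: tuple[int, ...] = (5, 5, 5, 4, 2, 1, 3, 0)
    lengths: tuple[int, ...] = (180, 600, 240, 320, 280, 260, 300, 220)
    decoy_length: int = 280

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_rate <= 0.3:
            raise InvalidInputError("mutation_rate must be in [0, 0.3]")
        if len(self.heme_counts) != self.n_planted or len(self.lengths) != self.n_planted:
            raise InvalidInputError("heme_counts and lengths must match n_planted")
        for k, L in zip(self.heme_counts, self.lengths):
            if k * 10 + 5 > L:  # motifs are spaced ~L/k apart; need room for k windows
                raise InvalidInputError(
                    f"cannot place {k} motifs in a {L}-residue protein"
                )


def _random_sequence(rng: np.random.Generator, length: int, alphabet: str) -> str:
    return "".join(rng.choice(list(alphabet), size=length, p=_background_probs(alphabet)))


def _plant_motifs(rng: np.random.Generator, length: int, k: int) -> tuple[str, list[int]]:
    """Motif-free random backbone (no C/H) with k CXXCH motifs planted evenly."""
    seq = list(_random_sequence(rng, length, _NON_CH_RESIDUES))
    starts: list[int] = []
    if k:
        slots = np.linspace(0, length - 5, k).astype(int) if k > 1 else np.array([length // 2])
        for s in slots:
            seq[s] = "C"
            seq[s + 3] = "C"
            seq[s + 4] = "H"
            starts.append(int(s))
    return "".join(seq), starts


def _mutate(
    rng: np.random.Generator, seq: str, rate: float, protected: set[int]
) -> str:
    out = list(seq)
    for i in range(len(out)):
        if i in protected:
            continue
        if rng.random() < rate:
            choices = _NON_CH_RESIDUES.replace(out[i], "")
            out[i] = choices[int(rng.choice(len(choices), p=_background_probs(choices)))]
    return "".join(out)


def gen_proteome_pair(
    spec: ProteomeSimSpec, motif_spec: MotifSpec = MotifSpec()
) -> tuple[list[ProteinRecord], list[ProteinRecord], pd.DataFrame]:
    """Two proteomes with planted homolog pairs, plus the ground-truth table.

    Proteome A holds the planted originals and half the decoys; proteome B
    holds the mutated partners and the other decoys.  The truth table lists
    pair ids, planted heme counts and cytochrome classes.
    """
    rng = np.random.default_rng(spec.seed)
    proteome_a: list[ProteinRecord] = []
    proteome_b: list[ProteinRecord] = []
    truth_rows = []
    for k in range(spec.n_planted):
        seq, starts = _plant_motifs(rng, spec.lengths[k], spec.heme_counts[k])
        protected = {p for s in starts for p in range(s, s + 5)}
        partner = _mutate(rng, seq, spec.mutation_rate, protected)
        rec_a = ProteinRecord(id=f"A_plant_{k:02d}", sequence=seq)
        rec_b = ProteinRecord(id=f"B_plant_{k:02d}", sequence=partner)
        proteome_a.append(rec_a)
        proteome_b.append(rec_b)
        ann = annotate(rec_a, motif_spec)
        truth_rows.append(
            {
                "id_a": rec_a.id,
                "id_b": rec_b.id,
                "heme_count": ann.heme_count,
                "cytochrome_class": ann.cytochrome_class,
            }
        )
    for k in range(spec.n_decoys):
        seq = _random_sequence(rng, spec.decoy_length, _ALL_RESIDUES)
        target = proteome_a if k % 2 == 0 else proteome_b
        prefix = "A" if k % 2 == 0 else "B"
        target.append(ProteinRecord(id=f"{prefix}_decoy_{k:02d}", sequence=seq))
    return proteome_a, proteome_b, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Vesicles

@dataclass(frozen=True)
class VesicleSimSpec:
    seed: int = 0
    n: int = 500
    imav_fraction: float = 0.9
    imav_diameter_mean_nm: float = 65.5
    imav_diameter_std_nm: float = 4.6
    cv_diameter_mean_nm: float = 68.9
    cv_diameter_std_nm: float = 4.6

    def __post_init__(self) -> None:
        _check_fraction("imav_fraction", self.imav_fraction)
        if self.n < 1:
            raise InvalidInputError("need at least one vesicle")
        for name in ("imav_diameter_mean_nm", "imav_diameter_std_nm",
                     "cv_diameter_mean_nm", "cv_diameter_std_nm"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")


def gen_vesicles(spec: VesicleSimSpec) -> list[VesicleObservation]:
    """Bernoulli IMAV/CV labels with Normal diameters truncated at zero."""
    rng = np.random.default_rng(spec.seed)
    obs: list[VesicleObservation] = []
    for _ in range(spec.n):
        is_imav = rng.random() < spec.imav_fraction
        mean = spec.imav_diameter_mean_nm if is_imav else spec.cv_diameter_mean_nm
        std = spec.imav_diameter_std_nm if is_imav else spec.cv_diameter_std_nm
        d = rng.normal(mean, std)
        while d <= 0:  # truncation at zero; essentially never loops at defaults
            d = rng.normal(mean, std)
        obs.append(VesicleObservation(diameter_nm=float(d), attachment="IMAV" if is_imav else "CV"))
    return obs
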