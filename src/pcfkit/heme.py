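"""CXXCH heme-motif mining and inter-proteome cytochrome conservation.

c-type cytochromes covalently bind heme at CXXCH motifs (cysteine, two
arbitrary residues, cysteine, histidine), so counting motif occurrences in a
protein counts its hemes.  Proteins with exactly five hemes form the
cable-bacteria pentaheme cytochrome (PHC) family, split into a small variant
(sPHC) and a large variant (lPHC, optionally fused to truncated-hemoglobin
domains) by the size of the cytochrome domain; here the split is made on
sequence length with a configurable threshold.

Conservation between two proteomes is established by reciprocal best hits
(RBH): x in proteome A and y in proteome B are conserved partners iff y is
x's unique top-scoring hit and vice versa, both above a score threshold.
Scores are Smith-Waterman optimal local alignment scores with affine gaps
(default BLOSUM62, gap open 11, gap extend 1; a gap of length k costs
open + k*extend, the BLAST convention).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ConfigError, InvalidInputError

__all__ = [
    "ProteinRecord",
    "MotifSpec",
    "HemeAnnotation",
    "ScoringScheme",
    "HomologPair",
    "CensusResult",
    "scan_heme_motifs",
    "classify_cytochrome",
    "local_align",
    "reciprocal_best_hits",
    "conserved_cytochrome_census",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
LENIENT_AA = STANDARD_AA | {"X"}

CYTOCHROME_CLASSES = (
    "none",
    "monoheme",
    "multiheme",
    "pentaheme_sPHC",
    "pentaheme_lPHC",
    "other_pentaheme",
)

DEFAULT_SPHC_MAX_LENGTH = 250


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence; uppercase, 20 standard residues plus X."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise InvalidInputError("protein record needs a non-empty id")
        if not self.sequence:
            raise InvalidInputError(f"protein {self.id!r}: empty sequence")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - LENIENT_AA
        if bad:
            raise InvalidInputError(
                f"protein {self.id!r}: unknown residue(s) {''.join(sorted(bad))}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifSpec:
    """Heme-binding motif C-x{n}-C-H; default n=2 (the canonical CXXCH)."""

    n_internal: int = 2
    overlap_policy: str = "non_overlapping"  # or "all"

    def __post_init__(self) -> None:
        if self.n_internal < 1:
            raise ConfigError("motif needs at least one internal wildcard")
        if self.overlap_policy not in ("non_overlapping", "all"):
            raise ConfigError(f"unknown overlap policy {self.overlap_policy!r}")

    @property
    def window(self) -> int:
        return self.n_internal + 3


@dataclass(frozen=True)
class HemeAnnotation:
    protein_id: str
    motif_starts: tuple[int, ...]
    heme_count: int
    cytochrome_class: str = "none"

    def __post_init__(self) -> None:
        if self.heme_count != len(self.motif_starts):
            raise InvalidInputError("heme count must equal number of motif starts")


@dataclass(frozen=True)
class ScoringScheme:
    """Local-alignment scoring: substitution matrix plus affine gap penalties.

    A gap of length k costs ``gap_open + k * gap_extend``.  In lenient mode
    the ambiguous residue X scores 0 against everything; strict mode rejects
    sequences containing X.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    strict: bool = False

    def __post_init__(self) -> None:
        if not (self.gap_open > 0 and self.gap_extend > 0):
            raise ConfigError("gap penalties must be positive")


@dataclass(frozen=True)
class HomologPair:
    id_a: str
    id_b: str
    score_ab: float
    score_ba: float
    reciprocal: bool
    tied: bool = False


@dataclass(frozen=True)
class CensusResult:
    """Conserved-cytochrome census between two proteomes."""

    table: pd.DataFrame  # one row per conserved pair where both sides bear hemes
    discordant: tuple[str, ...]  # pair labels where only one side bears a motif
    n_conserved_cytochromes: int
    n_conserved_multiheme: int
    n_conserved_pentaheme: int


def _window_matches(seq: str, i: int, spec: MotifSpec) -> bool:
    w = spec.window
    return (
        i + w <= len(seq)
        and seq[i] == "C"
        and seq[i + w - 2] == "C"
        and seq[i + w - 1] == "H"
    )


def scan_heme_motifs(rec: ProteinRecord, spec: MotifSpec = MotifSpec()) -> HemeAnnotation:
    """Left-to-right scan for the C-x{n}-C-H motif.

    Under the default ``non_overlapping`` policy the scan resumes after a
    match's last residue; ``all`` reports every matching window.
    """
    seq = rec.sequence
    starts: list[int] = []
    i = 0
    while i + spec.window <= len(seq):
        if _window_matches(seq, i, spec):
            starts.append(i)
            i += spec.window if spec.overlap_policy == "non_overlapping" else 1
        else:
            i += 1
    return HemeAnnotation(
        protein_id=rec.id, motif_starts=tuple(starts), heme_count=len(starts)
    )


def classify_cytochrome(
    ann: HemeAnnotation,
    seq_length: int,
    sphc_max_length: int = DEFAULT_SPHC_MAX_LENGTH,
) -> str:
    """Cytochrome class from heme count, with the pentaheme sPHC/lPHC split.

    0 hemes -> none; 1 -> monoheme; >= 2 -> multiheme, except exactly 5 which
    is pentaheme: sPHC when the sequence is at most ``sphc_max_length``
    residues, lPHC otherwise.
    """
    if sphc_max_length < 0:
        raise ConfigError("sPHC length threshold must be non-negative")
    n = ann.heme_count
    if n == 0:
        return "none"
    if n == 1:
        return "monoheme"
    if n == 5:
        return "pentaheme_sPHC" if seq_length <= sphc_max_length else "pentaheme_lPHC"
    return "multiheme"


def annotate(
    rec: ProteinRecord,
    spec: MotifSpec = MotifSpec(),
    sphc_max_length: int = DEFAULT_SPHC_MAX_LENGTH,
) -> HemeAnnotation:
    """Scan and classify in one step."""
    ann = scan_heme_motifs(rec, spec)
    cls = classify_cytochrome(ann, len(rec), sphc_max_length)
    return HemeAnnotation(
        protein_id=ann.protein_id,
        motif_starts=ann.motif_starts,
        heme_count=ann.heme_count,
        cytochrome_class=cls,
    )


@functools.lru_cache(maxsize=8)
def _build_aligner(matrix_name: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    matrix = substitution_matrices.load(matrix_name)
    if "X" in matrix.alphabet:
        matrix = matrix.copy()
        for letter in matrix.alphabet:
            matrix["X", letter] = 0.0
            matrix[letter, "X"] = 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    # first gapped position costs open+extend, later ones extend each:
    # a k-gap then totals open + k*extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _check_residues(rec: ProteinRecord, strict: bool) -> None:
    if strict and "X" in rec.sequence:
        raise InvalidInputError(
            f"protein {rec.id!r}: residue X not allowed in strict scoring mode"
        )


def local_align(a: ProteinRecord, b: ProteinRecord, s: ScoringScheme = ScoringScheme()) -> float:
    """Smith-Waterman optimal local alignment score (affine gaps).

    Symmetric in its arguments and never negative (the empty alignment
    scores 0).
    """
    _check_residues(a, s.strict)
    _check_residues(b, s.strict)
    aligner = _build_aligner(s.matrix_name, s.gap_open, s.gap_extend)
    return float(aligner.score(a.sequence, b.sequence))


def _best_hits(
    queries: Sequence[ProteinRecord],
    scores: np.ndarray,
    target_ids: Sequence[str],
    axis_ids: Sequence[str],
) -> dict[str, tuple[str, float, bool]]:
    """Per-query (best-target-id, score, tied?) with lexicographic tie-break."""
    out: dict[str, tuple[str, float, bool]] = {}
    for qi, qid in enumerate(axis_ids):
        row = scores[qi]
        best = row.max()
        winners = [target_ids[j] for j in np.flatnonzero(row == best)]
        out[qid] = (min(winners), float(best), len(winners) > 1)
    return out


def reciprocal_best_hits(
    proteome_a: Sequence[ProteinRecord],
    proteome_b: Sequence[ProteinRecord],
    s: ScoringScheme = ScoringScheme(),
    min_score: float = 50.0,
) -> list[HomologPair]:
    """Reciprocal best hits between two proteomes under local-alignment scores.

    (x, y) is reciprocal iff y is x's best hit in B, x is y's best hit in A,
    and both scores reach ``min_score``.  Best-hit ties are broken by
    lexicographic id and the pair is flagged ``tied``.
    """
    ids_a = [r.id for r in proteome_a]
    ids_b = [r.id for r in proteome_b]
    for name, ids in (("A", ids_a), ("B", ids_b)):
        if len(ids) != len(set(ids)):
            raise InvalidInputError(f"duplicate protein ids in proteome {name}")
    if not proteome_a or not proteome_b:
        return []

    scores = np.zeros((len(proteome_a), len(proteome_b)))
    for i, ra in enumerate(proteome_a):
        for j, rb in enumerate(proteome_b):
            scores[i, j] = local_align(ra, rb, s)

    best_in_b = _best_hits(proteome_a, scores, ids_b, ids_a)
    best_in_a = _best_hits(proteome_b, scores.T, ids_a, ids_b)

    pairs: list[HomologPair] = []
    for ia, ida in enumerate(ids_a):
        idb, score_ab, tied_a = best_in_b[ida]
        back, score_ba, tied_b = best_in_a[idb]
        if back != ida:
            continue
        if score_ab < min_score or score_ba < min_score:
            continue
        pairs.append(
            HomologPair(
                id_a=ida,
                id_b=idb,
                score_ab=score_ab,
                score_ba=score_ba,
                reciprocal=True,
                tied=tied_a or tied_b,
            )
        )
    return pairs


def conserved_cytochrome_census(
    proteome_a: Sequence[ProteinRecord],
    proteome_b: Sequence[ProteinRecord],
    spec: MotifSpec = MotifSpec(),
    scheme: ScoringScheme = ScoringScheme(),
    min_score: float = 50.0,
    sphc_max_length: int = DEFAULT_SPHC_MAX_LENGTH,
) -> CensusResult:
    """Census of heme-bearing reciprocal pairs between two proteomes.

    A pair enters the census only when BOTH members carry at least one heme
    motif; pairs where exactly one member does are listed as discordant.
    """
    ann_a = {r.id: annotate(r, spec, sphc_max_length) for r in proteome_a}
    ann_b = {r.id: annotate(r, spec, sphc_max_length) for r in proteome_b}
    pairs = reciprocal_best_hits(proteome_a, proteome_b, scheme, min_score)

    rows = []
    discordant: list[str] = []
    for p in pairs:
        a, b = ann_a[p.id_a], ann_b[p.id_b]
        if a.heme_count >= 1 and b.heme_count >= 1:
            rows.append(
                {
                    "id_a": p.id_a,
                    "id_b": p.id_b,
                    "score": p.score_ab,
                    "hemes_a": a.heme_count,
                    "hemes_b": b.heme_count,
                    "class_a": a.cytochrome_class,
                    "class_b": b.cytochrome_class,
                    "tied": p.tied,
                }
            )
        elif a.heme_count >= 1 or b.heme_count >= 1:
            discordant.append(f"{p.id_a}~{p.id_b}")

    table = pd.DataFrame(
        rows,
        columns=["id_a", "id_b", "score", "hemes_a", "hemes_b", "class_a", "class_b", "tied"],
    )
    pentaheme = int(
        ((table["hemes_a"] == 5) & (table["hemes_b"] == 5)).sum()
    ) if len(table) else 0
    multiheme = int(
        ((table["hemes_a"] >= 2) & (table["hemes_b"] >= 2)).sum()
    ) if len(table) else 0
    return CensusResult(
        table=table,
        discordant=tuple(discordant),
        n_conserved_cytochromes=len(table),
        n_conserved_multiheme=multiheme,
        n_conserved_pentaheme=pentaheme,
    )
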