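"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths under test: ordinary least squares
via the closed-form normal equations, Smith-Waterman via a plain quadratic
Gotoh dynamic program, and motif detection via brute-force window
enumeration.
"""

from __future__ import annotations

from typing import Callable, Sequence

from Bio.Align import substitution_matrices


def ols_line(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Closed-form least-squares slope/intercept from the normal equations."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(v * v for v in x)
    sxy = sum(v * w for v, w in zip(x, y))
    denom = n * sxx - sx * sx
    slope = (n * sxy - sx * sy) / denom
    intercept = (sy - slope * sx) / n
    return slope, intercept


def blosum62_lookup(x_scores_zero: bool = True) -> Callable[[str, str], float]:
    """Substitution lookup for the oracle DP (X scores 0 against everything)."""
    matrix = substitution_matrices.load("BLOSUM62")

    def lookup(a: str, b: str) -> float:
        if x_scores_zero and ("X" in (a, b)):
            return 0.0
        return float(matrix[a, b])

    return lookup


def sw_score_gotoh(
    a: str,
    b: str,
    substitution: Callable[[str, str], float],
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> float:
    """Quadratic-time Smith-Waterman score with affine gaps (Gotoh recursion).

    A gap of length k costs gap_open + k * gap_extend.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    first = gap_open + gap_extend
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - first, E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - first, F[i][j - 1] - gap_extend)
            diag = H[i - 1][j - 1] + substitution(a[i - 1], b[j - 1])
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def enumerate_motif_windows(seq: str, n_internal: int = 2) -> list[int]:
    """Every window matching C-x{n}-C-H, by exhaustive enumeration."""
    w = n_internal + 3
    return [
        i
        for i in range(len(seq) - w + 1)
        if seq[i] == "C" and seq[i + w - 2] == "C" and seq[i + w - 1] == "H"
    ]
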