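"""Protein scoring schemes and Karlin–Altschul statistics.

The translated-homology searches score amino-acid alignments with an
integer substitution matrix (BLOSUM62 by default) and affine gap
penalties, and convert raw local-alignment scores to bit scores and
E-values through the Karlin–Altschul formalism::

    bits = (lambda * S - ln K) / ln 2
    E    = K * m * n * exp(-lambda * S)

where ``m`` is the query length, ``n`` the total search-space length
(in residues) and ``(lambda, K)`` are the statistical parameters of the
scoring regime.  The default gapped pair (11/1 with BLOSUM62) uses the
conventional precomputed values; no composition-based adjustment or
edge-effect correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

#: Internal amino-acid alphabet: the 20 canonical residues, then the
#: ambiguity character X and the stop character '*'.  Translated frames
#: and database proteins are encoded against this order.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX*"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
N_AA = len(AA_ALPHABET)

# Robinson & Robinson background amino-acid frequencies, indexed as
# AA_ALPHABET[:20]; used to solve the ungapped characteristic equation.
_ROBINSON = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}
BACKGROUND_FREQS = np.array([_ROBINSON[a] for a in AA_ALPHABET[:20]])
BACKGROUND_FREQS = BACKGROUND_FREQS / BACKGROUND_FREQS.sum()


def load_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """Return an ``N_AA x N_AA`` int matrix over :data:`AA_ALPHABET`.

    Scores come from the named substitution matrix; residues absent
    from it fall back to the matrix's X column.
    """
    m = substitution_matrices.load(name)
    out = np.zeros((N_AA, N_AA), dtype=np.int64)
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            aa = a if a in m.alphabet else "X"
            bb = b if b in m.alphabet else "X"
            out[i, j] = int(m[aa, bb])
    return out


def encode_aa(seq: str) -> np.ndarray:
    """Encode an amino-acid string as int8 indices into AA_ALPHABET.

    Unknown / ambiguous residues (B, Z, J, U, O ...) map to X.
    """
    x = AA_INDEX["X"]
    return np.array([AA_INDEX.get(c, x) for c in seq.upper()], dtype=np.int8)


def karlin_lambda_ungapped(
    matrix: np.ndarray,
    freqs: np.ndarray = BACKGROUND_FREQS,
    tol: float = 1e-9,
) -> float:
    """Solve the Karlin–Altschul characteristic equation for lambda.

    Finds the unique positive root of
    ``sum_ij p_i p_j exp(lambda * s_ij) = 1`` by bisection.  Requires a
    matrix with negative expected score and at least one positive entry.
    """
    s = matrix[:20, :20].astype(float)
    p = np.outer(freqs, freqs)
    expected = float((p * s).sum())
    if expected >= 0:
        raise ValueError("expected score must be negative for valid statistics")
    if s.max() <= 0:
        raise ValueError("matrix must have at least one positive score")

    def phi(lam: float) -> float:
        return float((p * np.exp(lam * s)).sum()) - 1.0

    lo, hi = 1e-6, 2.0
    while phi(hi) < 0:
        hi *= 2.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if phi(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class ScoringScheme:
    """Scoring parameters for the translated searches.

    Defaults are BLOSUM62 with gap open 11 / extend 1 (a gap of length
    ``k`` costs ``gap_open + k * gap_extend``), word size 3 with a
    neighborhood word threshold of 11, and the conventional gapped
    Karlin parameters for that matrix/gap pair.
    """

    matrix: np.ndarray = field(default_factory=load_matrix)
    gap_open: int = 11
    gap_extend: int = 1
    karlin_lambda: float = 0.267
    karlin_K: float = 0.041
    word_size: int = 3
    neighborhood_threshold: int = 11
    #: pairs with q*s cells at or below this run exact Smith-Waterman
    sw_fallback_cells: int = 400_000
    #: raw-score drop allowed during ungapped seed extension
    ungapped_xdrop: int = 16
    #: minimum ungapped extension score to trigger gapped extension
    ungapped_trigger: int = 60
    #: max diagonal distance between two word hits forming a seed pair
    two_hit_window: int = 40

    def __post_init__(self) -> None:
        if self.matrix.shape != (N_AA, N_AA):
            raise ValueError(f"matrix must be {N_AA}x{N_AA} over {AA_ALPHABET!r}")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")
        if self.gap_open < 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be non-negative / positive")

    def bit_score(self, raw: float) -> float:
        return (self.karlin_lambda * raw - math.log(self.karlin_K)) / math.log(2)

    def evalue(self, raw: float, m: int, n: int) -> float:
        # K*m*n*exp(-lambda*S), computed in log space to avoid underflow
        log_e = (
            math.log(self.karlin_K)
            + math.log(m)
            + math.log(n)
            - self.karlin_lambda * raw
        )
        return math.exp(log_e) if log_e > -700 else 5e-324
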