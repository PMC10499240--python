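"""Substitution scoring and diagonal weights for gap-free pairwise alignments.

A *diagonal* (an ungapped pairwise alignment of two equal-length segments)
is scored by summing integer substitution-matrix scores column by column.
Its *weight* is the negative natural log of the probability that a random
pair of independent segments of the same length — residues drawn i.i.d.
from a background distribution — reaches at least that summed score:

    w(l, s) = -ln P(score >= s | length l)

so a weight threshold of 10 corresponds to a match probability below
e^-10 ~ 4.5e-5 in random sequences.  P is computed exactly by convolving
the integer per-column score distribution ``l`` times; no asymptotic
approximation is involved.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

#: Robinson & Robinson (1991) amino-acid background frequencies, the
#: standard background for protein local-alignment statistics.
ROBINSON_FREQUENCIES = {
    "A": 0.078047, "R": 0.051269, "N": 0.044873, "D": 0.053640,
    "C": 0.019246, "Q": 0.042644, "E": 0.062949, "G": 0.073772,
    "H": 0.021992, "I": 0.051420, "L": 0.090191, "K": 0.057438,
    "M": 0.022425, "F": 0.038556, "P": 0.052028, "S": 0.071198,
    "T": 0.058413, "W": 0.013298, "Y": 0.032165, "V": 0.064409,
}


class ScoringModel:
    """Integer substitution scores plus the exact weight tables.

    Parameters
    ----------
    matrix:
        Name of a Biopython substitution matrix (default ``"BLOSUM62"``),
        or a mapping ``(aa, aa) -> int`` over `alphabet`.
    background:
        Mapping residue -> frequency over `alphabet`; renormalised.
        Defaults to the Robinson–Robinson frequencies.
    alphabet:
        Residue alphabet; the unknown residue ``X`` is always appended
        and scores 0 against everything.
    """

    def __init__(self, matrix="BLOSUM62", background=None, alphabet=AMINO_ACIDS):
        self.alphabet = alphabet
        self.n = len(alphabet)
        if isinstance(matrix, str):
            mat = substitution_matrices.load(matrix)
            scores = np.array(
                [[int(mat[a, b]) for b in alphabet] for a in alphabet],
                dtype=np.int64,
            )
        else:
            scores = np.array(
                [[int(matrix[a, b]) for b in alphabet] for a in alphabet],
                dtype=np.int64,
            )
        # pad with an X row/column scoring 0 against everything
        self.score = np.zeros((self.n + 1, self.n + 1), dtype=np.int64)
        self.score[: self.n, : self.n] = scores
        self._index = {a: i for i, a in enumerate(alphabet)}
        self._index["X"] = self.n

        if background is None:
            background = ROBINSON_FREQUENCIES
        freqs = np.array([float(background[a]) for a in alphabet])
        if np.any(freqs <= 0):
            raise ValueError("background frequencies must be positive")
        self.background = freqs / freqs.sum()

        # per-column score distribution over residue pairs
        self.smin = int(scores.min())
        self.smax = int(scores.max())
        pair_prob = np.outer(self.background, self.background)
        pmf = np.zeros(self.smax - self.smin + 1)
        np.add.at(pmf, (scores - self.smin).ravel(), pair_prob.ravel())
        self._column_pmf = pmf

    def encode(self, sequence: str) -> np.ndarray:
        """Map a residue string to integer indices (X and unknowns -> X)."""
        n = self.n
        idx = self._index
        return np.fromiter(
            (idx.get(c, n) for c in sequence.upper()), dtype=np.int64,
            count=len(sequence),
        )

    def segment_score(self, seg_a: str, seg_b: str) -> int:
        """Summed substitution score of two equal-length ungapped segments."""
        if len(seg_a) != len(seg_b):
            raise ValueError(
                f"segments differ in length: {len(seg_a)} vs {len(seg_b)}"
            )
        if len(seg_a) == 0:
            raise ValueError("segments must have length >= 1")
        ia, ib = self.encode(seg_a), self.encode(seg_b)
        return int(self.score[ia, ib].sum())

    @lru_cache(maxsize=None)
    def _tables(self, length: int):
        """(pmf, tail) of the summed score at a given length.

        ``tail[k]`` is P(score >= length*smin + k), exact up to float64
        rounding of the repeated convolution.
        """
        pmf = self._column_pmf
        out = pmf
        for _ in range(length - 1):
            out = np.convolve(out, pmf)
        tail = np.cumsum(out[::-1])[::-1]
        return out, tail

    def tail_probability(self, length: int, score: int) -> float:
        """Exact P(summed score >= `score`) for random length-`length` pairs."""
        if length < 1:
            raise ValueError("length must be >= 1")
        _, tail = self._tables(length)
        k = score - length * self.smin
        if k < 0:
            return 1.0
        if k >= tail.size:
            return 0.0
        return float(tail[k])

    def weight(self, length: int, score: int) -> float:
        """-ln P(score >= s) in nats; +inf when the score is unattainable."""
        p = self.tail_probability(length, score)
        if p <= 0.0:
            return np.inf
        return float(-np.log(p))

    def weight_lookup(self, length: int) -> np.ndarray:
        """Vector w such that ``w[s - length*smin]`` is the weight of score s."""
        _, tail = self._tables(length)
        with np.errstate(divide="ignore"):
            return -np.log(tail)

    def corrected_weight(self, length: int, score: int,
                         len_a: int, len_b: int) -> float:
        """Sequence-length corrected weight, dialign style.

        The raw -ln P is the surprise of one fixed placement; comparing
        two sequences offers (len_a-l+1)(len_b-l+1) placements for a
        length-l diagonal, so the probability of observing such a score
        anywhere is bounded by N*P and the corrected weight is
        ``-ln P - ln N``.  This is the weight thresholded and ranked
        during enumeration; it may be negative for chance-level scores.
        """
        n = (len_a - length + 1) * (len_b - length + 1)
        if n < 1:
            raise ValueError("diagonal longer than a sequence")
        return self.weight(length, score) - float(np.log(n))


def diagonal_weight(seg_a: str, seg_b: str, scoring: ScoringModel) -> tuple[int, float]:
    """Score and -ln P weight of the diagonal aligning ``seg_a`` with ``seg_b``."""
    s = scoring.segment_score(seg_a, seg_b)
    return s, scoring.weight(len(seg_a), s)
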