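"""Polarization of read counts into a two-taxon coordinate system.

The two grandparents of the cross come from different taxa (the
*B. variegata* grandsire and the *B. bombina* granddam).  Dividing each
grandparent's count matrix by its column totals gives per-position state
frequencies; the difference (variegata minus bombina) is a signed matrix
whose positive entries mark states associated with the variegata side and
negative entries states associated with the bombina side.  Each column i is
down-weighted by the significance Sig(i) of a multinomial likelihood-ratio
test between the two grandparental count vectors — columns where the
grandparents look alike carry no ancestry signal and get weight
1 - Sig(i) ~ 0.  The result is the weighted polarized matrix M_p.

Multiplying a sample's raw counts elementwise into M_p and averaging the
positive and negative parts yields a (v, b) score pair: the average
weighted read coverage of variegata- and bombina-associated states.  In
this plane homozygotes lie on the axes, heterozygotes near the diagonal,
and low-coverage samples near the origin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import stats


@dataclass
class PolarizedMatrix:
    """The weighted polarized matrix M_p plus its per-column weights."""

    values: np.ndarray   # (6, n), entries in [-1, 1]
    weights: np.ndarray  # (n,), 1 - Sig(i), each in [0, 1]
    source: str = "initial_F0"  # or "updated_clusters"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.values.shape != (6, self.weights.shape[0]):
            raise ValueError("values must be 6 x n matching weights length")

    @property
    def n(self) -> int:
        return self.values.shape[1]

    @property
    def informative(self) -> np.ndarray:
        """Boolean mask of columns with weight > 0."""
        return self.weights > 0.0


@dataclass(frozen=True)
class SampleScore:
    """A sample's position in the (variegata, bombina) score plane."""

    v_score: float  # average weighted coverage of Bv-associated states
    b_score: float  # same for Bb-associated states

    @property
    def radius(self) -> float:
        return float(np.hypot(self.v_score, self.b_score))

    @property
    def angle(self) -> float:
        """Degrees in [0, 90]; 0 = pure variegata axis, 90 = pure bombina."""
        if self.radius == 0.0:
            return float("nan")
        return float(np.degrees(np.arctan2(self.b_score, self.v_score)))


def column_frequencies(counts: np.ndarray) -> np.ndarray:
    """Divide counts by column totals; zero-depth columns stay all-zero."""
    counts = np.asarray(counts, dtype=float)
    tot = counts.sum(axis=0)
    out = np.zeros_like(counts)
    nz = tot > 0
    out[:, nz] = counts[:, nz] / tot[nz]
    return out


def _multinomial_lnl(counts: np.ndarray) -> float:
    # log-likelihood at the MLE, dropping the multinomial coefficient
    # (it cancels in the ratio)
    counts = counts[counts > 0]
    n = counts.sum()
    return float(np.sum(counts * np.log(counts / n))) if n > 0 else 0.0


def position_weight(
    counts_bv_col: np.ndarray, counts_bb_col: np.ndarray
) -> Tuple[float, float]:
    """Significance Sig and weight 1 - Sig for one reference position.

    A G-test compares the hypotheses that the two grandparents' state counts
    at this position were drawn from the same versus different multinomials:
    G = 2 (lnL_separate - lnL_pooled), referred to a chi-square with
    df = (number of states observed in the pooled counts) - 1.  Positions
    with no contrast to test (either grandparent unobserved, or a single
    pooled state) get Sig = 1, weight = 0.
    """
    a = np.asarray(counts_bv_col, dtype=float)
    b = np.asarray(counts_bb_col, dtype=float)
    pooled = a + b
    df = int(np.count_nonzero(pooled)) - 1
    if df <= 0 or a.sum() == 0 or b.sum() == 0:
        return 1.0, 0.0
    g = 2.0 * (_multinomial_lnl(a) + _multinomial_lnl(b) - _multinomial_lnl(pooled))
    g = max(g, 0.0)
    sig = float(stats.chi2.sf(g, df))
    return sig, 1.0 - sig


def position_weights(counts_bv: np.ndarray, counts_bb: np.ndarray) -> np.ndarray:
    """Vector of weights 1 - Sig(i) over all columns of two 6 x n matrices."""
    counts_bv = np.asarray(counts_bv, dtype=float)
    counts_bb = np.asarray(counts_bb, dtype=float)
    n = counts_bv.shape[1]
    w = np.empty(n)
    for i in range(n):
        _, w[i] = position_weight(counts_bv[:, i], counts_bb[:, i])
    return w


def build_polarized_matrix(
    freq_bv: np.ndarray,
    freq_bb: np.ndarray,
    weights: np.ndarray,
    source: str = "initial_F0",
) -> PolarizedMatrix:
    """M_p[x, i] = (freq_bv[x, i] - freq_bb[x, i]) * weights[i]."""
    freq_bv = np.asarray(freq_bv, dtype=float)
    freq_bb = np.asarray(freq_bb, dtype=float)
    if freq_bv.shape != freq_bb.shape:
        raise ValueError("frequency matrices must have identical shapes")
    values = (freq_bv - freq_bb) * np.asarray(weights, dtype=float)[None, :]
    return PolarizedMatrix(values, weights, source)


def polarize_counts(
    counts_bv: np.ndarray, counts_bb: np.ndarray, source: str = "initial_F0"
) -> PolarizedMatrix:
    """Build M_p directly from two grandparental (or pooled-cluster) count
    matrices: frequencies, G-test weights, then the weighted difference."""
    w = position_weights(counts_bv, counts_bb)
    return build_polarized_matrix(
        column_frequencies(counts_bv), column_frequencies(counts_bb), w, source
    )


def score_sample(counts: np.ndarray, mp: PolarizedMatrix) -> SampleScore:
    """Project one sample's raw counts onto the polarized coordinate system.

    P = counts * M_p elementwise; v = (sum of positive entries of P) / m and
    b = |sum of negative entries| / m, where m is the number of informative
    columns (weight > 0).  With no informative columns the score is (0, 0).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != mp.values.shape:
        raise ValueError("counts shape does not match the polarized matrix")
    m = int(np.count_nonzero(mp.informative))
    if m == 0:
        return SampleScore(0.0, 0.0)
    p = counts * mp.values
    v = float(p[p > 0].sum()) / m
    b = float(-p[p < 0].sum()) / m
    return SampleScore(v, b)


def score_samples(stack: np.ndarray, mp: PolarizedMatrix) -> np.ndarray:
    """Vectorized scores for an (S, 6, n) stack; returns (S, 2) of (v, b)."""
    stack = np.asarray(stack, dtype=float)
    m = int(np.count_nonzero(mp.informative))
    if m == 0:
        return np.zeros((stack.shape[0], 2))
    p = stack * mp.values[None, :, :]
    v = np.where(p > 0, p, 0.0).sum(axis=(1, 2)) / m
    b = -np.where(p < 0, p, 0.0).sum(axis=(1, 2)) / m
    return np.column_stack([v, b])
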