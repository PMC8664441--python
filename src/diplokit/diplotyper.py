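"""Per-locus diplotype calling.

The caller works in two stages.  A heuristic stage clusters all samples'
(v, b) scores by angle in the polarized coordinate plane, updates the
polarized matrix from the pooled reads of the two clusters nearest the
axes (the "purest" individuals of each taxon, at far higher depth than the
two grandparents alone), and reduces each cluster's pooled counts to a
strict-majority consensus — the candidate haplotypes.  A likelihood stage
then coestimates the maximum-likelihood taxon haplotype pair and every
sample's ML diplotype (BbHOM / HET / BvHOM) under a Mendelian model: each
sample's count matrix must be explicable as a homozygous or heterozygous
combination of the pair, with sequencing error epsilon and, for
heterozygotes, an admixture coefficient alpha absorbing enrichment bias
toward the taxon the capture baits were designed from.

Calling is deliberately late: haplotypes come from pooled cluster data
(hundreds to thousands of reads per position), which makes the calls
robust to overmerged reads and to low per-sample coverage.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from diplokit.formats import (
    CALLABLE_STATES,
    DIPLOTYPE_STATES,
    NOCALL,
    STATE_INDEX,
    STATES,
    WhitelistEntry,
)
from diplokit.polarity import (
    PolarizedMatrix,
    SampleScore,
    polarize_counts,
    score_sample,
)

log = logging.getLogger(__name__)

_N_IDX = STATE_INDEX["N"]
# Admixture bounds for the heterozygote model.  Capture bias shifts the
# read fraction of a true heterozygote moderately (~0.55 toward the taxon
# the baits came from); leaving alpha free to approach 0 or 1 would let the
# HET model nest both homozygote models and destroy the identifiability of
# the three diplotypes, so the bounds express the biological range of
# enrichment bias.
ALPHA_MIN = 0.1
ALPHA_MAX = 0.9
#: a variant position counts as detected when its G-test p-value is below this
SIG_DETECT = 1e-6


class NoVariantsError(ValueError):
    """No informative position distinguishes the two taxa at this locus."""


@dataclass
class Haplotype:
    """A locus-spanning haplotype as state indices; NOCALL (-1) marks
    positions without a strict-majority state."""

    states: np.ndarray  # (n,) int, values in {0..5} \ {N} or NOCALL

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int16)

    @classmethod
    def from_string(cls, s: str) -> "Haplotype":
        idx = [NOCALL if c == "?" else STATE_INDEX[c if c != "-" else "DEL"] for c in s]
        return cls(np.array(idx, dtype=np.int16))

    def to_string(self) -> str:
        out = []
        for x in self.states:
            if x == NOCALL:
                out.append("?")
            elif STATES[x] == "DEL":
                out.append("-")
            else:
                out.append(STATES[x])
        return "".join(out)

    @property
    def called(self) -> np.ndarray:
        return self.states != NOCALL

    def same_as(self, other: "Haplotype") -> bool:
        """Identical on jointly called positions (and at least one such)."""
        both = self.called & other.called
        if not both.any():
            return False
        return bool(np.array_equal(self.states[both], other.states[both]))

    def __len__(self) -> int:
        return len(self.states)


@dataclass
class Cluster:
    members: List[str]
    pooled_counts: np.ndarray  # (6, n)
    mean_angle: float  # radius-weighted mean angle of members, degrees
    consensus: Optional[Haplotype] = None

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def depth(self) -> int:
        return int(self.pooled_counts.sum())


@dataclass
class ClusterSet:
    """Angular clusters of samples at one locus, sorted by mean angle
    (variegata side first)."""

    clusters: List[Cluster]
    labels: Dict[str, int]  # sample -> index into clusters
    excluded: List[str] = field(default_factory=list)  # radius below r_min

    @property
    def k(self) -> int:
        return len(self.clusters)

    def male_proportions(self, sexes: Mapping[str, str]) -> List[Optional[float]]:
        """Per-cluster proportion of males among sexed F2 members (p_m);
        None when a cluster has no sexed members."""
        out: List[Optional[float]] = []
        for c in self.clusters:
            sexed = [sexes.get(m) for m in c.members]
            sexed = [s for s in sexed if s in ("male", "female")]
            out.append(sum(s == "male" for s in sexed) / len(sexed) if sexed else None)
        return out


@dataclass
class DiplotypeCall:
    state: str  # BbHOM / HET / BvHOM / MISSING
    lnL: Optional[Tuple[float, float, float]] = None  # (BbHOM, HET, BvHOM)
    support: float = 0.0  # lnL_best - lnL_second, ln units
    alpha_hat: Optional[float] = None  # admixture coefficient if HET evaluated
    flags: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.state not in DIPLOTYPE_STATES + ("MISSING",):
            raise ValueError(f"bad diplotype state {self.state!r}")


MISSING_CALL = DiplotypeCall("MISSING")


# ---------------------------------------------------------------------------
# clustering


def _weighted_1d_kmeans(x: np.ndarray, w: np.ndarray, k: int) -> Tuple[np.ndarray, float]:
    """Optimal weighted k-means partition of sorted 1-D data by dynamic
    programming.  Returns (labels in input order, total within-cluster SS)."""
    order = np.argsort(x, kind="stable")
    xs, ws = x[order], w[order]
    n = len(xs)
    cw = np.concatenate([[0.0], np.cumsum(ws)])
    cwx = np.concatenate([[0.0], np.cumsum(ws * xs)])
    cwx2 = np.concatenate([[0.0], np.cumsum(ws * xs * xs)])

    def seg_cost(i: np.ndarray, j: int) -> np.ndarray:
        # cost of segment [i, j] inclusive, vectorized over i
        sw = cw[j + 1] - cw[i]
        swx = cwx[j + 1] - cwx[i]
        swx2 = cwx2[j + 1] - cwx2[i]
        with np.errstate(invalid="ignore", divide="ignore"):
            c = swx2 - np.where(sw > 0, swx * swx / sw, 0.0)
        return np.maximum(c, 0.0)

    dp = np.array([seg_cost(np.array([0]), j)[0] for j in range(n)])
    back = np.zeros((k, n), dtype=int)
    for kk in range(1, k):
        new = np.full(n, np.inf)
        for j in range(kk, n):
            starts = np.arange(kk, j + 1)
            cand = dp[starts - 1] + seg_cost(starts, j)
            best = int(np.argmin(cand))
            new[j] = cand[best]
            back[kk, j] = starts[best]
        dp = new
    # recover boundaries
    labels_sorted = np.zeros(n, dtype=int)
    j = n - 1
    for kk in range(k - 1, 0, -1):
        start = back[kk, j]
        labels_sorted[start : j + 1] = kk
        j = start - 1
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    wss = float(dp[n - 1]) if k > 1 else float(seg_cost(np.array([0]), n - 1)[0])
    return labels, wss


_ANGLE_VAR_FLOOR = 1.0  # deg^2; regularizes the BIC for zero-spread clusters
_SEP_FACTOR = 5.0  # adjacent clusters must sit this many pooled sds apart
_SEP_VAR_FLOOR = 0.04  # deg^2; keeps the separation test finite
_SEP_MIN_DEG = 8.0  # clusters closer than this are one diplotype group


def _well_separated(x: np.ndarray, w: np.ndarray, labels: np.ndarray, k: int) -> bool:
    """True when every pair of adjacent cluster means is far apart both
    relative to the within-cluster spread and in absolute degrees.

    Splitting a single unimodal blob produces halves whose means differ by
    ~1.6 within-sds, so genuine groups must sit several sds apart.  The
    absolute floor reflects the geometry: distinct diplotype groups of a
    haplotype pair differ by tens of degrees, and groups closer than a few
    degrees (e.g. carriers of a dominant sex-limited haplotype whose other
    allele barely moves them) belong together for every downstream purpose.
    """
    stats = []
    for c in range(k):
        sel = labels == c
        mu = float(np.average(x[sel], weights=w[sel]))
        var = float(np.average((x[sel] - mu) ** 2, weights=w[sel]))
        stats.append((mu, var, float(w[sel].sum())))
    stats.sort()
    for (m1, v1, w1), (m2, v2, w2) in zip(stats, stats[1:]):
        pooled = (w1 * v1 + w2 * v2) / (w1 + w2) + _SEP_VAR_FLOOR
        if (m2 - m1) < max(_SEP_FACTOR * np.sqrt(pooled), _SEP_MIN_DEG):
            return False
    return True


def _select_k(x: np.ndarray, w: np.ndarray, k_max: int) -> Tuple[int, np.ndarray]:
    """Pick the number of angular clusters by BIC under a shared-variance
    Gaussian model (radius-weighted), k in 1..k_max, subject to the
    separation criterion of :func:`_well_separated`."""
    n = len(x)
    k_max = min(k_max, n)
    wsum = float(w.sum())
    best = None
    for k in range(1, k_max + 1):
        labels, wss = _weighted_1d_kmeans(x, w, k)
        if len(np.unique(labels)) < k:
            continue  # fewer distinct points than clusters
        if k > 1 and not _well_separated(x, w, labels, k):
            continue
        sigma2 = wss / wsum + _ANGLE_VAR_FLOOR
        bic = n * np.log(sigma2) + 2.0 * k * np.log(n)
        if best is None or bic < best[0] - 1e-12:
            best = (bic, k, labels)
    assert best is not None
    return best[1], best[2]


def cluster_scores(
    scores: Mapping[str, SampleScore],
    counts: Mapping[str, np.ndarray],
    r_min_frac: float = 0.05,
    k_max: int = 6,
) -> ClusterSet:
    """Cluster samples by angle in the (v, b) plane, weighted by radius.

    Samples with radius below ``r_min_frac`` of the locus maximum are kept
    out of the cluster statistics (they sit near the origin and carry little
    signal) but remain available for likelihood calling.  More than three
    clusters can form when more than two haplotypes segregate.
    """
    radii = {s: sc.radius for s, sc in scores.items()}
    rmax = max(radii.values(), default=0.0)
    if rmax == 0.0:
        raise NoVariantsError("all samples score at the origin")
    usable = [s for s, r in radii.items() if r > 0 and r >= r_min_frac * rmax]
    excluded = [s for s in scores if s not in usable]
    if len(usable) < 5:
        raise NoVariantsError(f"only {len(usable)} samples with usable radius")
    x = np.array([scores[s].angle for s in usable])
    w = np.array([radii[s] for s in usable])
    k, labels = _select_k(x, w, k_max)

    clusters: List[Cluster] = []
    for ci in range(k):
        members = [s for s, lab in zip(usable, labels) if lab == ci]
        pooled = sum(
            (np.asarray(counts[m], dtype=np.int64) for m in members),
        )
        ang = float(np.average([scores[m].angle for m in members],
                               weights=[radii[m] for m in members]))
        clusters.append(Cluster(members, pooled, ang))
    order = np.argsort([c.mean_angle for c in clusters], kind="stable")
    clusters = [clusters[i] for i in order]
    label_map = {s: i for i, c in enumerate(clusters) for s in c.members}
    return ClusterSet(clusters, label_map, excluded)


def update_polarized_matrix(clusters: ClusterSet) -> PolarizedMatrix:
    """Rebuild M_p from the pooled counts of the two clusters closest to the
    coordinate axes — the purest variegata (near 0 deg) and bombina (near
    90 deg) individuals — recomputing the per-position G-test weights on
    these high-coverage pools.  Angle ties break toward larger pooled depth.
    """
    if clusters.k < 2:
        raise ValueError("need at least two clusters to update the matrix")

    def nearest(target: float) -> Cluster:
        key = lambda c: (abs(c.mean_angle - target), -c.depth)
        return min(clusters.clusters, key=key)

    bv, bb = nearest(0.0), nearest(90.0)
    if bv is bb:  # degenerate geometry; fall back to extreme clusters
        bv = clusters.clusters[0]
        bb = clusters.clusters[-1]
    return polarize_counts(bv.pooled_counts, bb.pooled_counts, source="updated_clusters")


def contamination_mask(
    clusters: ClusterSet,
    angle_tol: float = 37.0,
    max_minor_frac: float = 0.2,
    min_depth: int = 20,
) -> np.ndarray:
    """Boolean keep-mask over columns, from the pooled axis clusters.

    Overmerged (mis-mapped) reads hit every sample at a locus, so they show
    up as a substantial minor state even in the pooled reads of the
    homozygote clusters sitting on the coordinate axes, where sequencing
    error alone predicts near-purity.  Columns where either axis pool's
    minor-state fraction exceeds ``max_minor_frac`` are dropped from the
    likelihood model; this is what makes the diplotype calls robust to
    contamination that happens to coincide with a diagnostic position.
    Pools are only trusted when their cluster sits within ``angle_tol``
    degrees of its axis — clearly nearer the axis than the heterozygote
    diagonal, since contamination itself drags homozygote clusters inward.
    """
    n = clusters.clusters[0].pooled_counts.shape[1]
    keep = np.ones(n, dtype=bool)
    for target in (0.0, 90.0):
        c = min(clusters.clusters, key=lambda c: (abs(c.mean_angle - target), -c.depth))
        if abs(c.mean_angle - target) > angle_tol:
            continue
        pooled = c.pooled_counts
        depth = pooled.sum(axis=0)
        major = pooled.max(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            minor_frac = np.where(depth > 0, 1.0 - major / np.maximum(depth, 1), 0.0)
        keep &= ~((depth >= min_depth) & (minor_frac > max_minor_frac))
    return keep


def _masked(hap: Haplotype, keep: Optional[np.ndarray]) -> Haplotype:
    if keep is None:
        return hap
    states = hap.states.copy()
    states[~keep] = NOCALL
    return Haplotype(states)


def consensus_haplotype(pooled_counts: np.ndarray, z_margin: float = 3.0) -> Haplotype:
    """Strict-majority consensus: per column, the state carried by more than
    half the reads; ties, zero depth, and N-majorities give NOCALL.

    The majority must clear 50% by ``z_margin`` binomial standard
    deviations: a 50:50 column in a deep pool (two haplotypes mixed in the
    contributing samples) would otherwise get an arbitrary call from
    sampling noise, and such phantom states corrupt the likelihood model.
    """
    pooled = np.asarray(pooled_counts, dtype=np.int64)
    depth = pooled.sum(axis=0)
    best = pooled.argmax(axis=0)
    lead = 2 * pooled[best, np.arange(pooled.shape[1])] - depth
    strict = (lead > 0) & (lead > z_margin * np.sqrt(depth))
    states = np.where(strict & (depth > 0) & (best != _N_IDX), best, NOCALL)
    return Haplotype(states.astype(np.int16))


# ---------------------------------------------------------------------------
# likelihood


def _pair_suffstats(
    stack: np.ndarray, hap_bv: Haplotype, hap_bb: Haplotype
) -> Optional[dict]:
    """Sufficient statistics of the error model for a haplotype pair.

    Under the model every unmasked column's expected distribution depends
    only on whether a read matches the variegata state, the bombina state,
    or neither, so the log-likelihoods reduce to a handful of totals per
    sample.  Returns None when no column is called in both haplotypes.
    """
    a, b = hap_bv.states, hap_bb.states
    mask = (a != NOCALL) & (b != NOCALL)
    if not mask.any():
        return None
    cols = np.flatnonzero(mask)
    eq = cols[a[cols] == b[cols]]
    diff = cols[a[cols] != b[cols]]
    S = stack.shape[0]
    tot = stack[:, :, cols].sum(axis=(1, 2)).astype(float)
    match_a = stack[:, a[cols], cols].sum(axis=1).astype(float)
    match_b = stack[:, b[cols], cols].sum(axis=1).astype(float)
    if len(eq):
        tot_eq = stack[:, :, eq].sum(axis=(1, 2)).astype(float)
        match_eq = stack[:, a[eq], eq].sum(axis=1).astype(float)
    else:
        tot_eq = np.zeros(S)
        match_eq = np.zeros(S)
    if len(diff):
        ca = stack[:, a[diff], diff].sum(axis=1).astype(float)
        cb = stack[:, b[diff], diff].sum(axis=1).astype(float)
        tot_diff = stack[:, :, diff].sum(axis=(1, 2)).astype(float)
    else:
        ca = cb = tot_diff = np.zeros(S)
    return dict(
        tot=tot, match_a=match_a, match_b=match_b,
        tot_eq=tot_eq, match_eq=match_eq,
        ca=ca, cb=cb, tot_diff=tot_diff, n_cols=len(cols),
    )


def _hom_lnl(tot: np.ndarray, match: np.ndarray, epsilon: float) -> np.ndarray:
    p, q = np.log(1.0 - epsilon), np.log(epsilon / 5.0)
    return match * p + (tot - match) * q


def _het_lnl(ss: dict, epsilon: float) -> Tuple[np.ndarray, np.ndarray]:
    """Vector of heterozygote log-likelihoods maximized over the admixture
    coefficient alpha in [ALPHA_MIN, ALPHA_MAX], plus alpha-hat.

    Across differing columns the mixture probability of the variegata state
    is alpha(1-e) + (1-alpha)e/5 and of the bombina state the mirror image,
    so the alpha-profile likelihood has the closed-form maximizer
    alpha* = (Ca(1-e) - Cb e/5) / ((Ca+Cb)((1-e) - e/5)), clipped to the
    bounds (the objective is concave in alpha).
    """
    p, q = 1.0 - epsilon, epsilon / 5.0
    ca, cb = ss["ca"], ss["cb"]
    denom = (ca + cb) * (p - q)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(denom > 0, (ca * p - cb * q) / denom, 0.5)
    alpha = np.clip(alpha, ALPHA_MIN, ALPHA_MAX)
    pv = alpha * p + (1.0 - alpha) * q
    pb = alpha * q + (1.0 - alpha) * p
    lnl = (
        ca * np.log(pv)
        + cb * np.log(pb)
        + (ss["tot_diff"] - ca - cb) * np.log(q)
        + _hom_lnl(ss["tot_eq"], ss["match_eq"], epsilon)
    )
    return lnl, alpha


def _triple_lnl(ss: dict, epsilon: float) -> Tuple[np.ndarray, np.ndarray]:
    """(S, 3) log-likelihoods in (BbHOM, HET, BvHOM) order, plus alpha-hat."""
    bb = _hom_lnl(ss["tot"], ss["match_b"], epsilon)
    bv = _hom_lnl(ss["tot"], ss["match_a"], epsilon)
    het, alpha = _het_lnl(ss, epsilon)
    return np.column_stack([bb, het, bv]), alpha


def diplotype_loglik(
    counts: np.ndarray,
    hap_bv: Haplotype,
    hap_bb: Haplotype,
    state: str,
    epsilon: float = 0.005,
) -> Tuple[float, Optional[float]]:
    """ln-likelihood of one sample's counts under one diplotype state.

    Columns where either haplotype is NOCALL are masked.  Reads follow the
    column's expected distribution pi(x) = sum_h mu(h) [(1-e) if x = h else
    e/5]: mu is a point mass on the haplotype state for a homozygote, and
    the alpha : (1-alpha) mixture of the two taxon states for a heterozygote
    (alpha returned as the second element; None for homozygotes).
    """
    if not 0.0 < epsilon < 0.5:
        raise ValueError("epsilon must be in (0, 0.5)")
    stack = np.asarray(counts, dtype=np.int64)[None, :, :]
    ss = _pair_suffstats(stack, hap_bv, hap_bb)
    if ss is None:
        raise ValueError("all columns masked: likelihood undefined")
    if state == "HET":
        lnl, alpha = _het_lnl(ss, epsilon)
        return float(lnl[0]), float(alpha[0])
    if state == "BvHOM":
        return float(_hom_lnl(ss["tot"], ss["match_a"], epsilon)[0]), None
    if state == "BbHOM":
        return float(_hom_lnl(ss["tot"], ss["match_b"], epsilon)[0]), None
    raise ValueError(f"unknown diplotype state {state!r}")


# ---------------------------------------------------------------------------
# coestimation


@dataclass
class LocusResult:
    locus_id: str
    calls: Dict[str, DiplotypeCall]
    hap_bv: Optional[Haplotype] = None
    hap_bb: Optional[Haplotype] = None
    pair_support: float = 0.0
    clusters: Optional[ClusterSet] = None
    scores: Optional[Dict[str, SampleScore]] = None
    mp: Optional[PolarizedMatrix] = None
    flags: Tuple[str, ...] = ()


def _call_samples(
    stack: np.ndarray,
    sample_ids: Sequence[str],
    hap_bv: Haplotype,
    hap_bb: Haplotype,
    epsilon: float,
) -> Tuple[Dict[str, DiplotypeCall], float]:
    ss = _pair_suffstats(stack, hap_bv, hap_bb)
    if ss is None:
        return {s: MISSING_CALL for s in sample_ids}, -np.inf
    lnl, alpha = _triple_lnl(ss, epsilon)
    order = np.argsort(lnl, axis=1)
    total = 0.0
    calls: Dict[str, DiplotypeCall] = {}
    for i, s in enumerate(sample_ids):
        if ss["tot"][i] == 0:
            calls[s] = DiplotypeCall("MISSING", flags=("low_depth",))
            continue
        best, second = order[i, 2], order[i, 1]
        state = DIPLOTYPE_STATES[best]
        calls[s] = DiplotypeCall(
            state=state,
            lnL=tuple(float(v) for v in lnl[i]),
            support=float(lnl[i, best] - lnl[i, second]),
            alpha_hat=float(alpha[i]),
        )
        total += float(lnl[i, best])
    return calls, total


def _pair_total(stack: np.ndarray, ss: Optional[dict], epsilon: float) -> float:
    if ss is None:
        return -np.inf
    lnl, _ = _triple_lnl(ss, epsilon)
    active = ss["tot"] > 0
    return float(lnl[active].max(axis=1).sum()) if active.any() else -np.inf


@dataclass
class CoestimateResult:
    hap_bv: Haplotype
    hap_bb: Haplotype
    calls: Dict[str, DiplotypeCall]
    pair_support: float
    flags: Tuple[str, ...] = ()


def coestimate_locus(
    counts_by_sample: Mapping[str, np.ndarray],
    candidates: Sequence[Tuple[Haplotype, float]],
    pedigree=None,
    epsilon: float = 0.005,
    refine: bool = True,
    keep_mask: Optional[np.ndarray] = None,
) -> CoestimateResult:
    """Coestimate the ML taxon-haplotype pair and all samples' diplotypes.

    ``candidates`` are (haplotype, source-cluster mean angle) tuples.  Every
    distinct unordered pair is scored by the summed best-state
    ln-likelihood over all samples with data; the member nearer the 0-deg
    (variegata) axis is taken as the variegata haplotype, with an angle tie
    resolved by trying both orientations.  ``pair_support`` is the total
    score margin of the winning pair over the runner-up.

    After calling, each taxon haplotype is refined once from the pooled
    counts of all samples called homozygous for it (a far deeper pool than
    any single cluster) and every sample is recalled.
    """
    sample_ids = list(counts_by_sample)
    stack = np.stack([np.asarray(counts_by_sample[s]) for s in sample_ids])

    # collapse redundant candidates: a haplotype that agrees with a kept one
    # on every jointly called position and calls no position the kept one
    # lacks adds nothing (subclusters of one diplotype group, or an
    # uninformative heterozygote-pool consensus); when the newcomer is the
    # more complete of the two it replaces the kept one
    distinct: List[Tuple[Haplotype, float]] = []
    for ha, anga in candidates:
        ha = _masked(ha, keep_mask)
        if not ha.called.any():
            continue
        redundant = False
        for i, (hb, angb) in enumerate(distinct):
            if not ha.same_as(hb):
                continue
            if not (ha.called & ~hb.called).any():
                redundant = True
                break
            if not (hb.called & ~ha.called).any():
                distinct[i] = (ha, anga)
                redundant = True
                break
        if not redundant:
            distinct.append((ha, anga))

    oriented: List[Tuple[Haplotype, Haplotype]] = []
    for (ha, anga), (hb, angb) in itertools.combinations(distinct, 2):
        if ha.same_as(hb):
            continue
        if anga < angb:
            oriented.append((ha, hb))
        elif angb < anga:
            oriented.append((hb, ha))
        else:
            oriented.append((ha, hb))
            oriented.append((hb, ha))
    if not oriented:
        raise UnresolvableLocusError("no distinct candidate haplotype pair")

    totals = [
        _pair_total(stack, _pair_suffstats(stack, a, b), epsilon) for a, b in oriented
    ]
    ranked = sorted(range(len(oriented)), key=lambda i: totals[i], reverse=True)
    best_i = ranked[0]
    pair_support = (
        totals[best_i] - totals[ranked[1]] if len(ranked) > 1 else float("inf")
    )
    hap_bv, hap_bb = oriented[best_i]
    calls, _ = _call_samples(stack, sample_ids, hap_bv, hap_bb, epsilon)

    if refine:
        hap_bv = _refined(stack, sample_ids, calls, "BvHOM", hap_bv, keep_mask)
        hap_bb = _refined(stack, sample_ids, calls, "BbHOM", hap_bb, keep_mask)
        if hap_bv.same_as(hap_bb):
            # refinement collapsed the pair; keep the original haplotypes
            hap_bv, hap_bb = oriented[best_i]
        calls, _ = _call_samples(stack, sample_ids, hap_bv, hap_bb, epsilon)

    flags: Tuple[str, ...] = ()
    if pedigree is not None:
        expected = {pedigree.grandsire: "BvHOM", pedigree.granddam: "BbHOM",
                    pedigree.f1_father: "HET"}
        for m in pedigree.f1_mothers:
            expected[m] = "HET"
        bad = [
            s for s, exp in expected.items()
            if s in calls and calls[s].state not in ("MISSING", exp)
        ]
        if bad:
            flags = ("expected_F0F1_pattern_violated",)
    return CoestimateResult(hap_bv, hap_bb, calls, pair_support, flags)


class UnresolvableLocusError(ValueError):
    """Fewer than two distinct candidate haplotypes at a locus."""


def _refined(
    stack: np.ndarray,
    sample_ids: Sequence[str],
    calls: Mapping[str, DiplotypeCall],
    state: str,
    fallback: Haplotype,
    keep_mask: Optional[np.ndarray] = None,
) -> Haplotype:
    idx = [i for i, s in enumerate(sample_ids) if calls[s].state == state]
    if not idx:
        return fallback
    hap = _masked(consensus_haplotype(stack[idx].sum(axis=0)), keep_mask)
    return hap if hap.called.any() else fallback


def rescore_with_whitelist(
    counts_by_sample: Mapping[str, np.ndarray],
    entries: Sequence[WhitelistEntry],
    epsilon: float = 0.005,
) -> Dict[str, DiplotypeCall]:
    """Recall all samples from manually annotated diagnostic variants.

    The same likelihood machinery runs restricted to the whitelisted
    columns, with the taxon haplotypes defined by the annotated
    (variegata-state, bombina-state) pairs.  Samples with no reads at any
    whitelisted column are MISSING.
    """
    if not entries:
        raise ValueError("whitelist for this locus is empty")
    sample_ids = list(counts_by_sample)
    n = np.asarray(counts_by_sample[sample_ids[0]]).shape[1]
    bv = np.full(n, NOCALL, dtype=np.int16)
    bb = np.full(n, NOCALL, dtype=np.int16)
    for e in entries:
        if e.position > n:
            raise ValueError(f"whitelist position {e.position} beyond locus length {n}")
        bv[e.position - 1] = STATE_INDEX[e.state_bv]
        bb[e.position - 1] = STATE_INDEX[e.state_bb]
    stack = np.stack([np.asarray(counts_by_sample[s]) for s in sample_ids])
    calls, _ = _call_samples(stack, sample_ids, Haplotype(bv), Haplotype(bb), epsilon)
    return calls


# ---------------------------------------------------------------------------
# per-locus driver


@dataclass
class CallerConfig:
    epsilon: float = 0.005
    r_min_frac: float = 0.05
    k_max: int = 6
    refine: bool = True


def diplotype_locus(
    locus_id: str,
    counts_by_sample: Mapping[str, np.ndarray],
    pedigree=None,
    config: Optional[CallerConfig] = None,
    grandsire: Optional[str] = None,
    granddam: Optional[str] = None,
) -> LocusResult:
    """Run the full caller for one locus.

    Steps: polarize on the two F0 grandparents, score and cluster all
    samples, update the polarized matrix from the two axis clusters and
    re-cluster once, take strict-majority cluster consensuses as candidate
    haplotypes, then coestimate the ML pair and all diplotypes.
    """
    cfg = config or CallerConfig()
    if pedigree is not None:
        grandsire = grandsire or pedigree.grandsire
        granddam = granddam or pedigree.granddam
    if grandsire is None or granddam is None:
        raise ValueError("grandsire and granddam sample ids are required")

    def _missing(flag: str) -> LocusResult:
        calls = {s: DiplotypeCall("MISSING", flags=(flag,)) for s in counts_by_sample}
        return LocusResult(locus_id, calls, flags=(flag,))

    mp = polarize_counts(counts_by_sample[grandsire], counts_by_sample[granddam])
    # a locus has detectable variation only if some column's G-test is
    # decisively significant; scattered sequencing errors give mid-range
    # weights but never approach weight 1 at realistic depth
    if not (mp.weights > 1.0 - SIG_DETECT).any():
        return _missing("no_variants")

    def _score_all(m: PolarizedMatrix) -> Dict[str, SampleScore]:
        return {s: score_sample(c, m) for s, c in counts_by_sample.items()}

    scores = _score_all(mp)
    try:
        clusters = cluster_scores(scores, counts_by_sample, cfg.r_min_frac, cfg.k_max)
    except NoVariantsError:
        return _missing("no_variants")

    if clusters.k >= 2:
        # one high-coverage update of M_p from the axis-cluster pools,
        # accepted only if the re-clustering keeps at least as many
        # separated groups (a within-taxon haplotype, e.g. a diverged
        # sex-limited one, can scramble the updated polarization)
        mp2 = update_polarized_matrix(clusters)
        if mp2.informative.any():
            scores2 = _score_all(mp2)
            try:
                clusters2 = cluster_scores(
                    scores2, counts_by_sample, cfg.r_min_frac, cfg.k_max
                )
            except NoVariantsError:
                clusters2 = None
            if clusters2 is not None and clusters2.k >= clusters.k:
                mp, scores, clusters = mp2, scores2, clusters2

    # deepest pools first, so candidate deduplication keeps the consensus
    # with the most supporting reads
    candidates: List[Tuple[Haplotype, float]] = []
    for c in sorted(clusters.clusters, key=lambda c: -c.depth):
        c.consensus = consensus_haplotype(c.pooled_counts)
        if c.consensus.called.any():
            candidates.append((c.consensus, c.mean_angle))
    keep = contamination_mask(clusters)
    try:
        co = coestimate_locus(
            counts_by_sample, candidates, pedigree, cfg.epsilon, cfg.refine,
            keep_mask=keep,
        )
    except UnresolvableLocusError:
        res = _missing("unresolvable")
        res.clusters = clusters
        res.scores = scores
        res.mp = mp
        return res
    return LocusResult(
        locus_id,
        co.calls,
        hap_bv=co.hap_bv,
        hap_bb=co.hap_bb,
        pair_support=co.pair_support,
        clusters=clusters,
        scores=scores,
        mp=mp,
        flags=co.flags,
    )


def run_pipeline(
    sync, pedigree, config: Optional[CallerConfig] = None
) -> Dict[str, LocusResult]:
    """Diplotype every locus of a :class:`~diplokit.formats.SyncData`."""
    results: Dict[str, LocusResult] = {}
    for locus in sync.loci:
        arr = sync.locus_array(locus)
        counts = {s: arr[i] for i, s in enumerate(sync.sample_ids)}
        results[locus] = diplotype_locus(locus, counts, pedigree, config)
    return results


def calls_of(results: Mapping[str, LocusResult]) -> Dict[str, Dict[str, DiplotypeCall]]:
    """Extract the {locus: {sample: call}} mapping the writers expect."""
    return {locus: res.calls for locus, res in results.items()}


def flagged_queue(results: Mapping[str, LocusResult]) -> List[str]:
    """Loci whose F0/F1 calls violate the expected (BvHOM, BbHOM, HET...)
    pattern — the queue for the manual-annotation rescoring path."""
    return [
        locus for locus, r in results.items()
        if "expected_F0F1_pattern_violated" in r.flags
    ]
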