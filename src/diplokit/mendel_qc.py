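"""Segregation-distortion statistics and the reduced-map bin filter.

In an F2 intercross, autosomal diplotypes segregate 1:2:1
(BbHOM : HET : BvHOM).  Each locus x family is tested with a chi-square
goodness-of-fit (df 2) on the non-missing F2 calls.  Two significance
thresholds are applied: a genome-wise Bonferroni correction dividing alpha
by the number of chromosome arms (lower threshold), and the
Benjamini-Hochberg step-up FDR across all locus x family tests (upper
threshold).

The bin filter validates map robustness: among loci mapped to the same cM
position (a bin), pairwise diplotype differences across the F2s should be
tiny.  Loci whose pairwise differences exceed three are removed greedily
and one survivor per bin is picked at random to build a one-locus-per-bin
reduced dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from diplokit.formats import MapTable, PedigreeTable


@dataclass
class SegregationRecord:
    locus_id: str
    family: object
    counts: Tuple[int, int, int]  # (n_BbHOM, n_HET, n_BvHOM)
    chi2: float
    p_value: float
    exceeds_bonferroni: bool = False
    exceeds_bh: bool = False

    @property
    def n(self) -> int:
        return sum(self.counts)


def segregation_chisq(
    locus_id: str,
    locus_calls: Mapping[str, object],
    pedigree: PedigreeTable,
) -> List[SegregationRecord]:
    """Chi-square (df 2) against 1:2:1 per F2 family; MISSING excluded.

    ``locus_calls`` maps sample id to either a DiplotypeCall or a bare
    state string.  Families with no informative calls get NaN statistics.
    """
    records = []
    for fam in pedigree.families:
        tally = {"BbHOM": 0, "HET": 0, "BvHOM": 0}
        for s in pedigree.offspring_of_family(fam):
            call = locus_calls.get(s)
            state = getattr(call, "state", call)
            if state in tally:
                tally[state] += 1
        counts = (tally["BbHOM"], tally["HET"], tally["BvHOM"])
        n = sum(counts)
        if n == 0:
            records.append(
                SegregationRecord(locus_id, fam, counts, float("nan"), float("nan"))
            )
            continue
        expected = np.array([n / 4.0, n / 2.0, n / 4.0])
        chi2 = float(((np.array(counts) - expected) ** 2 / expected).sum())
        p = float(stats.chi2.sf(chi2, df=2))
        records.append(SegregationRecord(locus_id, fam, counts, chi2, p))
    return records


def bonferroni_critical_chi2(alpha: float = 0.05, n_arms: int = 24) -> float:
    """Chi-square (df 2) critical value at the per-test level alpha/n_arms.

    With df 2 the survival function is exp(-x/2), so the critical value is
    -2 ln(alpha / n_arms) in closed form.
    """
    return float(stats.chi2.isf(alpha / n_arms, df=2))


def significance_thresholds(
    records: Sequence[SegregationRecord],
    n_arms: int = 24,
    alpha: float = 0.05,
) -> List[SegregationRecord]:
    """Flag records against the two thresholds (in place; returns records).

    Lower threshold: chi2 above the df-2 critical value at alpha/n_arms
    (Bonferroni over chromosome arms).  Upper threshold: Benjamini-Hochberg
    step-up over all locus x family p-values at experiment-wise alpha.
    """
    crit = bonferroni_critical_chi2(alpha, n_arms)
    valid = [r for r in records if np.isfinite(r.p_value)]
    for r in records:
        r.exceeds_bonferroni = bool(np.isfinite(r.chi2) and r.chi2 > crit)
        r.exceeds_bh = False
    if valid:
        pvals = np.array([r.p_value for r in valid])
        m = len(pvals)
        order = np.argsort(pvals, kind="stable")
        thresh = alpha * (np.arange(1, m + 1)) / m
        passed = pvals[order] <= thresh
        if passed.any():
            kmax = int(np.max(np.flatnonzero(passed)))
            for idx in order[: kmax + 1]:
                valid[int(idx)].exceeds_bh = True
    return list(records)


# ---------------------------------------------------------------------------
# bin reduction


@dataclass
class BinReduction:
    bin_id: Tuple[int, float]  # (LG, cM)
    members: List[str]
    diff_matrix: np.ndarray  # pairwise F2 call differences among members
    removed: List[str] = field(default_factory=list)
    selected: Optional[str] = None
    seed: Optional[int] = None

    @property
    def survivors(self) -> List[str]:
        return [m for m in self.members if m not in self.removed]


def _pairwise_differences(
    loci: Sequence[str],
    calls: Mapping[str, Mapping[str, object]],
    offspring: Sequence[str],
) -> np.ndarray:
    """Counts of F2 individuals with unequal non-missing calls per locus
    pair; pairs with a MISSING member are skipped."""
    k = len(loci)
    states = []
    for locus in loci:
        lc = calls.get(locus, {})
        states.append(
            [getattr(lc.get(s), "state", lc.get(s)) for s in offspring]
        )
    diff = np.zeros((k, k), dtype=int)
    valid_states = ("BbHOM", "HET", "BvHOM")
    for i in range(k):
        for j in range(i + 1, k):
            d = sum(
                1
                for a, b in zip(states[i], states[j])
                if a in valid_states and b in valid_states and a != b
            )
            diff[i, j] = diff[j, i] = d
    return diff


def reduce_bins(
    map_table: MapTable,
    calls: Mapping[str, Mapping[str, object]],
    pedigree: PedigreeTable,
    seed: int,
    max_diff: int = 3,
    exclude: Optional[Sequence[str]] = None,
) -> Tuple[List[BinReduction], List[str]]:
    """Build the one-locus-per-bin reduced dataset.

    ``exclude`` lists loci already removed for excess segregation
    distortion.  Within each remaining bin the pairwise F2 diplotype
    differences are computed; while any pair differs at more than
    ``max_diff`` individuals, the locus with the largest summed differences
    is dropped (ties break on locus id for determinism).  One survivor per
    bin is then picked uniformly at random; singleton bins pass through.
    """
    rng = np.random.default_rng(seed)
    excluded = set(exclude or ())
    offspring = pedigree.offspring
    reductions: List[BinReduction] = []
    reduced: List[str] = []
    for (lg, cm), members in map_table.bins():
        members = [m for m in members if m not in excluded]
        if not members:
            continue
        diff = _pairwise_differences(members, calls, offspring)
        red = BinReduction((lg, cm), list(members), diff.copy(), seed=seed)
        active = list(range(len(members)))
        while len(active) >= 2:
            sub = diff[np.ix_(active, active)]
            if sub.max() <= max_diff:
                break
            sums = sub.sum(axis=1)
            worst = max(
                range(len(active)),
                key=lambda i: (sums[i], members[active[i]]),
            )
            red.removed.append(members[active[worst]])
            del active[worst]
        survivors = [members[i] for i in active]
        if not survivors:
            continue
        red.selected = survivors[int(rng.integers(len(survivors)))]
        reductions.append(red)
        reduced.append(red.selected)
    return reductions, reduced
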