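"""Locating the sex-determining (SD) region and inferring heterogamety.

The cross direction (variegata grandsire x bombina granddam) taxon-labels
the sex haplotypes of the heterogametic F1 parent.  Under an XY system the
F1 father passes the variegata-labeled Y to his sons and the
bombina-labeled X to his daughters, so at the SD locus F2 males can only be
BvHOM or HET and F2 females only BbHOM or HET — the same holds under ZW.
The sex-homozygote bias

    b = (N[male BbHOM] + N[female BvHOM]) / N[HOM]

is therefore ~0.5 at autosomal loci (equal sex ratio, no heterozygote
deficit) and 0 at the SD locus; its global minimum along the linkage map
locates the SD region.  Which sex is heterogametic is inferred separately:
a sufficiently diverged sex-limited haplotype (Y or W) forms an extra,
strongly sex-biased cluster in the score plane, flagged by the
cluster-sex statistics pMaleInMaleClusters / pFemaleInFemaleClusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from diplokit.diplotyper import ClusterSet
from diplokit.formats import MapTable


@dataclass
class SexScanRecord:
    locus_id: str
    linkage_group: Optional[int] = None
    position_cM: Optional[float] = None
    n_hom: int = 0
    b: float = float("nan")
    p_binomial: float = float("nan")
    p_male_in_male_clusters: float = float("nan")
    p_female_in_female_clusters: float = float("nan")
    # number of clusters in each statistic's minimal prefix; 1 marks the
    # sex-limited-haplotype signature (one cluster holds most of that sex)
    male_prefix_size: int = 0
    female_prefix_size: int = 0
    # mean angle (deg) of each side's top-ranked cluster; carriers of a
    # sex-limited haplotype are obligate heterozygotes and sit off-axis
    male_top_angle: float = float("nan")
    female_top_angle: float = float("nan")


@dataclass
class HeterogametyReport:
    verdict: str  # XY / ZW / inconclusive
    sd_linkage_group: Optional[int] = None
    sd_interval_cM: Optional[Tuple[float, float]] = None
    minimum_locus: Optional[str] = None
    minimum_b: float = float("nan")
    minimum_p: float = float("nan")
    male_outliers: Sequence[str] = ()
    female_outliers: Sequence[str] = ()


def _state_of(call) -> Optional[str]:
    return getattr(call, "state", call)


def sex_homozygote_bias(
    locus_calls: Mapping[str, object], sexes: Mapping[str, str]
) -> Tuple[float, int, float]:
    """(b, n_hom, one-sided binomial p) for one locus.

    Only samples sexed male/female count (uncertain/unknown excluded).  The
    p-value is the exact lower tail P(X <= k | n_hom, 1/2) with
    k = N[male BbHOM] + N[female BvHOM]: the SD signal is exclusively a
    deficit of these two sex-homozygote combinations.
    """
    k = 0
    n_hom = 0
    for s, sex in sexes.items():
        if sex not in ("male", "female"):
            continue
        state = _state_of(locus_calls.get(s))
        if state not in ("BbHOM", "BvHOM"):
            continue
        n_hom += 1
        if (sex == "male" and state == "BbHOM") or (sex == "female" and state == "BvHOM"):
            k += 1
    if n_hom == 0:
        return float("nan"), 0, float("nan")
    b = k / n_hom
    p = float(stats.binom.cdf(k, n_hom, 0.5))
    return b, n_hom, p


def _prefix_stat(
    proportions: Sequence[Optional[float]], totals: Sequence[int], want: str
) -> float:
    """Mean cluster-wise proportion of ``want`` over the minimal prefix of
    clusters (ranked by that proportion, descending) jointly holding more
    than half of all ``want`` individuals."""
    props = []
    counts = []
    orig = []
    for ci, (p, t) in enumerate(zip(proportions, totals)):
        if p is None:
            continue
        props.append(p if want == "male" else 1.0 - p)
        counts.append(t)
        orig.append(ci)
    if not props:
        return float("nan"), 0, -1
    n_want = sum(p * t for p, t in zip(props, counts))
    if n_want == 0:
        return float("nan"), 0, -1
    order = sorted(range(len(props)), key=lambda i: props[i], reverse=True)
    got = 0.0
    chosen: List[int] = []
    for i in order:
        chosen.append(i)
        got += props[i] * counts[i]
        if got > 0.5 * n_want:
            break
    return float(np.mean([props[i] for i in chosen])), len(chosen), orig[chosen[0]]


def cluster_sex_stats(
    clusters: ClusterSet, sexes: Mapping[str, str]
) -> Tuple[float, float]:
    """(pMaleInMaleClusters, pFemaleInFemaleClusters) for one locus.

    Clusters are ranked by their proportion of males p_m (computed over
    sexed F2 members); the statistic is the unweighted mean p_m of the
    minimal descending prefix whose clusters jointly contain more than 50%
    of all males.  The female statistic is the mirror image.  At an
    autosomal locus every cluster sits near p_m = 0.5 and both statistics
    are ~0.5; a sex-limited haplotype cluster drives one of them toward 1.
    """
    pm, _, _, pf, _, _ = cluster_sex_stats_full(clusters, sexes)
    return pm, pf


def cluster_sex_stats_full(
    clusters: ClusterSet, sexes: Mapping[str, str]
) -> Tuple[float, int, float, float, int, float]:
    """As :func:`cluster_sex_stats`, also returning each statistic's
    minimal-prefix size and the top-ranked cluster's mean angle."""
    pm = clusters.male_proportions(sexes)
    totals = [
        sum(1 for m in c.members if sexes.get(m) in ("male", "female"))
        for c in clusters.clusters
    ]
    m_stat, m_k, m_top = _prefix_stat(pm, totals, "male")
    f_stat, f_k, f_top = _prefix_stat(pm, totals, "female")
    m_ang = clusters.clusters[m_top].mean_angle if m_top >= 0 else float("nan")
    f_ang = clusters.clusters[f_top].mean_angle if f_top >= 0 else float("nan")
    return m_stat, m_k, m_ang, f_stat, f_k, f_ang


def scan_records(
    calls: Mapping[str, Mapping[str, object]],
    sexes: Mapping[str, str],
    map_table: Optional[MapTable] = None,
    cluster_sets: Optional[Mapping[str, ClusterSet]] = None,
) -> List[SexScanRecord]:
    """Per-locus SD statistics across the dataset."""
    records = []
    for locus, locus_calls in calls.items():
        rec = SexScanRecord(locus)
        if map_table is not None:
            try:
                rec.linkage_group, rec.position_cM = map_table.position_of(locus)
            except KeyError:
                pass
        rec.b, rec.n_hom, rec.p_binomial = sex_homozygote_bias(locus_calls, sexes)
        if cluster_sets is not None and locus in cluster_sets:
            cs = cluster_sets[locus]
            if cs is not None:
                pm, mk, ma, pf, fk, fa = cluster_sex_stats_full(cs, sexes)
                rec.p_male_in_male_clusters = pm
                rec.p_female_in_female_clusters = pf
                rec.male_prefix_size = mk
                rec.female_prefix_size = fk
                rec.male_top_angle = ma
                rec.female_top_angle = fa
        records.append(rec)
    return records


def scan_sd_region(
    records: Sequence[SexScanRecord], b_threshold: float = 0.05
) -> HeterogametyReport:
    """Locate the SD region: the global b minimum and the contiguous cM
    interval around it where b stays below ``b_threshold``.

    The interval's significance is reported conservatively as the minimum
    locus's exact binomial p alone.
    """
    usable = [r for r in records if np.isfinite(r.b)]
    if not usable:
        return HeterogametyReport("inconclusive")
    best = min(usable, key=lambda r: (r.b, r.p_binomial))
    report = HeterogametyReport(
        "inconclusive",
        minimum_locus=best.locus_id,
        minimum_b=best.b,
        minimum_p=best.p_binomial,
        sd_linkage_group=best.linkage_group,
    )
    if best.linkage_group is not None and best.position_cM is not None:
        on_lg = sorted(
            (r for r in usable
             if r.linkage_group == best.linkage_group and r.position_cM is not None),
            key=lambda r: r.position_cM,
        )
        i = next(j for j, r in enumerate(on_lg) if r.locus_id == best.locus_id)
        lo = hi = i
        while lo > 0 and on_lg[lo - 1].b <= b_threshold:
            lo -= 1
        while hi < len(on_lg) - 1 and on_lg[hi + 1].b <= b_threshold:
            hi += 1
        report.sd_interval_cM = (on_lg[lo].position_cM, on_lg[hi].position_cM)
    return report


def infer_heterogamety(
    records: Sequence[SexScanRecord],
    outlier_threshold: float = 0.9,
    b_threshold: float = 0.05,
) -> HeterogametyReport:
    """Combine the b scan with cluster-sex outliers into a verdict.

    Loci whose pMaleInMaleClusters exceeds ``outlier_threshold`` (against a
    genome-wide mode of ~0.5) mark a male-limited haplotype; the female
    statistic mirrors this.  Male-side outliers with no female-side
    outliers imply XY, the mirror implies ZW, anything else is
    inconclusive.

    A locus only qualifies as an outlier when it shows the full signature
    of a sex-limited haplotype, not merely a high statistic:

    * the minimal prefix is a *single* cluster — the diverged haplotype
      dominates its carriers' read signal and gathers nearly all of one
      sex together, while the other sex splits across clusters by its
      ordinary allele;
    * that cluster sits *off* the coordinate axes (between
      ``axis_margin`` and 90 - ``axis_margin`` degrees) — carriers of a
      sex-limited haplotype are obligate heterozygotes for it, whereas the
      spuriously sex-pure clusters that arise near the SD region by
      linkage alone are the homozygote clusters on the axes.
    """
    report = scan_sd_region(records, b_threshold)
    axis_margin = 15.0

    def qualifies(stat: float, prefix: int, angle: float) -> bool:
        return (
            np.isfinite(stat)
            and stat > outlier_threshold
            and prefix == 1
            and np.isfinite(angle)
            and axis_margin <= angle <= 90.0 - axis_margin
        )

    male = [
        r.locus_id for r in records
        if qualifies(r.p_male_in_male_clusters, r.male_prefix_size, r.male_top_angle)
    ]
    female = [
        r.locus_id for r in records
        if qualifies(
            r.p_female_in_female_clusters, r.female_prefix_size, r.female_top_angle
        )
    ]
    report.male_outliers = male
    report.female_outliers = female
    if male and not female:
        report.verdict = "XY"
    elif female and not male:
        report.verdict = "ZW"
    else:
        report.verdict = "inconclusive"
    return report
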