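"""Synthetic three-generation cross with capture-pileup read counts.

The generator emulates the statistical structure of a targeted-enrichment
experiment on an F2 intercross between two diverged taxa:

* founder haplotypes differing at Binomial(length, d_xy) positions, with
  d_xy drawn lognormally (mean 0.0202, mode 0.013 across loci);
* Mendelian transmission through one F1 father and one F1 mother per
  family, with inter-locus recombination from cM distances via the inverse
  Kosambi mapping function (no crossover interference);
* a center-peaked coverage profile (flat over the central bait span,
  decaying linearly toward the locus ends) around a mean depth of 147x;
* sequencing error, enrichment (capture) bias toward the variegata taxon
  in heterozygotes, and "overmerging" — mis-mapped paralogous reads added
  to every sample at a subset of positions of a subset of loci, which
  mimics consistently heterozygous-looking sites;
* an optional sex-determining locus (XY or ZW), optionally carrying a
  diverged sex-limited (Y or W) haplotype.

Everything is driven by a single integer seed; identical configs produce
byte-identical sync output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from diplokit.formats import (
    MapTable,
    PedigreeTable,
    STATES,
    SyncData,
)

log = logging.getLogger(__name__)

# lognormal(mu, sigma) with mean 0.0202 and mode 0.013:
#   mu + sigma^2/2 = ln 0.0202,  mu - sigma^2 = ln 0.013
_DXY_SIGMA = float(np.sqrt((np.log(0.0202) - np.log(0.013)) * 2.0 / 3.0))
_DXY_MU = float(np.log(0.013) + _DXY_SIGMA**2)

_ACGT = np.arange(4)


@dataclass
class SimConfig:
    """Scenario parameters; defaults mirror the real experiment's scale."""

    n_loci: int = 20
    locus_length_mean: int = 673
    locus_length_sd: int = 120
    locus_length_min: int = 120
    d_xy_fixed: Optional[float] = None  # overrides the lognormal draw
    n_linkage_groups: int = 12
    lg_length_cM: float = 132.0
    family_sizes: Tuple[int, ...] = (80, 82)
    coverage_mean: float = 147.0
    coverage_sample_sd: float = 0.25  # lognormal sd of per-sample depth factor
    bait_span: int = 250  # bp at full coverage in the profile center
    profile_floor: float = 0.1  # relative coverage at the locus termini
    epsilon_seq: float = 0.005
    overmerge_locus_frac: float = 0.2
    overmerge_pos_frac: float = 0.15
    overmerge_depth_frac: float = 0.5
    capture_bias: float = 0.55  # expected Bv read fraction in true HETs
    sd_locus: Optional[Tuple[int, float]] = None  # (LG, cM) or None
    system: str = "XY"
    sd_diverged_sex_haplotype: bool = False
    # divergence of the Y/W-limited haplotype: "strongly diverged", well
    # above d_xy, so that its carriers cluster together regardless of the
    # allele on their other chromosome
    sd_sex_divergence: float = 0.15
    # the sex-limited haplotype sits this far from the SD locus (same LG);
    # recombinants then leak into the opposite sex's clusters, as real
    # sex-linked loci near (not at) an SD region behave
    sd_sex_hap_offset_cM: float = 5.0
    # taxon divergence forced at the sex-haplotype locus (None = drawn like
    # any locus); 0 models a target where the taxa are identical but the
    # Y (or W) carries a strongly diverged allele, the cleanest signature
    sd_sex_hap_dxy: Optional[float] = None
    sex_uncertain_frac: float = 0.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["sd_locus"] is not None:
            d["sd_locus"] = list(d["sd_locus"])
        d["family_sizes"] = list(d["family_sizes"])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if d.get("sd_locus") is not None:
            d["sd_locus"] = tuple(d["sd_locus"])
        if "family_sizes" in d:
            d["family_sizes"] = tuple(d["family_sizes"])
        return cls(**d)


def preset(name: str, seed: int = 0, **overrides) -> SimConfig:
    """Named scenario presets.

    ``clean``: error-free reads, no overmerging, no capture bias.
    ``study``: 147x coverage, 0.5% error, 20% overmerged loci, capture
    bias 0.55.  ``no_variant``: zero divergence between the taxa.
    """
    base = dict(seed=seed)
    if name == "clean":
        base.update(epsilon_seq=0.0, overmerge_locus_frac=0.0, capture_bias=0.5)
    elif name == "study":
        pass
    elif name == "no_variant":
        base.update(d_xy_fixed=0.0, overmerge_locus_frac=0.0)
    else:
        raise ValueError(f"unknown preset {name!r}")
    base.update(overrides)
    return SimConfig(**base)


@dataclass
class SimTruth:
    """Complete generative truth for one simulated scenario."""

    config: SimConfig
    locus_ids: List[str]
    locus_lengths: Dict[str, int]
    map_table: MapTable
    pedigree: PedigreeTable
    # per-locus founder haplotypes (state indices 0..3), keys Bv/Bb and
    # optionally BvY (or BbW) and paralog
    haplotypes: Dict[str, Dict[str, np.ndarray]]
    # per F2, per locus: 0 = the parent's variegata-labeled copy, 1 = bombina
    paternal_gamete: np.ndarray  # (n_f2, n_loci)
    maternal_gamete: np.ndarray
    f2_ids: List[str]
    sexes: Dict[str, str]
    sd_locus_id: Optional[str]
    # locus carrying the diverged Y- (or W-) limited haplotype, if any
    sex_hap_locus_id: Optional[str] = None
    overmerged_loci: List[str] = field(default_factory=list)

    def diplotype(self, f2_index: int, locus_index: int) -> str:
        n_bv = 2 - int(self.paternal_gamete[f2_index, locus_index]) - int(
            self.maternal_gamete[f2_index, locus_index]
        )
        return ("BbHOM", "HET", "BvHOM")[n_bv]

    def truth_matrix(self) -> pd.DataFrame:
        """loci x F2 DataFrame of true diplotype states."""
        data = {
            sid: [self.diplotype(i, j) for j in range(len(self.locus_ids))]
            for i, sid in enumerate(self.f2_ids)
        }
        return pd.DataFrame(data, index=self.locus_ids)


def _inverse_kosambi(cm_gap: np.ndarray) -> np.ndarray:
    """Map cM distance to recombination fraction, r = tanh(2d)/2."""
    d = np.asarray(cm_gap, dtype=float) / 100.0
    return 0.5 * np.tanh(2.0 * d)


def _random_haplotype(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n).astype(np.int16)


def _diverge(rng: np.random.Generator, hap: np.ndarray, d: float) -> np.ndarray:
    """Copy with Binomial(n, d) positions substituted to another base."""
    out = hap.copy()
    if d <= 0:
        return out
    flip = rng.random(len(hap)) < d
    shift = rng.integers(1, 4, size=int(flip.sum()))
    out[flip] = (out[flip] + shift) % 4
    return out


def simulate_cross(config: SimConfig) -> SimTruth:
    """Generate founder haplotypes, the linkage map, the pedigree, and
    Mendelian gametes (with Kosambi recombination) for all F2 offspring."""
    rng = np.random.default_rng(config.seed)
    L = config.n_loci
    locus_ids = [f"L{i + 1:04d}" for i in range(L)]

    lengths = np.maximum(
        config.locus_length_min,
        rng.normal(config.locus_length_mean, config.locus_length_sd, size=L).astype(int),
    )
    locus_lengths = dict(zip(locus_ids, (int(x) for x in lengths)))

    lgs = rng.integers(1, config.n_linkage_groups + 1, size=L)
    cms = rng.uniform(0.0, config.lg_length_cM, size=L)
    sd_locus_id: Optional[str] = None
    sex_hap_locus_id: Optional[str] = None
    if config.sd_locus is not None:
        sd_lg, sd_cm = config.sd_locus
        lgs[0], cms[0] = sd_lg, sd_cm
        sd_locus_id = locus_ids[0]
        if config.sd_diverged_sex_haplotype:
            if L < 2:
                raise ValueError("a diverged sex haplotype needs >= 2 loci")
            lgs[1] = sd_lg
            cms[1] = max(sd_cm - config.sd_sex_hap_offset_cM, 0.0)
            sex_hap_locus_id = locus_ids[1]
    map_table = MapTable(
        pd.DataFrame(
            {
                "locus_id": locus_ids,
                "linkage_group": lgs,
                "position_cM": np.round(cms, 2),
            }
        )
    )

    if config.d_xy_fixed is not None:
        dxy = np.full(L, config.d_xy_fixed)
    else:
        dxy = rng.lognormal(_DXY_MU, _DXY_SIGMA, size=L)
    if sex_hap_locus_id is not None and config.sd_sex_hap_dxy is not None:
        dxy[locus_ids.index(sex_hap_locus_id)] = config.sd_sex_hap_dxy

    haplotypes: Dict[str, Dict[str, np.ndarray]] = {}
    for j, locus in enumerate(locus_ids):
        bv = _random_haplotype(rng, locus_lengths[locus])
        bb = _diverge(rng, bv, dxy[j])
        haps = {"Bv": bv, "Bb": bb}
        if locus == sex_hap_locus_id:
            if config.system == "XY":
                haps["BvY"] = _diverge(rng, bv, config.sd_sex_divergence)
            else:
                haps["BbW"] = _diverge(rng, bb, config.sd_sex_divergence)
        haplotypes[locus] = haps

    # pedigree
    families = list(range(6, 6 + len(config.family_sizes)))
    rows = [
        ("F0_sire", "F0", "grandsire_Bv", pd.NA, "male"),
        ("F0_dam", "F0", "granddam_Bb", pd.NA, "female"),
        ("F1_father", "F1", "F1_father", pd.NA, "male"),
    ]
    for fam in families:
        rows.append((f"F1_mother{fam}", "F1", "F1_mother", fam, "female"))
    f2_ids: List[str] = []
    f2_family: List[int] = []
    for fam, size in zip(families, config.family_sizes):
        for k in range(size):
            sid = f"F2_{fam}_{k + 1:03d}"
            f2_ids.append(sid)
            f2_family.append(fam)
            rows.append((sid, "F2", "offspring", fam, "unknown"))
    ped_df = pd.DataFrame(
        rows, columns=["sample_id", "generation", "role", "family", "sex"]
    )
    ped_df["family"] = ped_df["family"].astype("Int64")

    # meiosis: gamete value 0 = variegata-labeled copy, 1 = bombina-labeled
    order = map_table.table.set_index("locus_id")
    lg_cols: Dict[int, np.ndarray] = {}
    for lg in map_table.linkage_groups:
        ids = list(map_table.loci_of(lg)["locus_id"])
        lg_cols[lg] = np.array([locus_ids.index(x) for x in ids])

    n_f2 = len(f2_ids)

    def meiosis_batch(r: np.random.Generator) -> np.ndarray:
        g = np.zeros((n_f2, L), dtype=np.int8)
        for lg, cols in lg_cols.items():
            cm = order.loc[[locus_ids[c] for c in cols], "position_cM"].to_numpy(float)
            rec = _inverse_kosambi(np.diff(cm))
            start = r.integers(0, 2, size=n_f2)
            if len(cols) > 1:
                switch = r.random((n_f2, len(cols) - 1)) < rec[None, :]
                phase = np.concatenate(
                    [start[:, None], switch.astype(np.int8)], axis=1
                ).cumsum(axis=1) % 2
            else:
                phase = start[:, None]
            g[:, cols] = phase.astype(np.int8)
        return g

    pat = meiosis_batch(rng)
    mat = meiosis_batch(rng)

    # sex assignment via SD-locus transmission
    sexes: Dict[str, str] = {}
    if sd_locus_id is not None:
        j = locus_ids.index(sd_locus_id)
        for i, sid in enumerate(f2_ids):
            if config.system == "XY":
                # the F1 father's Bv-labeled copy is the Y
                sexes[sid] = "male" if pat[i, j] == 0 else "female"
            else:
                # ZW: the F1 mother's Bb-labeled copy is the W
                sexes[sid] = "female" if mat[i, j] == 1 else "male"
    else:
        draw = rng.random(n_f2) < 0.5
        for i, sid in enumerate(f2_ids):
            sexes[sid] = "male" if draw[i] else "female"
    if config.sex_uncertain_frac > 0:
        unc = rng.random(n_f2) < config.sex_uncertain_frac
        for i, sid in enumerate(f2_ids):
            if unc[i]:
                sexes[sid] = "uncertain"

    ped_df.loc[ped_df["role"] == "offspring", "sex"] = [sexes[s] for s in f2_ids]
    pedigree = PedigreeTable(ped_df)

    overmerged: List[str] = []
    if config.overmerge_locus_frac > 0:
        hit = rng.random(L) < config.overmerge_locus_frac
        overmerged = [locus_ids[j] for j in np.flatnonzero(hit)]
        for locus in overmerged:
            bv = haplotypes[locus]["Bv"]
            haplotypes[locus]["paralog"] = _diverge(
                rng, bv, max(2.0 * dxy[locus_ids.index(locus)], 0.02)
            )

    return SimTruth(
        config=config,
        locus_ids=locus_ids,
        locus_lengths=locus_lengths,
        map_table=map_table,
        pedigree=pedigree,
        haplotypes=haplotypes,
        paternal_gamete=pat,
        maternal_gamete=mat,
        f2_ids=f2_ids,
        sexes=sexes,
        sd_locus_id=sd_locus_id,
        sex_hap_locus_id=sex_hap_locus_id,
        overmerged_loci=overmerged,
    )


def coverage_profile(n: int, bait_span: int, floor: float) -> np.ndarray:
    """Relative coverage along a locus: 1.0 over the central bait span,
    decaying linearly to ``floor`` at the termini."""
    pos = np.arange(n, dtype=float)
    center = (n - 1) / 2.0
    half = bait_span / 2.0
    dist = np.maximum(np.abs(pos - center) - half, 0.0)
    slope_len = max(center - half, 1.0)
    return np.maximum(1.0 - (1.0 - floor) * dist / slope_len, floor)


def _sample_copies(
    truth: SimTruth, sample_id: str, locus: str
) -> Tuple[np.ndarray, np.ndarray, bool]:
    """The two haplotype sequences an individual carries at a locus, as
    (variegata-labeled copy, bombina-labeled copy, is_het_by_ancestry)."""
    cfg = truth.config
    haps = truth.haplotypes[locus]
    bv, bb = haps["Bv"], haps["Bb"]
    at_sex_hap = locus == truth.sex_hap_locus_id
    father_bv = haps.get("BvY", bv) if at_sex_hap else bv
    mother_bb = haps.get("BbW", bb) if at_sex_hap else bb
    if sample_id == "F0_sire":
        # under XY with a diverged Y, the sire carries X (Bv) and Y (BvY)
        return bv, (haps.get("BvY", bv) if at_sex_hap else bv), False
    if sample_id == "F0_dam":
        return (haps.get("BbW", bb) if at_sex_hap else bb), bb, False
    if sample_id == "F1_father":
        return father_bv, bb, True
    if sample_id.startswith("F1_mother"):
        return bv, mother_bb, True
    i = truth.f2_ids.index(sample_id)
    j = truth.locus_ids.index(locus)
    pat = father_bv if truth.paternal_gamete[i, j] == 0 else bb
    mat = bv if truth.maternal_gamete[i, j] == 0 else mother_bb
    het = truth.paternal_gamete[i, j] != truth.maternal_gamete[i, j]
    if het and truth.paternal_gamete[i, j] == 1:
        # enrichment bias attaches to the variegata-labeled copy, which a
        # heterozygote may carry on either the paternal or maternal side
        return mat, pat, True
    return pat, mat, bool(het)


def _scatter_errors(
    counts: np.ndarray, seq: np.ndarray, n_reads: np.ndarray,
    eps: float, rng: np.random.Generator,
) -> None:
    """Add ``n_reads`` reads of haplotype ``seq`` to ``counts`` (6 x n),
    flipping each read to a uniform other state with probability eps."""
    n = len(seq)
    if eps > 0:
        errs = rng.binomial(n_reads, eps)
    else:
        errs = np.zeros(n, dtype=np.int64)
    np.add.at(counts, (seq, np.arange(n)), n_reads - errs)
    if errs.any():
        # distribute errors over the five other states, uniformly
        rows = np.arange(6)[:, None] == seq[None, :]
        others = np.argsort(rows, axis=0, kind="stable")[:5]  # rows != seq
        remaining = errs.copy()
        for k in range(5):
            take = rng.binomial(remaining, 1.0 / (5 - k)) if k < 4 else remaining
            np.add.at(counts, (others[k], np.arange(n)), take)
            remaining = remaining - take


def simulate_reads(truth: SimTruth, config: Optional[SimConfig] = None) -> SyncData:
    """Draw per-position read counts for every sample at every locus.

    Depth is Poisson around coverage_mean x per-sample factor x profile.
    In ancestry heterozygotes reads come from the variegata-labeled copy
    with probability ``capture_bias``; sequencing errors flip reads to a
    uniform other state; overmerged loci add paralog reads to all samples
    at a fixed subset of positions.
    """
    cfg = config or truth.config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    ped = truth.pedigree
    sample_ids = ped.sample_ids
    factors = {
        s: float(np.exp(rng.normal(0.0, cfg.coverage_sample_sd)))
        for s in sample_ids
    }

    counts: Dict[str, np.ndarray] = {}
    for locus in truth.locus_ids:
        n = truth.locus_lengths[locus]
        profile = coverage_profile(n, cfg.bait_span, cfg.profile_floor)
        over_pos = None
        if locus in truth.overmerged_loci:
            over_pos = rng.random(n) < cfg.overmerge_pos_frac
            paralog = truth.haplotypes[locus]["paralog"]
        arr = np.zeros((len(sample_ids), 6, n), dtype=np.int64)
        for si, sid in enumerate(sample_ids):
            copy_v, copy_b, het = _sample_copies(truth, sid, locus)
            lam = cfg.coverage_mean * factors[sid] * profile
            depth = rng.poisson(lam)
            c = np.zeros((6, n), dtype=np.int64)
            if np.array_equal(copy_v, copy_b):
                _scatter_errors(c, copy_v, depth, cfg.epsilon_seq, rng)
            else:
                p_v = cfg.capture_bias if het else 0.5
                from_v = rng.binomial(depth, p_v)
                _scatter_errors(c, copy_v, from_v, cfg.epsilon_seq, rng)
                _scatter_errors(c, copy_b, depth - from_v, cfg.epsilon_seq, rng)
            if over_pos is not None:
                extra = rng.poisson(cfg.overmerge_depth_frac * lam) * over_pos
                np.add.at(c, (paralog, np.arange(n)), extra)
            arr[si] = c
        counts[locus] = arr

    ref_bases = {
        locus: "".join(STATES[x] for x in truth.haplotypes[locus]["Bv"])
        for locus in truth.locus_ids
    }
    return SyncData(sample_ids, counts, ref_bases)


# ---------------------------------------------------------------------------
# end-to-end scenario


def run_scenario(config: SimConfig, outdir=None) -> dict:
    """Simulate, diplotype, QC, and sex-scan one scenario end to end.

    Returns a report dict with the call-vs-truth confusion matrix, call
    accuracy over F2s, support distribution, per-locus segregation
    chi-squares, the b profile, and the heterogamety verdict.
    """
    from diplokit import mendel_qc
    from diplokit.diplotyper import CallerConfig, calls_of, run_pipeline
    from diplokit import sexscan as sx
    from diplokit.formats import write_map, write_pedigree, write_sync

    truth = simulate_cross(config)
    sync = simulate_reads(truth)
    results = run_pipeline(sync, truth.pedigree, CallerConfig())
    calls = calls_of(results)

    states = ("BbHOM", "HET", "BvHOM", "MISSING")
    confusion = {t: {c: 0 for c in states} for t in states[:3]}
    supports: List[float] = []
    for j, locus in enumerate(truth.locus_ids):
        if "no_variants" in results[locus].flags:
            # indistinguishable taxa at this locus: reported separately,
            # excluded from the call-accuracy denominator
            continue
        for i, sid in enumerate(truth.f2_ids):
            t = truth.diplotype(i, j)
            call = calls[locus].get(sid)
            c = call.state if call is not None else "MISSING"
            confusion[t][c] += 1
            if c != "MISSING":
                supports.append(call.support)
    total = sum(sum(row.values()) for row in confusion.values())
    correct = sum(confusion[t][t] for t in states[:3])
    accuracy = correct / total if total else float("nan")

    seg = []
    for locus in truth.locus_ids:
        seg.extend(mendel_qc.segregation_chisq(locus, calls[locus], truth.pedigree))
    mendel_qc.significance_thresholds(seg)

    records = sx.scan_records(
        calls, truth.sexes, truth.map_table,
        {loc: results[loc].clusters for loc in results},
    )
    report_het = sx.infer_heterogamety(records)

    supports_arr = np.array(supports) if supports else np.array([])
    no_variant_loci = [
        loc for loc, r in results.items() if "no_variants" in r.flags
    ]
    report = {
        "config": config.to_dict(),
        "n_loci": config.n_loci,
        "n_f2": len(truth.f2_ids),
        "accuracy": accuracy,
        "confusion": confusion,
        "support_median": float(np.median(supports_arr)) if supports else float("nan"),
        "support_frac_gt10": float(np.mean(supports_arr > 10.0)) if supports else 0.0,
        "no_variant_loci": no_variant_loci,
        "flagged_loci": [
            loc for loc, r in results.items()
            if "expected_F0F1_pattern_violated" in r.flags
        ],
        "sd": {
            "verdict": report_het.verdict,
            "minimum_locus": report_het.minimum_locus,
            "minimum_b": report_het.minimum_b,
            "true_sd_locus": truth.sd_locus_id,
        },
        "segregation": [
            {
                "locus_id": r.locus_id,
                "family": int(r.family),
                "chi2": r.chi2,
                "p": r.p_value,
                "bonferroni": r.exceeds_bonferroni,
                "bh": r.exceeds_bh,
            }
            for r in seg
        ],
        "b_profile": [
            {"locus_id": r.locus_id, "b": r.b, "n_hom": r.n_hom, "p": r.p_binomial}
            for r in records
        ],
    }

    if outdir is not None:
        import os

        os.makedirs(outdir, exist_ok=True)
        write_sync(sync, os.path.join(outdir, "counts.sync"))
        write_pedigree(truth.pedigree, os.path.join(outdir, "pedigree.tsv"))
        write_map(truth.map_table, os.path.join(outdir, "map.tsv"))
        truth.truth_matrix().to_csv(os.path.join(outdir, "truth.tsv"), sep="\t")
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report
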