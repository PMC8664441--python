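"""Clustering, consensus, and the Mendelian diplotype likelihood."""

import math

import numpy as np
import pytest

from diplokit.diplotyper import (
    ALPHA_MAX,
    ALPHA_MIN,
    CallerConfig,
    Cluster,
    ClusterSet,
    Haplotype,
    NoVariantsError,
    UnresolvableLocusError,
    cluster_scores,
    coestimate_locus,
    consensus_haplotype,
    diplotype_locus,
    diplotype_loglik,
    rescore_with_whitelist,
    run_pipeline,
    update_polarized_matrix,
)
from diplokit.formats import NOCALL, STATE_INDEX, STATES, WhitelistEntry
from diplokit.polarity import SampleScore


def col(**kw):
    order = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "DEL": 5}
    v = np.zeros(6, dtype=np.int64)
    for k, n in kw.items():
        v[order[k]] = n
    return v


# ---------------------------------------------------------------------------
# consensus


class TestConsensus:
    def test_clear_majority_called(self):
        hap = consensus_haplotype(col(A=90, C=10).reshape(6, 1))
        assert STATES[hap.states[0]] == "A"

    def test_even_split_nocall(self):
        hap = consensus_haplotype(col(A=50, C=50).reshape(6, 1))
        assert hap.states[0] == NOCALL

    def test_n_majority_nocall(self):
        hap = consensus_haplotype(col(N=95, A=5).reshape(6, 1))
        assert hap.states[0] == NOCALL

    def test_zero_depth_nocall(self):
        hap = consensus_haplotype(np.zeros((6, 2), dtype=int))
        assert (hap.states == NOCALL).all()

    def test_marginal_majority_in_deep_pool_nocall(self):
        # 50.5% of 6000 reads is sampling noise around an even mixture,
        # not a haplotype state
        hap = consensus_haplotype(col(A=3030, C=2970).reshape(6, 1))
        assert hap.states[0] == NOCALL

    def test_deep_homozygote_pool_recovers_truth(self, small_clean):
        truth, sync = small_clean
        locus = truth.locus_ids[0]
        arr = sync.locus_array(locus)
        # pool all true BvHOM offspring plus the grandsire
        j = 0
        idx = [sync.sample_ids.index("F0_sire")] + [
            sync.sample_ids.index(s)
            for i, s in enumerate(truth.f2_ids)
            if truth.diplotype(i, j) == "BvHOM"
        ]
        hap = consensus_haplotype(arr[idx].sum(axis=0))
        true_bv = truth.haplotypes[locus]["Bv"]
        called = hap.called
        assert called.mean() > 0.95
        assert (hap.states[called] == true_bv[called]).all()


# ---------------------------------------------------------------------------
# likelihood


def dumb_loglik(counts, hap_a, hap_b, state, eps, alpha_grid=None):
    """Naive per-column likelihood, the independent oracle.

    The heterozygote case enumerates an explicit alpha grid (no closed
    form): per grid point the full 6 x n expected distribution is built and
    contracted against the counts.
    """
    a, b = hap_a.states, hap_b.states
    cols = np.flatnonzero((a != NOCALL) & (b != NOCALL))
    sub = counts[:, cols].astype(float)

    def point_mass(h):
        # (6, n_cols) expected distribution for a homozygote of h
        return np.where(np.arange(6)[:, None] == h[cols][None, :], 1 - eps, eps / 5)

    def contract(pi):
        with np.errstate(divide="ignore"):
            lp = np.log(pi)
        masked = np.where(sub > 0, lp, 0.0)
        return float(np.sum(sub * masked))

    if state == "BvHOM":
        return contract(point_mass(a)), None
    if state == "BbHOM":
        return contract(point_mass(b)), None
    pa, pb = point_mass(a), point_mass(b)
    al = np.asarray(alpha_grid)[:, None, None]
    pi = al * pa[None] + (1 - al) * pb[None]  # (G, 6, n_cols)
    with np.errstate(divide="ignore"):
        lp = np.log(pi)
    lp = np.where(sub[None] > 0, lp, 0.0)
    vals = np.tensordot(lp, sub, axes=([1, 2], [0, 1]))
    best = int(np.argmax(vals))
    return float(vals[best]), float(np.asarray(alpha_grid)[best])


class TestDiplotypeLoglik:
    def test_hom_all_matching_closed_form(self):
        eps = 0.01
        counts = np.vstack([col(A=30), col(A=20)]).T  # 2 columns
        a = Haplotype.from_string("AA")
        b = Haplotype.from_string("CC")
        lnl, alpha = diplotype_loglik(counts, a, b, "BvHOM", eps)
        assert alpha is None
        assert math.isclose(lnl, 50 * math.log(1 - eps), rel_tol=1e-12)

    def test_het_symmetric_reads_give_half(self):
        counts = np.vstack([col(A=40, C=40), col(A=25, C=25)]).T
        a = Haplotype.from_string("AA")
        b = Haplotype.from_string("CC")
        _, alpha = diplotype_loglik(counts, a, b, "HET", 0.005)
        assert math.isclose(alpha, 0.5, abs_tol=1e-3)

    def test_biased_het_matches_grid_oracle(self):
        eps = 1e-4
        counts = np.vstack([col(A=70, C=30), col(A=140, C=60)]).T
        a = Haplotype.from_string("AA")
        b = Haplotype.from_string("CC")
        lnl, alpha = diplotype_loglik(counts, a, b, "HET", eps)
        grid = np.arange(ALPHA_MIN, ALPHA_MAX + 1e-9, 1e-4)
        ref, ref_alpha = dumb_loglik(counts, a, b, "HET", eps, grid)
        assert math.isclose(alpha, 0.7, abs_tol=2e-3)
        assert lnl >= ref - 1e-9 and abs(lnl - ref) < 1e-6

    def test_all_columns_masked_is_error(self):
        counts = col(A=5).reshape(6, 1)
        a = Haplotype(np.array([NOCALL]))
        b = Haplotype.from_string("C")
        with pytest.raises(ValueError, match="masked"):
            diplotype_loglik(counts, a, b, "HET", 0.005)

    @pytest.mark.parametrize("state", ["BbHOM", "BvHOM", "HET"])
    def test_matches_naive_implementation(self, state):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 40, (6, 8))
        a = Haplotype(rng.integers(0, 4, 8).astype(np.int16))
        b = Haplotype(rng.integers(0, 4, 8).astype(np.int16))
        eps = 0.02
        lnl, _ = diplotype_loglik(counts, a, b, state, eps)
        grid = np.arange(ALPHA_MIN, ALPHA_MAX + 1e-9, 1e-4)
        ref, _ = dumb_loglik(counts, a, b, state, eps, grid)
        assert abs(lnl - ref) < 1e-4


# ---------------------------------------------------------------------------
# clustering


def make_scores(angle_groups, radius=50.0, jitter=0.5, seed=0):
    rng = np.random.default_rng(seed)
    scores, counts = {}, {}
    k = 0
    for ang_deg, n in angle_groups:
        for _ in range(n):
            a = math.radians(ang_deg + rng.normal(0, jitter))
            scores[f"s{k}"] = SampleScore(radius * math.cos(a), radius * math.sin(a))
            counts[f"s{k}"] = np.zeros((6, 1), dtype=np.int64)
            k += 1
    return scores, counts


class TestClusterScores:
    def test_three_blobs_recovered(self):
        scores, counts = make_scores([(2, 20), (45, 40), (88, 20)])
        cs = cluster_scores(scores, counts)
        assert cs.k == 3
        sizes = sorted(c.size for c in cs.clusters)
        assert sizes == [20, 20, 40]
        # membership matches the generating blob
        for sid, sc in scores.items():
            ci = cs.labels[sid]
            assert abs(cs.clusters[ci].mean_angle - sc.angle) < 10

    def test_identical_scores_one_cluster(self):
        scores = {f"s{i}": SampleScore(10.0, 10.0) for i in range(12)}
        counts = {s: np.zeros((6, 1), dtype=np.int64) for s in scores}
        cs = cluster_scores(scores, counts)
        assert cs.k == 1

    def test_four_blobs_give_four_clusters(self):
        scores, counts = make_scores([(2, 15), (30, 15), (60, 15), (88, 15)])
        cs = cluster_scores(scores, counts)
        assert cs.k >= 4

    def test_all_origin_flags_no_variants(self):
        scores = {f"s{i}": SampleScore(0.0, 0.0) for i in range(10)}
        counts = {s: np.zeros((6, 1), dtype=np.int64) for s in scores}
        with pytest.raises(NoVariantsError):
            cluster_scores(scores, counts)

    def test_low_radius_samples_excluded(self):
        scores, counts = make_scores([(2, 10), (88, 10)])
        scores["dust"] = SampleScore(0.01, 0.01)
        counts["dust"] = np.zeros((6, 1), dtype=np.int64)
        cs = cluster_scores(scores, counts)
        assert "dust" in cs.excluded
        assert "dust" not in cs.labels


class TestUpdateMatrix:
    def test_axis_clusters_pool_as_new_sources(self):
        bv_pool = np.zeros((6, 2), dtype=np.int64)
        bv_pool[STATE_INDEX["A"]] = [400, 400]
        bb_pool = np.zeros((6, 2), dtype=np.int64)
        bb_pool[STATE_INDEX["C"]] = [400, 400]
        het_pool = bv_pool + bb_pool
        cs = ClusterSet(
            clusters=[
                Cluster(["x"], bv_pool, 1.0),
                Cluster(["y"], het_pool, 45.0),
                Cluster(["z"], bb_pool, 89.0),
            ],
            labels={"x": 0, "y": 1, "z": 2},
        )
        mp = update_polarized_matrix(cs)
        assert mp.source == "updated_clusters"
        assert (mp.values[STATE_INDEX["A"]] > 0.99).all()
        assert (mp.values[STATE_INDEX["C"]] < -0.99).all()

    def test_two_clusters_suffice(self):
        bv_pool = np.zeros((6, 1), dtype=np.int64)
        bv_pool[0, 0] = 300
        bb_pool = np.zeros((6, 1), dtype=np.int64)
        bb_pool[1, 0] = 300
        cs = ClusterSet(
            [Cluster(["x"], bv_pool, 5.0), Cluster(["y"], bb_pool, 80.0)],
            {"x": 0, "y": 1},
        )
        mp = update_polarized_matrix(cs)
        assert mp.values[0, 0] > 0.99

    def test_single_cluster_rejected(self):
        cs = ClusterSet([Cluster(["x"], np.zeros((6, 1), dtype=np.int64), 45.0)], {"x": 0})
        with pytest.raises(ValueError):
            update_polarized_matrix(cs)

    def test_update_does_not_degrade_separation(self, small_clean):
        truth, sync = small_clean
        ped = truth.pedigree
        results = run_pipeline(sync, ped, CallerConfig())
        for locus, res in results.items():
            if res.clusters is None or res.clusters.k < 2:
                continue
            angles = sorted(c.mean_angle for c in res.clusters.clusters)
            assert min(np.diff(angles)) > 5.0


# ---------------------------------------------------------------------------
# coestimation


class TestCoestimate:
    def test_clean_family_fully_recovered(self, small_clean):
        truth, sync = small_clean
        results = run_pipeline(sync, truth.pedigree, CallerConfig())
        for j, locus in enumerate(truth.locus_ids):
            res = results[locus]
            assert res.flags == ()
            for i, sid in enumerate(truth.f2_ids):
                assert res.calls[sid].state == truth.diplotype(i, j)
            # F0/F1 calls follow the expected cross pattern
            assert res.calls["F0_sire"].state == "BvHOM"
            assert res.calls["F0_dam"].state == "BbHOM"
            assert res.calls["F1_father"].state == "HET"

    def test_noisy_family_recovered(self, small_noisy):
        truth, sync = small_noisy
        results = run_pipeline(sync, truth.pedigree, CallerConfig())
        total = correct = 0
        for j, locus in enumerate(truth.locus_ids):
            if "no_variants" in results[locus].flags:
                continue  # no divergent position drawn: undiagnosable
            for i, sid in enumerate(truth.f2_ids):
                total += 1
                correct += results[locus].calls[sid].state == truth.diplotype(i, j)
        assert total > 0
        assert correct / total >= 0.99

    def test_identical_candidates_unresolvable(self):
        counts = {f"s{i}": col(A=20).reshape(6, 1) for i in range(6)}
        hap = Haplotype.from_string("A")
        with pytest.raises(UnresolvableLocusError):
            coestimate_locus(counts, [(hap, 0.0), (Haplotype.from_string("A"), 90.0)])

    def test_pair_support_positive_with_decoy(self, small_clean):
        truth, sync = small_clean
        locus = truth.locus_ids[0]
        arr = sync.locus_array(locus)
        counts = {s: arr[i] for i, s in enumerate(sync.sample_ids)}
        n = arr.shape[2]
        bv = Haplotype(truth.haplotypes[locus]["Bv"].astype(np.int16))
        bb = Haplotype(truth.haplotypes[locus]["Bb"].astype(np.int16))
        decoy = Haplotype((truth.haplotypes[locus]["Bv"] + 1) % 4)
        co = coestimate_locus(
            counts, [(bv, 0.0), (bb, 90.0), (decoy, 45.0)], refine=False
        )
        assert co.pair_support > 0
        assert co.hap_bv.same_as(bv) and co.hap_bb.same_as(bb)

    def test_f2_ratio_consistent_with_mendelian_expectation(self, small_clean):
        from scipy import stats

        truth, sync = small_clean
        results = run_pipeline(sync, truth.pedigree, CallerConfig())
        counts = {"BbHOM": 0, "HET": 0, "BvHOM": 0}
        for locus in truth.locus_ids:
            for sid in truth.f2_ids:
                st_ = results[locus].calls[sid].state
                if st_ in counts:
                    counts[st_] += 1
        n = sum(counts.values())
        chi2 = sum(
            (counts[k] - e) ** 2 / e
            for k, e in zip(("BbHOM", "HET", "BvHOM"), (n / 4, n / 2, n / 4))
        )
        assert stats.chi2.sf(chi2, 2) > 0.001


class TestWhitelistRescore:
    def test_equivalent_to_full_matrix_on_clean_data(self, small_clean):
        truth, sync = small_clean
        results = run_pipeline(sync, truth.pedigree, CallerConfig())
        locus = truth.locus_ids[0]
        arr = sync.locus_array(locus)
        counts = {s: arr[i] for i, s in enumerate(sync.sample_ids)}
        bv = truth.haplotypes[locus]["Bv"]
        bb = truth.haplotypes[locus]["Bb"]
        entries = [
            WhitelistEntry(int(i) + 1, STATES[bv[i]], STATES[bb[i]])
            for i in np.flatnonzero(bv != bb)
        ]
        calls = rescore_with_whitelist(counts, entries)
        for sid in sync.sample_ids:
            assert calls[sid].state == results[locus].calls[sid].state

    def test_reads_only_off_whitelist_missing(self):
        counts = {"s": col(A=30).reshape(6, 1)}
        counts["s"] = np.hstack([counts["s"], np.zeros((6, 1), dtype=np.int64)])
        entries = [WhitelistEntry(2, "A", "C")]  # depth only at column 1
        calls = rescore_with_whitelist(counts, entries)
        assert calls["s"].state == "MISSING"

    def test_empty_whitelist_rejected(self):
        with pytest.raises(ValueError):
            rescore_with_whitelist({"s": np.zeros((6, 1))}, [])


class TestLocusDriver:
    def test_no_variant_locus_flagged(self):
        rng = np.random.default_rng(1)
        base = rng.integers(0, 4, 50)
        counts = {}
        for i, s in enumerate(["sire", "dam"] + [f"o{k}" for k in range(10)]):
            c = np.zeros((6, 50), dtype=np.int64)
            c[base, np.arange(50)] = rng.poisson(100, 50)
            counts[s] = c
        res = diplotype_locus("L", counts, grandsire="sire", granddam="dam")
        assert "no_variants" in res.flags
        assert all(c.state == "MISSING" for c in res.calls.values())
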