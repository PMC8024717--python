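"""Decomposition pipeline: filters, CCF estimation, DP clustering, trees."""

import io
import warnings

import numpy as np
import pytest

import biphasic as bp
from biphasic import simulate as sim
from biphasic.decompose import (
    CcfClusterModel,
    CloneCluster,
    CloneTree,
    build_component_tree,
    classify_truncal,
    detect_clonal_selection,
    estimate_ccf,
    expected_vaf,
    filter_for_decomposition,
    pair_mutations,
)


def rec(comp, pos=1000, t_ref=250, t_alt=250, n_ref=100, n_alt=0, chrom="1"):
    return bp.MutationRecord(
        "S1", comp, chrom, pos, "A", "C", "SNV",
        t_ref=t_ref, t_alt=t_alt, n_ref=n_ref, n_alt=n_alt,
    )


def paired(pos=1000, **per_comp):
    """per_comp: comp -> dict of count overrides."""
    return pair_mutations([rec(c, pos=pos, **kw) for c, kw in per_comp.items()])[0]


class TestPairing:
    def test_groups_by_site(self):
        muts = [rec("epithelial", 1000), rec("mesenchymal", 1000),
                rec("epithelial", 2000), rec("mesenchymal", 2000)]
        pairs = pair_mutations(muts)
        assert len(pairs) == 2
        assert pairs[0].components == ["epithelial", "mesenchymal"]

    def test_missing_component_counts_rejected(self):
        muts = [rec("epithelial", 1000), rec("mesenchymal", 1000),
                rec("epithelial", 2000)]
        with pytest.raises(ValueError, match="missing read counts"):
            pair_mutations(muts)


class TestFilters:
    """Eight-mutation fixture exercising each rule and the tally order."""

    def _fixture(self):
        ok = dict(t_ref=250, t_alt=250, n_ref=100, n_alt=0)
        return [
            paired(1000, epithelial=ok, mesenchymal=ok),                     # keep
            paired(2000, epithelial=dict(t_ref=250, t_alt=250, n_ref=19, n_alt=0),
                   mesenchymal=ok),                                          # a
            paired(3000, epithelial=dict(t_ref=30, t_alt=19, n_ref=100, n_alt=0),
                   mesenchymal=ok),                                          # b
            paired(4000, epithelial=dict(t_ref=490, t_alt=10, n_ref=95, n_alt=5),
                   mesenchymal=dict(t_ref=490, t_alt=10, n_ref=95, n_alt=5)),  # c
            paired(5000, epithelial=dict(t_ref=1000, t_alt=600, n_ref=100, n_alt=0),
                   mesenchymal=ok),                                          # d
            paired(6000, epithelial=dict(t_ref=10, t_alt=10, n_ref=10, n_alt=0),
                   mesenchymal=ok),                                          # a before b
            paired(7000, epithelial=ok, mesenchymal=ok),                     # keep
            paired(8000, epithelial=dict(t_ref=475, t_alt=25, n_ref=99, n_alt=1),
                   mesenchymal=dict(t_ref=450, t_alt=50, n_ref=99, n_alt=1)),  # keep: 0.1 >= 5*0.01
        ]

    def test_retention_and_tally(self):
        retained, tally = filter_for_decomposition(self._fixture())
        assert [pm.key[1] for pm in retained] == [1000, 7000, 8000]
        assert tally == {"a": 2, "b": 1, "c": 1, "d": 1}

    def test_clean_input_all_retained(self):
        pairs = [paired(1000 * k, epithelial={}, mesenchymal={}) for k in range(1, 6)]
        retained, tally = filter_for_decomposition(pairs)
        assert len(retained) == 5
        assert tally == {"a": 0, "b": 0, "c": 0, "d": 0}

    def test_zero_normal_vaf_never_fails_rule_c(self):
        pm = paired(
            1000,
            epithelial=dict(t_ref=495, t_alt=5, n_ref=100, n_alt=0),
            mesenchymal=dict(t_ref=495, t_alt=5, n_ref=100, n_alt=0),
        )
        retained, tally = filter_for_decomposition([pm])
        assert len(retained) == 1


class TestCcfEstimation:
    def test_pure_diploid_closed_form(self):
        # vaf 0.5, purity 1, CN 2: ccf = 0.5 * 2 / 1 = 1.0 at m=1
        est = estimate_ccf(rec("epithelial"), purity=1.0, total_cn=2)
        assert est.ccf == pytest.approx(1.0)
        assert est.multiplicity == 1

    def test_matches_exhaustive_oracle(self):
        """Dual route: enumerate every m and replicate the selection rule."""
        rng = np.random.default_rng(8)
        for _ in range(200):
            purity = float(rng.uniform(0.2, 1.0))
            cn = int(rng.integers(1, 7))
            depth = 500
            t_alt = int(rng.integers(0, depth + 1))
            r = rec("epithelial", t_ref=depth - t_alt, t_alt=t_alt)
            est = estimate_ccf(r, purity=purity, total_cn=cn)
            denom = purity * cn + (1 - purity) * 2
            cands = [(m, r.vaf * denom / (purity * m)) for m in range(1, cn + 1)]
            best = min(cands, key=lambda mc: (max(0.0, mc[1] - 1.0), mc[0]))
            assert est.multiplicity == best[0]
            assert est.ccf == pytest.approx(best[1])
            assert 0.0 <= est.clipped_ccf <= 1.0

    def test_expected_vaf_inverts_estimate(self):
        for purity, cn, m, ccf in [(0.8, 3, 2, 0.6), (0.5, 2, 1, 1.0), (1.0, 4, 1, 0.3)]:
            vaf = expected_vaf(ccf, purity, cn, m)
            denom = purity * cn + (1 - purity) * 2
            assert vaf * denom / (purity * m) == pytest.approx(ccf)

    def test_no_segment_defaults_cn2_with_warning(self, toy_assembly):
        profile = bp.SegmentProfile("S1", [bp.Segment("2", 1, 100, 3, 1)], 0.8, 2.0)
        with pytest.warns(UserWarning, match="outside any segment"):
            est = estimate_ccf(rec("epithelial", chrom="1"), profile=profile)
        assert est.total_cn == 2

    def test_segment_cn_used(self):
        profile = bp.SegmentProfile(
            "S1", [bp.Segment("1", 1, 10_000, 4, 1)], 0.8, 2.0
        ).canonicalize()
        est = estimate_ccf(rec("epithelial"), profile=profile)
        assert est.total_cn == 4

    def test_bad_purity_rejected(self):
        with pytest.raises(ValueError, match="purity"):
            estimate_ccf(rec("epithelial"), purity=0.0, total_cn=2)


def quick_config(seed=0):
    return bp.RunConfig(mcmc_iterations=2000, mcmc_burn_in=1000, rng_seed=seed)


def fit_planted(clusters, seed, depth=500, purity_a=0.8, purity_b=0.7,
                config=None, assembly=None):
    assembly = assembly or bp.load_assembly("toy")
    records, truth = sim.simulate_paired_components(
        clusters, purity_a, purity_b, depth, seed=seed
    )
    pairs = pair_mutations(records)
    retained, _ = filter_for_decomposition(pairs)
    profiles = {
        "epithelial": sim.flat_segment_profile("S1", assembly, purity_a),
        "mesenchymal": sim.flat_segment_profile("S1", assembly, purity_b),
    }
    model = CcfClusterModel(retained, profiles, config=config or quick_config(seed))
    return model.fit(seed=seed + 1), truth


class TestClustering:
    def test_single_truncal_cluster(self):
        res, _ = fit_planted([(1.0, 1.0, 40)], seed=2)
        assert res.n_clusters == 1
        cl = res.clusters[0]
        assert cl.ccf["epithelial"] == pytest.approx(1.0, abs=0.08)
        assert cl.ccf["mesenchymal"] == pytest.approx(1.0, abs=0.08)

    def test_three_planted_clusters_recovered(self):
        planted = [(1.0, 1.0, 40), (0.7, 0.05, 40), (0.05, 0.6, 40)]
        res, truth = fit_planted(planted, seed=5)
        assert res.n_clusters == 3
        # match planted to recovered by nearest mean CCF
        for ccf_a, ccf_b, _ in planted:
            best = min(
                res.clusters,
                key=lambda cl: abs(cl.ccf["epithelial"] - ccf_a)
                + abs(cl.ccf["mesenchymal"] - ccf_b),
            )
            assert cl_close(best, ccf_a, ccf_b, tol=0.1)

    def test_cluster_membership_matches_truth(self):
        planted = [(1.0, 1.0, 30), (0.1, 0.8, 30)]
        res, truth = fit_planted(planted, seed=9)
        assert res.n_clusters == 2
        # mutations planted together must land together
        labels = res.assignments
        for k in range(2):
            idx = [i for i, a in enumerate(truth.cluster_assignment) if a == k]
            assert len({labels[i] for i in idx}) == 1

    def test_deterministic_given_seed(self):
        r1, _ = fit_planted([(1.0, 1.0, 20), (0.3, 0.9, 20)], seed=4)
        r2, _ = fit_planted([(1.0, 1.0, 20), (0.3, 0.9, 20)], seed=4)
        assert np.array_equal(r1.assignments, r2.assignments)
        assert r1.summary().equals(r2.summary())

    def test_summary_has_ci_columns(self):
        res, _ = fit_planted([(1.0, 1.0, 25)], seed=3)
        df = res.summary()
        assert {"cluster", "size", "ccf_epithelial", "ccf_mesenchymal"} <= set(df.columns)
        assert df["ccf_epithelial_ci"].str.match(r"\[.*, .*\]").all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no retained"):
            CcfClusterModel([], {})


def cl_close(cluster, ccf_a, ccf_b, tol=0.1):
    return (
        abs(cluster.ccf["epithelial"] - ccf_a) <= tol
        and abs(cluster.ccf["mesenchymal"] - ccf_b) <= tol
    )


def mk_cluster(cid, size, ccf_a, ccf_b):
    return CloneCluster(
        cluster_id=cid,
        member_keys=[("1", 1000 * (cid + 1) + i, "A", "C") for i in range(size)],
        size=size,
        ccf={"epithelial": ccf_a, "mesenchymal": ccf_b},
        ccf_ci={"epithelial": (ccf_a, ccf_a), "mesenchymal": (ccf_b, ccf_b)},
    )


class TestTruncalAndSelection:
    def test_truncal_label(self):
        clusters = [mk_cluster(0, 30, 1.0, 0.98), mk_cluster(1, 10, 0.4, 0.1)]
        labels = classify_truncal(clusters)
        assert labels == {0: "truncal", 1: "branch"}

    def test_tolerance_boundary(self):
        clusters = [mk_cluster(0, 30, 1.0, 1.0), mk_cluster(1, 10, 0.91, 0.95)]
        assert classify_truncal(clusters)[1] == "truncal"
        clusters[1].ccf["epithelial"] = 0.89
        assert classify_truncal(clusters)[1] == "branch"

    def test_selection_direction(self):
        # minor in epithelial (A), dominant in mesenchymal (B)
        clusters = [mk_cluster(0, 30, 1.0, 1.0), mk_cluster(1, 12, 0.2, 0.9)]
        verdict, evidence = detect_clonal_selection(clusters)
        assert verdict == "selection_in_B"
        assert evidence.cluster_id == 1
        # mirrored
        clusters[1].ccf = {"epithelial": 0.9, "mesenchymal": 0.2}
        verdict, _ = detect_clonal_selection(clusters)
        assert verdict == "selection_in_A"

    def test_truncal_cluster_never_evidence(self):
        clusters = [mk_cluster(0, 30, 1.0, 1.0)]
        verdict, evidence = detect_clonal_selection(clusters)
        assert verdict == "none" and evidence is None

    def test_cutoffs_respected(self):
        clusters = [mk_cluster(0, 30, 1.0, 1.0), mk_cluster(1, 12, 0.35, 0.9)]
        assert detect_clonal_selection(clusters)[0] == "none"  # 0.35 > 0.3
        assert detect_clonal_selection(clusters, minor_cutoff=0.4)[0] == "selection_in_B"

    def test_end_to_end_selection_detected(self):
        planted = [(1.0, 1.0, 40), (0.1, 0.85, 40)]
        res, _ = fit_planted(planted, seed=12)
        labels = classify_truncal(res.clusters)
        verdict, evidence = detect_clonal_selection(res.clusters, labeling=labels)
        assert verdict == "selection_in_B"
        assert evidence.size == 40


class TestCloneTree:
    def test_lengths_and_newick(self):
        clusters = [
            mk_cluster(0, 25, 1.0, 1.0),
            mk_cluster(1, 7, 0.8, 0.1),
            mk_cluster(2, 4, 0.05, 0.6),
        ]
        tree = build_component_tree(clusters, classify_truncal(clusters))
        assert tree.trunk_length == 25
        assert tree.branch_lengths == {"epithelial": 7, "mesenchymal": 4}
        assert tree.to_newick() == "(epithelial:7,mesenchymal:4)trunk:25;"

    def test_newick_parses_with_biopython(self):
        from Bio import Phylo

        tree = CloneTree(trunk_length=12, branch_lengths={"epithelial": 3, "mesenchymal": 5})
        parsed = Phylo.read(io.StringIO(tree.to_newick()), "newick")
        leaves = {t.name: t.branch_length for t in parsed.get_terminals()}
        assert leaves == {"epithelial": 3.0, "mesenchymal": 5.0}
        assert parsed.root.branch_length == 12.0

    def test_tie_goes_to_first_component(self):
        clusters = [mk_cluster(0, 10, 1.0, 1.0), mk_cluster(1, 6, 0.5, 0.5)]
        tree = build_component_tree(clusters, classify_truncal(clusters))
        assert tree.branch_lengths == {"epithelial": 6, "mesenchymal": 0}
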