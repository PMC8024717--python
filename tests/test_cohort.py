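"""Cohort statistics: enumeration oracles, FDR properties, cohort wrappers."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import biphasic as bp
from biphasic.cohort import (
    CohortTable,
    benjamini_hochberg,
    classify_pathogenic,
    compare_continuous,
    compare_frequency,
    fisher_test,
    load_pathway_gene_sets,
    mutation_burden,
    pathway_alteration_summary,
)

from conftest import make_snv


def oracle_fisher_p(table):
    """Exact two-sided Fisher p by complete enumeration: sum of probabilities
    of all tables with the same margins whose hypergeometric probability does
    not exceed the observed one (scipy's two-sided convention)."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-10):
            total += p
    return total


def oracle_mw_p(a, b):
    """Exact two-sided Mann-Whitney p by complete enumeration of group-A
    position sets (tie-free data only)."""
    pooled = sorted(a + b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1, n2 = len(a), len(b)
    u_obs = sum(ranks[v] for v in a) - n1 * (n1 + 1) / 2
    us = []
    for positions in itertools.combinations(range(1, n1 + n2 + 1), n1):
        us.append(sum(positions) - n1 * (n1 + 1) / 2)
    us = np.asarray(us)
    p_le = (us <= u_obs).mean()
    p_ge = (us >= u_obs).mean()
    return min(1.0, 2 * min(p_le, p_ge))


class TestFisher:
    def test_matches_enumeration_oracle(self):
        tables = [
            [[24, 11], [51, 4]],
            [[3, 7], [6, 2]],
            [[0, 5], [5, 0]],
            [[10, 10], [10, 10]],
            [[1, 0], [0, 1]],
        ]
        for t in tables:
            _, p = fisher_test(t)
            assert p == pytest.approx(oracle_fisher_p(t), rel=1e-9)

    def test_balanced_table_p_one(self):
        _, p = fisher_test([[5, 5], [5, 5]])
        assert p == 1.0

    def test_bad_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_test([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(ValueError):
            fisher_test([[1, -2], [3, 4]])


class TestMannWhitney:
    def test_matches_enumeration_oracle_small_groups(self):
        rng = np.random.default_rng(14)
        for _ in range(10):
            n1, n2 = int(rng.integers(3, 7)), int(rng.integers(3, 7))
            pooled = rng.choice(1000, size=n1 + n2, replace=False).astype(float)
            a, b = list(pooled[:n1]), list(pooled[n1:])
            _, p = compare_continuous(a, b)
            assert p == pytest.approx(oracle_mw_p(a, b), rel=1e-9)

    def test_identical_distributions_high_p(self):
        a = list(range(0, 20, 2))
        b = list(range(1, 21, 2))
        _, p = compare_continuous(a, b)
        assert p > 0.5

    def test_separated_distributions_low_p(self):
        _, p = compare_continuous(list(range(10)), list(range(100, 110)))
        assert p < 1e-3

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_continuous([], [1.0])


class TestBenjaminiHochberg:
    def test_hand_computed_example(self):
        p = [0.01, 0.02, 0.03, 0.04]
        # q_i = min over j>=i of p_(j) * m / j (sorted), here:
        # 0.01*4/1=0.04, 0.02*4/2=0.04, 0.03*4/3=0.04, 0.04*4/4=0.04
        np.testing.assert_allclose(benjamini_hochberg(p), [0.04, 0.04, 0.04, 0.04])

    def test_matches_direct_step_up_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            p = rng.uniform(size=int(rng.integers(1, 30)))
            q = benjamini_hochberg(p)
            order = np.argsort(p)
            m = p.size
            adj = p[order] * m / np.arange(1, m + 1)
            adj = np.minimum.accumulate(adj[::-1])[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(adj, 1.0)
            np.testing.assert_allclose(q, expected, rtol=1e-12)

    def test_q_at_least_p_and_order_preserved(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=50)
        q = benjamini_hochberg(p)
        assert (q >= p - 1e-15).all()
        assert (q <= 1.0).all()
        # BH preserves the p-value ordering of q-values
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_bad_p_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])

    def test_empty_family(self):
        assert benjamini_hochberg([]).size == 0


class TestBurdenAndPathogenicity:
    def test_burden_per_mb(self):
        assert mutation_burden(300, 150, 30.0) == (10.0, 5.0)

    def test_bad_capture_rejected(self):
        with pytest.raises(ValueError):
            mutation_burden(10, 5, 0.0)

    def test_hotspot_always_pathogenic(self):
        assert classify_pathogenic(make_snv(gene="PIK3CA", hotspot_flag=True))

    def test_lof_in_tumor_suppressor(self):
        roles = {"TP53": "tumor_suppressor", "KRAS": "oncogene"}
        assert classify_pathogenic(make_snv(gene="TP53", effect="nonsense"), roles)
        assert not classify_pathogenic(
            make_snv(gene="TP53", effect="nonsynonymous_missense"), roles
        )
        assert not classify_pathogenic(make_snv(gene="KRAS", effect="nonsense"), roles)

    def test_unknown_role_string_rejected(self):
        with pytest.raises(ValueError, match="unknown gene role"):
            classify_pathogenic(make_snv(gene="X"), {"X": "driver"})


def make_cohort(n_a=6, n_b=6, hyper=(), alterations=()):
    ids = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
    samples = pd.DataFrame(
        {
            "group": ["grpA"] * n_a + ["grpB"] * n_b,
            "total_mutations": np.arange(len(ids)) * 13 + 40,
            "nonsyn_mutations": np.arange(len(ids)) * 7 + 20,
            "capture_mb": 30.0,
            "hypermutated": [sid in hyper for sid in ids],
        },
        index=pd.Index(ids, name="sample_id"),
    )
    alt = pd.DataFrame(
        list(alterations), columns=["sample_id", "gene", "alteration_class", "pathogenic"]
    )
    return CohortTable(samples=samples, alterations=alt)


class TestCohortTable:
    def test_hypermutated_blocks_comparisons(self):
        cohort = make_cohort(hyper=("A0",))
        with pytest.raises(ValueError, match="hypermutated"):
            cohort.continuous_comparison("total_mutations")
        cleaned = cohort.exclude_hypermutated()
        assert "A0" not in cleaned.samples.index
        cleaned.continuous_comparison("total_mutations")  # no raise

    def test_two_group_requirement(self):
        cohort = make_cohort(n_b=0)
        with pytest.raises(ValueError, match="two nonempty groups"):
            cohort._require_comparable()

    def test_gene_frequency_matches_manual_table(self):
        alts = [("A0", "TP53", "mutation", True), ("A1", "TP53", "mutation", False),
                ("B0", "TP53", "mutation", True)]
        cohort = make_cohort(alterations=alts)
        df = cohort.gene_frequency_comparison(["TP53"])
        row = df.iloc[0]
        assert row["frac_grpA"] == pytest.approx(2 / 6)
        assert row["frac_grpB"] == pytest.approx(1 / 6)
        _, expected_p = fisher_test([[2, 4], [1, 5]])
        assert row["p"] == pytest.approx(expected_p)

    def test_group_label_swap_preserves_p(self):
        alts = [("A0", "G1", "mutation", True), ("B0", "G1", "mutation", True),
                ("B1", "G1", "mutation", True)]
        c1 = make_cohort(alterations=alts)
        swapped = c1.samples.copy()
        swapped["group"] = swapped["group"].map({"grpA": "grpB", "grpB": "grpA"})
        c2 = CohortTable(samples=swapped, alterations=c1.alterations)
        p1 = c1.gene_frequency_comparison(["G1"])["p"].iloc[0]
        p2 = c2.gene_frequency_comparison(["G1"])["p"].iloc[0]
        assert p1 == pytest.approx(p2)

    def test_alterations_for_unknown_sample_rejected(self):
        with pytest.raises(ValueError, match="unknown samples"):
            make_cohort(alterations=[("Z9", "TP53", "mutation", True)])

    def test_fdr_family_is_single_call(self):
        tables = {
            "G1": ((5, 1), (0, 6)),
            "G2": ((3, 3), (3, 3)),
            "G3": ((6, 0), (1, 5)),
        }
        df = compare_frequency(tables)
        q = benjamini_hochberg(df["p"])
        np.testing.assert_allclose(df["q"], q)


class TestPathways:
    def test_packaged_sets_load(self):
        sets = load_pathway_gene_sets()
        assert set(sets) == {"p53", "PI3K", "Wnt", "Notch"}
        assert "TP53" in sets["p53"]
        assert "PIK3CA" in sets["PI3K"]

    def test_fraction_computation(self):
        alts = [
            ("A0", "TP53", "mutation", True),
            ("A1", "TP53", "mutation", False),
            ("B0", "MDM2", "amplification", True),
        ]
        cohort = make_cohort(alterations=alts)
        summary = pathway_alteration_summary(cohort, {"p53": ["TP53", "MDM2"]})
        by = summary.set_index("group")
        assert by.loc["grpA", "frac_altered"] == pytest.approx(2 / 6)
        assert by.loc["grpA", "frac_pathogenic"] == pytest.approx(1 / 6)
        assert by.loc["grpB", "frac_altered"] == pytest.approx(1 / 6)

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError, match="empty gene set"):
            pathway_alteration_summary(make_cohort(), {"p53": []})
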