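"""Differential expression, overlap, and pathway over-representation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_config
from metorgan.de import de_test, deg_overlap, mets_vs_kidney, ora_hypergeometric, per_site_deg
from metorgan.stats import mann_whitney
from metorgan.synth import generate_cohort


def mw_permutation_oracle(x, y):
    """Two-sided Mann-Whitney p from the full permutation null of U."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sum(xi > yj for xi in x for yj in y)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        us.append(sum(xi > yj for xi in xs for yj in ys))
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_le, p_ge))


class TestMannWhitney:
    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 6), (5, 5), (7, 4), (6, 7)])
    def test_exact_branch_matches_permutation_oracle(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(3):
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            assert mann_whitney(x, y) == pytest.approx(mw_permutation_oracle(x, y), abs=1e-10)

    def test_all_identical_values_give_p_one(self):
        assert mann_whitney([2.0, 2.0, 2.0], [2.0, 2.0]) == 1.0

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([1.0], [2.0, 3.0])


class TestDeTest:
    def _expr(self, rng, n_genes=30, nA=10, nB=10, shift_genes=(), shift=0.0):
        A = rng.lognormal(3, 0.5, size=(n_genes, nA))
        B = rng.lognormal(3, 0.5, size=(n_genes, nB))
        genes = [f"g{i}" for i in range(n_genes)]
        for g in shift_genes:
            B[genes.index(g)] *= 2.0**shift
        cols = [f"A{i}" for i in range(nA)] + [f"B{i}" for i in range(nB)]
        return (
            pd.DataFrame(np.hstack([A, B]), index=genes, columns=cols),
            cols[:nA],
            cols[nA:],
        )

    def test_identical_gene_has_zero_fc_p_one(self):
        expr = pd.DataFrame(
            [[5.0] * 8, [1, 2, 3, 4, 5, 6, 7, 8]],
            index=["flat", "vary"],
            columns=[f"s{i}" for i in range(8)],
        )
        res = de_test(expr, [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)])
        assert res.loc["flat", "log2fc"] == 0.0
        assert res.loc["flat", "p_raw"] == 1.0

    def test_overlapping_groups_rejected(self):
        expr, A, B = self._expr(np.random.default_rng(0))
        with pytest.raises(ValueError, match="disjoint"):
            de_test(expr, A, A[:2] + B)

    def test_log2fc_antisymmetric_under_group_swap(self):
        expr, A, B = self._expr(np.random.default_rng(1))
        fwd = de_test(expr, A, B)
        rev = de_test(expr, B, A)
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-12)
        np.testing.assert_allclose(fwd["p_raw"], rev["p_raw"], atol=1e-12)

    def test_planted_genes_recovered(self):
        rng = np.random.default_rng(5)
        planted = [f"g{i}" for i in range(5)]
        expr, A, B = self._expr(rng, n_genes=60, nA=40, nB=40, shift_genes=planted, shift=2.0)
        res = de_test(expr, A, B)
        assert (res.loc[planted, "flag"] == "up").all()

    def test_bh_flag_count_monotone_in_alpha(self):
        expr, A, B = self._expr(np.random.default_rng(7), n_genes=80, nA=20, nB=20)
        counts = [
            (de_test(expr, A, B, alpha=a)["flag"] != "ns").sum() for a in (0.2, 0.05, 0.01)
        ]
        assert counts[0] >= counts[1] >= counts[2]


class TestPerSiteAndOverlap:
    def test_empty_site_errors(self, small_cohort):
        with pytest.raises(ValueError):
            per_site_deg(small_cohort.expression, small_cohort.samples, "skin")

    def test_planted_shared_degs_land_in_triple_intersection(self):
        # metastasis-wide planted program: up-genes and a down-gene shared
        # by lung, bone and liver (each vs kidney)
        cfg = make_config(
            {"kidney": 40, "lung": 20, "bone": 20, "liver": 20},
            seed=31,
            deg_effects={"ASPN": 2.0, "TTC14": 2.0, "REN": -3.0},
        )
        cohort = generate_cohort(cfg)
        de_by_site = {
            s: per_site_deg(cohort.expression, cohort.samples, s)
            for s in ("lung", "bone", "liver")
        }
        regions = deg_overlap(de_by_site)
        triple = frozenset({"lung", "bone", "liver"})
        assert {"ASPN", "TTC14"} <= regions["up"].get(triple, set())
        assert "REN" in regions["down"].get(triple, set())

    def test_identical_deg_lists_fall_entirely_in_triple_intersection(self):
        df = pd.DataFrame(
            {"flag": ["up", "down", "ns"]}, index=["g1", "g2", "g3"]
        )
        regions = deg_overlap({"a": df, "b": df, "c": df})
        triple = frozenset({"a", "b", "c"})
        assert regions["up"] == {triple: {"g1"}}
        assert regions["down"] == {triple: {"g2"}}

    def test_disjoint_lists_have_no_shared_regions(self):
        d1 = pd.DataFrame({"flag": ["up"]}, index=["g1"])
        d2 = pd.DataFrame({"flag": ["up"]}, index=["g2"])
        regions = deg_overlap({"a": d1, "b": d2})
        assert regions["up"] == {frozenset({"a"}): {"g1"}, frozenset({"b"}): {"g2"}}

    def test_two_sites_required(self):
        with pytest.raises(ValueError):
            deg_overlap({"a": pd.DataFrame({"flag": []})})


class TestOra:
    def test_pathway_equal_to_universe_gives_p_one(self):
        universe = [f"g{i}" for i in range(30)]
        res = ora_hypergeometric(universe[:5], universe, {"all": universe})
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_zero_overlap_gives_p_one_bounded(self):
        universe = [f"g{i}" for i in range(30)]
        res = ora_hypergeometric(universe[:5], universe, {"rest": universe[10:]})
        assert res["p"].iloc[0] <= 1.0
        assert res["k"].iloc[0] == 0

    def test_matches_combinatorial_enumeration(self):
        # p = P(X >= k) computed by direct tail sum of C(K,x) C(N-K,n-x) / C(N,n)
        universe = [f"g{i}" for i in range(20)]
        pathway = universe[:8]
        deg = universe[:4] + universe[10:12]  # k=4 of pathway, n=6
        N, K, n, k = 20, 8, 6, 4
        tail = sum(
            math.comb(K, x) * math.comb(N - K, n - x) for x in range(k, min(K, n) + 1)
        ) / math.comb(N, n)
        res = ora_hypergeometric(deg, universe, {"pw": pathway})
        assert res["p"].iloc[0] == pytest.approx(tail, abs=1e-12)

    def test_deg_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            ora_hypergeometric(["zz"], ["g1", "g2"], {"pw": ["g1"]})

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            ora_hypergeometric([], [], {"pw": ["g1"]})

    def test_sorted_ascending_p(self):
        rng = np.random.default_rng(4)
        universe = [f"g{i}" for i in range(50)]
        deg = list(rng.choice(universe, 10, replace=False))
        sets = {f"pw{i}": list(rng.choice(universe, 12, replace=False)) for i in range(6)}
        res = ora_hypergeometric(deg, universe, sets)
        assert (res["p"].diff().dropna() >= -1e-12).all()


def test_mets_vs_kidney_uses_site_class(small_cohort):
    res = mets_vs_kidney(small_cohort.expression, small_cohort.samples)
    assert len(res) == small_cohort.expression.shape[0]
    # the planted metastasis program should surface: REN down, ASPN up
    assert res.loc["REN", "flag"] == "down"
    assert res.loc["ASPN", "flag"] == "up"
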