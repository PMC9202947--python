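import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_matrix, table_from_matrix
import oracles

from refstab import (
    bestkeeper,
    cv_method,
    delta_ct_method,
    genorm,
    genorm_pairwise_variation,
    normfinder,
)
from refstab.stability import METHODS


class TestBestKeeper:
    def test_constant_gene_is_perfectly_stable(self):
        t = table_from_matrix({"A": [20.0] * 4, "B": [18, 19, 20, 21.0], "C": [25, 25, 26, 26.0]})
        r = bestkeeper(t)
        assert r.scores["A"] == 0.0
        assert r.extras.loc["A", "cv_pct"] == 0.0
        assert bool(r.extras.loc["A", "accepted"])
        assert r.ranking[0] == "A"

    def test_hand_computed_sd_and_cv(self):
        t = table_from_matrix({"A": [15.0, 16, 17, 18, 19, 20], "B": [20.0] * 6})
        r = bestkeeper(t)
        assert r.scores["A"] == pytest.approx(1.8708, abs=1e-4)
        assert r.extras.loc["A", "cv_pct"] == pytest.approx(10.69, abs=0.01)
        assert not bool(r.extras.loc["A", "accepted"])  # SD > 1 cycle

    def test_mad_geo_variant_available(self):
        t = table_from_matrix({"A": [20.0, 21, 22, 23], "B": [25.0] * 4})
        r = bestkeeper(t, variant="mad_geo")
        geo = np.exp(np.mean(np.log([20.0, 21, 22, 23])))
        expect = np.mean(np.abs(np.array([20.0, 21, 22, 23]) - geo))
        assert r.scores["A"] == pytest.approx(expect, abs=1e-12)

    def test_single_sample_rejected(self):
        t = table_from_matrix({"A": [20.0], "B": [25.0]}, groups=["egg"])
        with pytest.raises(ValueError):
            bestkeeper(t)


class TestCvMethod:
    def test_constant_gene_zero(self):
        t = table_from_matrix({"A": [20.0] * 3, "B": [21, 22, 23.0], "C": [25, 26, 27.0]})
        assert cv_method(t).scores["A"] == 0.0

    def test_hand_computed_quantity_cv(self):
        """Ct (20,21,22) -> Q (1, 1/2, 1/4) -> CV 65.47%."""
        t = table_from_matrix({"A": [20.0, 21.0, 22.0], "B": [30.0] * 3})
        assert cv_method(t).scores["A"] == pytest.approx(65.465, abs=1e-2)

    def test_efficiency_base_changes_scale(self):
        t = table_from_matrix({"A": [20.0, 21.0, 22.0], "B": [30.0] * 3})
        low = cv_method(t, efficiencies={"A": 80.0, "B": 80.0})
        assert low.scores["A"] < cv_method(t).scores["A"]


class TestDeltaCt:
    def test_hand_computed_pair_sds(self):
        t = table_from_matrix(
            {"A": [20.0, 21, 22], "B": [25.0, 26, 27], "C": [30.0, 30, 31]}
        )
        r = delta_ct_method(t)
        assert r.scores["A"] == pytest.approx(0.28868, abs=1e-4)
        assert r.scores["B"] == pytest.approx(0.28868, abs=1e-4)
        assert r.scores["C"] == pytest.approx(0.57735, abs=1e-4)

    def test_covarying_panel_scores_zero(self):
        base = np.array([20.0, 21.5, 19.5, 22.0])
        t = table_from_matrix({g: list(base + off) for g, off in [("A", 0), ("B", 3), ("C", 7)]})
        assert np.allclose(delta_ct_method(t).scores, 0.0)

    def test_requires_three_genes(self):
        t = table_from_matrix({"A": [20.0, 21], "B": [25.0, 26]})
        with pytest.raises(ValueError):
            delta_ct_method(t)


class TestGeNorm:
    def test_covarying_final_pair_has_zero_m(self):
        t = table_from_matrix(
            {
                "A": [20.0, 21, 22, 23],
                "B": [22.0, 23, 24, 25],  # A + 2 exactly
                "C": [30.0, 28, 33, 29],
            }
        )
        r = genorm(t)
        assert r.metadata["best_pair"] == ("A", "B")
        assert r.metadata["best_pair_m"] == pytest.approx(0.0, abs=1e-12)
        assert r.metadata["elimination_order"] == ("C",)

    def test_elimination_matches_naive_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            mat = random_matrix(rng, rng.integers(3, 8), rng.integers(4, 13))
            t = table_from_matrix(mat)
            r = genorm(t)
            order, pair, m_at_drop = oracles.genorm_elimination(mat)
            assert r.metadata["elimination_order"] == tuple(order)
            assert r.metadata["best_pair"] == pair
            for g in mat:
                assert r.scores[g] == pytest.approx(m_at_drop[g], abs=1e-9)

    def test_tie_removes_lexicographically_later_gene(self):
        base = [20.0, 21, 22, 23]
        t = table_from_matrix(
            {"A": base, "B": [x + 1 for x in base], "Z": [x + 2 for x in base]}
        )
        # all pairwise V = 0: tie at every M; the later id is dropped first
        r = genorm(t)
        assert r.metadata["elimination_order"] == ("Z",)
        assert r.metadata["best_pair"] == ("A", "B")

    def test_elimination_never_raises_mean_pairwise_variation(self):
        """Removing the worst gene cannot raise the survivors' mean M."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            mat = random_matrix(rng, rng.integers(4, 8), rng.integers(4, 10))
            surviving = list(mat)
            while len(surviving) > 2:
                mv = oracles.genorm_m({g: mat[g] for g in surviving})
                worst = max(surviving, key=lambda g: (mv[g], g))
                before = np.mean([mv[g] for g in surviving if g != worst])
                surviving.remove(worst)
                after = np.mean(
                    list(oracles.genorm_m({g: mat[g] for g in surviving}).values())
                )
                assert after <= before + 1e-12

    def test_m_threshold_flags(self):
        rng = np.random.default_rng(0)
        mat = {
            "A": list(20 + rng.normal(0, 0.05, 6)),
            "B": list(22 + rng.normal(0, 0.05, 6)),
            "C": list(24 + rng.normal(0, 0.05, 6)),
            "D": list(18 + rng.normal(0, 3.0, 6)),
        }
        r = genorm(table_from_matrix(mat))
        assert bool(r.extras.loc["A", "suitable"])
        assert not bool(r.extras.loc["D", "suitable"])


class TestPairwiseVariation:
    def test_covarying_panel_recommends_two(self):
        base = np.array([20.0, 21, 19, 22, 20.5, 21.5])
        t = table_from_matrix(
            {g: list(base + off) for g, off in [("A", 0), ("B", 2), ("C", 5), ("D", 8)]}
        )
        curve = genorm_pairwise_variation(t)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in curve.v.values())
        assert curve.recommended_n == 2

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            mat = random_matrix(rng, rng.integers(3, 8), rng.integers(4, 13))
            t = table_from_matrix(mat)
            r = genorm(t)
            curve = genorm_pairwise_variation(t, ranking=r)
            expect = oracles.pairwise_variation(mat, list(r.ranking))
            for n, v in curve.v.items():
                assert v == pytest.approx(expect[n], abs=1e-9)

    def test_no_v_below_threshold_recommends_all(self):
        rng = np.random.default_rng(5)
        mat = {f"g{i}": list(20 + rng.normal(0, 2.0, 6)) for i in range(4)}
        curve = genorm_pairwise_variation(table_from_matrix(mat), threshold=1e-6)
        assert curve.recommended_n == 4

    def test_foreign_ranking_rejected(self):
        t = table_from_matrix(
            {"A": [20.0, 21, 22], "B": [25.0, 26, 27], "C": [30.0, 30, 31]}
        )
        with pytest.raises(ValueError):
            genorm_pairwise_variation(t, ranking=["A", "B", "X"])


class TestNormFinder:
    def test_all_constant_gives_equal_minimal_scores(self):
        t = table_from_matrix(
            {"A": [20.0] * 6, "B": [22.0] * 6, "C": [24.0] * 6}
        )
        r = normfinder(t)
        assert np.allclose(r.scores, 0.0)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(15):
            n_s = int(rng.integers(4, 13))
            mat = random_matrix(rng, int(rng.integers(3, 8)), n_s)
            groups = ["egg"] * (n_s // 2) + ["cortex"] * (n_s - n_s // 2)
            t = table_from_matrix(mat, groups=groups)
            r = normfinder(t)
            expect = oracles.normfinder_rho(mat, groups)
            for g in mat:
                assert r.scores[g] == pytest.approx(expect[g], abs=1e-9)

    def test_designed_intergroup_shift_is_recovered(self):
        """A 1-cycle egg/cortex shift yields the largest |d| and the largest
        stability value, and the shift estimate is unbiased over seeds."""
        d_hats = []
        top = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            mat = {
                g: list(22 + rng.normal(0, 0.2, 6)) for g in ("A", "B", "C", "D")
            }
            shifted = 22 + rng.normal(0, 0.2, 6)
            shifted[3:] += 1.0  # cortex samples up 1 cycle
            mat["E"] = list(shifted)
            t = table_from_matrix(mat)
            r = normfinder(t)
            d_egg = r.extras["d_egg"]
            top += (d_egg.abs().idxmax() == "E") and (r.ranking[-1] == "E")
            d_hats.append(d_egg["E"])
        # true d: (delta - mean delta)/2 = (1 - 1/5)/2 = 0.4 on the log2 scale
        assert np.mean(d_hats) == pytest.approx(0.4, abs=3 * np.std(d_hats) / np.sqrt(n_seeds))
        assert top / n_seeds > 0.95  # shifted gene flagged least stable

    def test_group_requirements(self):
        t = table_from_matrix(
            {"A": [20.0, 21, 22], "B": [25.0, 26, 27], "C": [30.0, 30, 31]},
            groups=["egg", "egg", "cortex"],
        )
        with pytest.raises(ValueError, match="< 2 samples"):
            normfinder(t)
        t3 = table_from_matrix(
            {"A": [20.0] * 6, "B": [22.0] * 6, "C": [24.0] * 6},
            groups=["a", "a", "b", "b", "c", "c"],
        )
        with pytest.raises(ValueError, match="2 groups"):
            normfinder(t3)

    def test_best_pair_reported(self):
        rng = np.random.default_rng(8)
        mat = {
            "A": list(20 + rng.normal(0, 0.1, 6)),
            "B": list(22 + rng.normal(0, 0.1, 6)),
            "C": list(24 + rng.normal(0, 1.5, 6)),
            "D": list(26 + rng.normal(0, 1.5, 6)),
        }
        mat["C"] = [x + (1.5 if i >= 3 else 0) for i, x in enumerate(mat["C"])]
        r = normfinder(table_from_matrix(mat))
        assert set(r.metadata["best_pair"]) <= set(mat)
        assert r.metadata["best_pair_score"] >= 0


matrix_seeds = st.integers(min_value=0, max_value=10_000)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=matrix_seeds)
def test_gene_shift_invariance(seed):
    """Adding a constant to one gene's Ct leaves every stability score
    unchanged (BestKeeper's CV%, a ratio to mean Ct, is the lone exception)."""
    rng = np.random.default_rng(seed)
    mat = random_matrix(rng, int(rng.integers(3, 8)), int(rng.integers(4, 13)))
    shifted = dict(mat)
    gene = sorted(mat)[0]
    shifted[gene] = [x + 2.5 for x in mat[gene]]
    t0, t1 = table_from_matrix(mat), table_from_matrix(shifted)
    for name, fn in METHODS.items():
        s0, s1 = fn(t0).scores, fn(t1).scores
        assert np.allclose(s0.sort_index(), s1.sort_index(), atol=1e-9), name
    cv0 = bestkeeper(t0).extras["cv_pct"]
    cv1 = bestkeeper(t1).extras["cv_pct"]
    assert not np.isclose(cv0[gene], cv1[gene])


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=matrix_seeds)
def test_permutation_invariance(seed):
    """Reordering genes or samples permutes outputs without changing scores."""
    rng = np.random.default_rng(seed)
    n_s = int(rng.integers(4, 13))
    mat = random_matrix(rng, int(rng.integers(3, 8)), n_s)
    groups = ["egg"] * (n_s // 2) + ["cortex"] * (n_s - n_s // 2)
    perm_g = list(mat)[::-1]
    perm_s = list(rng.permutation(n_s))
    mat_p = {g: [mat[g][i] for i in perm_s] for g in perm_g}
    groups_p = [groups[i] for i in perm_s]
    t0 = table_from_matrix(mat, groups=groups)
    t1 = table_from_matrix(mat_p, groups=groups_p)
    for name, fn in METHODS.items():
        s0, s1 = fn(t0).scores.sort_index(), fn(t1).scores.sort_index()
        assert np.allclose(s0, s1, atol=1e-9), name


@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=matrix_seeds)
def test_optimized_matches_oracles(seed):
    """Vectorised estimators agree with loop-based definitions to 1e-9."""
    rng = np.random.default_rng(seed)
    n_s = int(rng.integers(4, 13))
    mat = random_matrix(rng, int(rng.integers(3, 8)), n_s)
    groups = ["egg"] * (n_s // 2) + ["cortex"] * (n_s - n_s // 2)
    t = table_from_matrix(mat, groups=groups)
    checks = {
        "bestkeeper": (bestkeeper(t).scores, oracles.bestkeeper_sd(mat)),
        "cv": (cv_method(t).scores, oracles.cv_of_quantities(mat)),
        "delta_ct": (delta_ct_method(t).scores, oracles.delta_ct_scores(mat)),
        "normfinder": (normfinder(t).scores, oracles.normfinder_rho(mat, groups)),
    }
    for name, (got, expect) in checks.items():
        for g in mat:
            assert got[g] == pytest.approx(expect[g], abs=1e-9), name
    gn = genorm(t)
    _, pair, m_at_drop = oracles.genorm_elimination(mat)
    assert gn.metadata["best_pair"] == pair
    for g in mat:
        assert gn.scores[g] == pytest.approx(m_at_drop[g], abs=1e-9)
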