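import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.cluster import hierarchy

from dppi import differential as dd
from dppi.synthetic_data import CohortSimConfig, simulate_cohort

from conftest import make_matrix, two_group_sheet


class TestModeratedT:
    def test_matches_pooled_variance_oracle(self):
        # independent hand evaluation: means 11 vs 15, pooled SE = sqrt(2/3)
        a, b = [10, 11, 12], [14, 15, 16]
        d, t, p = dd.moderated_t(a, b, s0=0.1)
        se = math.sqrt(2 / 3)
        assert t == pytest.approx(-4 / se, abs=1e-3)          # ~ -4.899
        assert d == pytest.approx(-4 / (se + 0.1), abs=1e-3)  # ~ -4.364
        assert p == pytest.approx(2 * stats.t.sf(4 / se, df=4), rel=1e-9)

    def test_s0_zero_reduces_to_classic_t(self, rng):
        a, b = rng.normal(0, 1, 5), rng.normal(0, 1, 6)
        d, t, _ = dd.moderated_t(a, b, s0=0.0)
        assert d == t

    def test_identical_groups_give_zero_and_p_one(self):
        d, t, p = dd.moderated_t([5.0, 5.0, 5.0], [5.0, 5.0, 5.0], s0=0.1)
        assert d == 0 and p == 1

    def test_moderation_shrinks_magnitude(self, rng):
        a, b = rng.normal(0, 1, 4), rng.normal(2, 1, 4)
        d, t, _ = dd.moderated_t(a, b, s0=0.5)
        assert abs(d) <= abs(t) and np.sign(d) == np.sign(t)

    def test_groups_smaller_than_two_error(self):
        with pytest.raises(ValueError):
            dd.moderated_t([1.0], [2.0, 3.0], s0=0.1)

    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=6),
           st.lists(st.floats(-50, 50), min_size=3, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_under_group_swap(self, a, b):
        d1, _, _ = dd.moderated_t(a, b, s0=0.1)
        d2, _, _ = dd.moderated_t(b, a, s0=0.1)
        assert d1 == pytest.approx(-d2, abs=1e-9)

    @given(shift=st.floats(-100, 100))
    @settings(max_examples=30, deadline=None)
    def test_location_invariance(self, shift):
        a, b = [20.0, 21.0, 22.5], [24.0, 23.1, 25.0]
        d1, t1, p1 = dd.moderated_t(a, b, s0=0.1)
        d2, t2, p2 = dd.moderated_t([x + shift for x in a],
                                    [x + shift for x in b], s0=0.1)
        assert d1 == pytest.approx(d2, abs=1e-8)
        assert p1 == pytest.approx(p2, abs=1e-8)


def brute_force_fdr(X, na, s0, fdr_target):
    """Independent exhaustive oracle: enumerate every label assignment,
    build the |d| null, apply the ratio-of-counts rule at each observed |d|."""
    n = X.shape[1]

    def dvec(ia):
        ia = list(ia)
        ib = [j for j in range(n) if j not in ia]
        A, B = X[:, ia], X[:, ib]
        diff = A.mean(1) - B.mean(1)
        sp2 = ((A.shape[1] - 1) * A.var(1, ddof=1) +
               (B.shape[1] - 1) * B.var(1, ddof=1)) / (n - 2)
        se = np.sqrt(sp2 * (1 / A.shape[1] + 1 / B.shape[1]))
        return diff / (se + s0)

    obs = np.abs(dvec(range(na)))
    null = np.array([np.abs(dvec(c))
                     for c in itertools.combinations(range(n), na)])
    sig = np.zeros(X.shape[0], bool)
    best_c = None
    for c in np.unique(obs):
        fdr_hat = null[null >= c].size / null.shape[0] / max(1, (obs >= c).sum())
        if fdr_hat <= fdr_target and (best_c is None or c < best_c):
            best_c = c
    if best_c is not None:
        sig = obs >= best_c
    return obs, sig


class TestPermutationFDR:
    def toy(self, rng, n_prot=5, na=3, nb=3, planted=0):
        X = rng.normal(25, 1, (n_prot, na + nb))
        X[:planted, :na] += 4.0
        sheet = two_group_sheet(na, nb)
        m = make_matrix(X, sample_ids=[r.sample_id for r in sheet], stage="imputed")
        return X, m, sheet

    def test_exhaustive_matches_brute_force_oracle(self, rng):
        # 3 vs 3: all 20 relabelings enumerated; must agree exactly
        for planted in (0, 2):
            X, m, sheet = self.toy(rng, planted=planted)
            res = dd.permutation_fdr(m, sheet, dd.DiffTestConfig(exhaustive=True))
            obs, sig = brute_force_fdr(X, 3, 0.1, 0.05)
            np.testing.assert_allclose(np.abs(res["d_moderated"]), obs, atol=1e-12)
            assert np.array_equal(res["significant"].to_numpy(), sig)

    def test_exhaustive_is_seed_independent(self, rng):
        _, m, sheet = self.toy(rng, planted=2)
        r1 = dd.permutation_fdr(m, sheet, dd.DiffTestConfig(seed=1, exhaustive=True))
        r2 = dd.permutation_fdr(m, sheet, dd.DiffTestConfig(seed=99, exhaustive=True))
        assert r1.equals(r2)

    def test_same_seed_bit_reproducible(self, rng):
        sheet = two_group_sheet(6, 6)
        X = rng.normal(25, 1, (50, 12))
        m = make_matrix(X, sample_ids=[r.sample_id for r in sheet], stage="imputed")
        cfg = dd.DiffTestConfig(seed=5, exhaustive=False, n_permutations=100)
        assert dd.permutation_fdr(m, sheet, cfg).equals(
            dd.permutation_fdr(m, sheet, cfg))

    def test_significant_set_monotone_in_fdr_target(self, rng):
        sheet = two_group_sheet(5, 5)
        X = rng.normal(25, 1, (60, 10))
        X[:10, :5] += 2.5
        m = make_matrix(X, sample_ids=[r.sample_id for r in sheet], stage="imputed")
        prev = set()
        for q in (0.01, 0.05, 0.1, 0.2):
            res = dd.permutation_fdr(m, sheet, dd.DiffTestConfig(fdr=q, seed=2))
            cur = set(np.flatnonzero(res["significant"]))
            assert prev <= cur
            prev = cur

    def test_small_design_warns_without_exhaustive(self, rng):
        sheet = two_group_sheet(2, 2)
        X = rng.normal(25, 1, (10, 4))
        m = make_matrix(X, sample_ids=[r.sample_id for r in sheet], stage="imputed")
        with pytest.warns(UserWarning, match="exhaustive"):
            dd.permutation_fdr(m, sheet,
                               dd.DiffTestConfig(exhaustive=False, n_permutations=20))

    def test_null_type_one_control(self, rng):
        # all proteins null: significant fraction stays near/below the target
        fracs = []
        for rep in range(15):
            sheet = two_group_sheet(13, 17)
            X = rng.normal(25, 1, (200, 30))
            m = make_matrix(X, sample_ids=[r.sample_id for r in sheet],
                            stage="imputed")
            res = dd.permutation_fdr(
                m, sheet, dd.DiffTestConfig(seed=rep, n_permutations=100))
            fracs.append(res["significant"].mean())
        assert np.mean(fracs) <= 0.07

    def test_power_on_planted_effects(self, rng):
        # 20 proteins at |log2 FC| = 2, SD 0.5, 13 vs 17; expect near-complete recovery
        hits = []
        for rep in range(3):
            sheet = two_group_sheet(13, 17)
            X = rng.normal(25, 0.5, (400, 30))
            X[:20, :13] += 2.0
            m = make_matrix(X, sample_ids=[r.sample_id for r in sheet],
                            stage="imputed")
            res = dd.permutation_fdr(
                m, sheet, dd.DiffTestConfig(seed=rep, n_permutations=150))
            hits.append(res["significant"].to_numpy()[:20].sum())
        assert np.mean(hits) >= 18

    def test_directions_follow_fold_change_sign(self, rng):
        sheet = two_group_sheet(4, 4)
        X = rng.normal(25, 0.3, (30, 8))
        X[:5, :4] += 3
        X[5:10, :4] -= 3
        m = make_matrix(X, sample_ids=[r.sample_id for r in sheet], stage="imputed")
        res = dd.permutation_fdr(m, sheet, dd.DiffTestConfig(seed=1))
        sig = res[res["significant"]]
        assert ((sig["direction"] == "up") == (sig["log2_fc"] > 0)).all()
        assert (res.loc[~res["significant"], "direction"] == "ns").all()


class TestVolcano:
    def test_classes_and_counts(self, rng):
        sheet = two_group_sheet(4, 4)
        X = rng.normal(25, 0.3, (30, 8))
        X[:5, :4] += 3
        m = make_matrix(X, sample_ids=[r.sample_id for r in sheet], stage="imputed")
        res = dd.permutation_fdr(m, sheet, dd.DiffTestConfig(seed=1))
        table, counts = dd.volcano_table(res)
        assert counts["up"] >= 1
        assert sum(counts.values()) == 30
        up = table[table["class"] == "up"]
        assert (up["log2_fc"] > 0).all()

    def test_all_ns_counts(self):
        import pandas as pd
        res = pd.DataFrame({"gene": list("abc"), "log2_fc": [0.1, -0.2, 0.0],
                            "p_value": [0.5, 0.9, 1.0],
                            "direction": ["ns"] * 3, "significant": [False] * 3})
        _, counts = dd.volcano_table(res)
        assert counts == {"up": 0, "down": 0, "ns": 3}

    def test_export_round_trip(self, tmp_path, rng):
        import pandas as pd
        sheet = two_group_sheet(3, 3)
        X = rng.normal(25, 1, (10, 6))
        m = make_matrix(X, sample_ids=[r.sample_id for r in sheet], stage="imputed")
        res = dd.permutation_fdr(m, sheet, dd.DiffTestConfig(seed=1))
        table, _ = dd.volcano_table(res)
        p = tmp_path / "v.tsv"
        table.to_csv(p, sep="\t", index=False)
        back = pd.read_csv(p, sep="\t")
        assert list(back.columns) == list(table.columns)
        np.testing.assert_allclose(back["log2_fc"], table["log2_fc"])


def brute_force_average_linkage(X):
    """O(n^3) agglomerative oracle over columns, Euclidean/average linkage."""
    cols = [[j] for j in range(X.shape[1])]
    dist = {(i, j): float(np.linalg.norm(X[:, i] - X[:, j]))
            for i in range(X.shape[1]) for j in range(i + 1, X.shape[1])}

    def cdist(a, b):
        return float(np.mean([dist[tuple(sorted((i, j)))] for i in a for j in b]))

    heights = []
    clusters = list(cols)
    while len(clusters) > 1:
        best = min(((i, j) for i in range(len(clusters))
                    for j in range(i + 1, len(clusters))),
                   key=lambda ij: cdist(clusters[ij[0]], clusters[ij[1]]))
        i, j = best
        heights.append(cdist(clusters[i], clusters[j]))
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return sorted(heights)


class TestClustering:
    def test_identical_columns_merge_first_at_zero(self):
        m = make_matrix([[1.0, 1.0, 5.0], [2.0, 2.0, 9.0]], stage="imputed")
        res = dd.hierarchical_cluster(m)
        assert res.linkage[0, 2] == 0.0
        assert set(res.linkage[0, :2].astype(int)) == {0, 1}

    def test_three_point_average_linkage_heights(self):
        # 1-D columns at 0, 1, 10: merge (0,1) at 1 then with 10 at (10+9)/2
        m = make_matrix([[0.0, 1.0, 10.0]], stage="imputed")
        res = dd.hierarchical_cluster(m)
        assert res.linkage[0, 2] == pytest.approx(1.0)
        assert res.linkage[1, 2] == pytest.approx(9.5)

    def test_agreement_with_brute_force_oracle(self, rng):
        for _ in range(25):
            X = rng.normal(0, 1, (8, 6))
            m = make_matrix(X, stage="imputed")
            res = dd.hierarchical_cluster(m)
            np.testing.assert_allclose(
                sorted(res.linkage[:, 2]), brute_force_average_linkage(X),
                rtol=1e-9)

    def test_missing_values_rejected(self):
        m = make_matrix([[1.0, np.nan]], stage="log2")
        with pytest.raises(ValueError, match="impute"):
            dd.hierarchical_cluster(m)

    def test_newick_and_cut(self):
        m = make_matrix([[0.0, 1.0, 10.0]], sample_ids=["a", "b", "c"],
                        stage="imputed")
        res = dd.hierarchical_cluster(m)
        nwk = res.to_newick()
        assert nwk.endswith(";") and all(x in nwk for x in "abc")
        parts = res.cut(2)
        assert parts["a"] == parts["b"] != parts["c"]
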