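"""Distances, NMDS, PERMANOVA/PERMDISP and group dissimilarity summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from nightchorus.dissimilarity import (
    DistanceMatrix,
    jaccard_binary,
    mean_pairwise_dissimilarity,
    nmds,
    permanova,
    permdisp,
    prepare_index_profile,
    ruzicka,
)


def dm_from_points(points, labels=None, method="euclidean"):
    labels = labels or [f"S{i}" for i in range(len(points))]
    return DistanceMatrix(labels=labels,
                          values=squareform(pdist(np.asarray(points))),
                          method=method)


class TestJaccard:
    def test_hand_examples(self):
        df = pd.DataFrame([[1, 1, 1, 0], [0, 1, 1, 1]], index=["a", "b"])
        assert jaccard_binary(df).values[0, 1] == pytest.approx(0.5)
        same = pd.DataFrame([[1, 0, 1], [1, 0, 1]], index=["a", "b"])
        assert jaccard_binary(same).values[0, 1] == 0.0
        disjoint = pd.DataFrame([[1, 1, 0, 0], [0, 0, 1, 1]], index=["a", "b"])
        assert jaccard_binary(disjoint).values[0, 1] == 1.0

    def test_all_zero_rows_zero_by_convention(self):
        df = pd.DataFrame([[0, 0], [0, 0]], index=["a", "b"])
        assert jaccard_binary(df).values[0, 1] == 0.0

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="0/1"):
            jaccard_binary(pd.DataFrame([[2, 0], [0, 1]], index=["a", "b"]))


class TestRuzicka:
    def test_hand_example(self):
        df = pd.DataFrame([[1, 2, 3], [3, 2, 1]], index=["a", "b"])
        assert ruzicka(df).values[0, 1] == pytest.approx(0.5)  # 1 - 4/8

    def test_equals_jaccard_on_binary(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            df = pd.DataFrame(rng.integers(0, 2, size=(6, 10)).astype(float),
                              index=[f"s{i}" for i in range(6)])
            assert np.allclose(ruzicka(df).values, jaccard_binary(df).values)

    def test_zero_rows_and_negatives(self):
        df = pd.DataFrame([[0.0, 0.0], [0.0, 0.0]], index=["a", "b"])
        assert ruzicka(df).values[0, 1] == 0.0
        with pytest.raises(ValueError, match="non-negative"):
            ruzicka(pd.DataFrame([[1.0, -0.1], [0.5, 0.2]], index=["a", "b"]))

    def test_metric_properties(self):
        # identity, symmetry, triangle inequality on random instances
        rng = np.random.default_rng(1)
        for _ in range(1000):
            df = pd.DataFrame(rng.uniform(0, 5, size=(4, 6)),
                              index=list("abcd"))
            d = ruzicka(df).values
            assert np.allclose(d, d.T)
            assert np.all(np.diag(d) == 0)
            for i, j, k in itertools.permutations(range(4), 3):
                assert d[i, k] <= d[i, j] + d[j, k] + 1e-12


class TestIndexProfile:
    def frame(self):
        rng = np.random.default_rng(2)
        return pd.DataFrame(rng.uniform(size=(8, 4)),
                            columns=["act", "aei", "hf", "sm"],
                            index=[f"S{i}" for i in range(8)])

    def test_range_and_act_inversion(self):
        df = self.frame()
        prof = prepare_index_profile(df)
        for col in prof.columns:
            assert prof[col].min() == pytest.approx(0.0)
            assert prof[col].max() == pytest.approx(1.0)
        # the site with max ACT maps to 0 after inversion
        assert prof.loc[df["act"].idxmax(), "act"] == pytest.approx(0.0)

    def test_constant_column_rejected(self):
        df = self.frame()
        df["hf"] = 0.5
        with pytest.raises(ValueError, match="constant"):
            prepare_index_profile(df)

    def test_site_order_equivariance(self):
        df = self.frame()
        d1 = ruzicka(prepare_index_profile(df))
        shuffled = df.iloc[::-1]
        d2 = ruzicka(prepare_index_profile(shuffled))
        f1, f2 = d1.to_frame(), d2.to_frame()
        assert np.allclose(f1.values, f2.loc[f1.index, f1.columns].values)


class TestNMDS:
    def test_recovers_exact_2d_configuration(self):
        rng = np.random.default_rng(3)
        pts = rng.standard_normal((12, 2))
        res = nmds(dm_from_points(pts), k=2, restarts=8, seed=0)
        assert res.stress < 0.01
        assert res.converged

    def test_seed_determinism(self):
        d = dm_from_points(np.random.default_rng(4).standard_normal((10, 2)))
        a = nmds(d, restarts=4, seed=7)
        b = nmds(d, restarts=4, seed=7)
        assert np.allclose(a.coordinates.values, b.coordinates.values)
        assert a.stress == b.stress

    def test_too_few_sites_rejected(self):
        d = dm_from_points(np.eye(3))
        with pytest.raises(ValueError):
            nmds(d, k=2)


def exhaustive_permanova_p(d: DistanceMatrix, codes: np.ndarray) -> float:
    """Exact p over every distinct assignment of group labels."""
    from nightchorus.dissimilarity import _permanova_ss
    n = d.n
    a = len(np.unique(codes))
    d2 = d.values ** 2

    def f_of(c):
        ss_t, ss_w, ss_b = _permanova_ss(d2, np.asarray(c))
        return (ss_b / (a - 1)) / (ss_w / (n - a))

    f_obs = f_of(codes)
    fs = [f_of(perm) for perm in set(itertools.permutations(codes))]
    return float(np.mean([f >= f_obs - 1e-12 for f in fs]))


class TestPermanova:
    def test_matches_exhaustive_enumeration_n6(self):
        rng = np.random.default_rng(5)
        pts = np.vstack([rng.standard_normal((3, 2)),
                         rng.standard_normal((3, 2)) + 1.0])
        d = dm_from_points(pts)
        codes = np.array([0, 0, 0, 1, 1, 1])
        exact = exhaustive_permanova_p(d, codes)
        sampled = permanova(d, ["A"] * 3 + ["B"] * 3, n_perm=9999, seed=1)
        assert sampled.p_value == pytest.approx(exact, abs=0.02)

    def test_statistic_matches_skbio(self):
        import skbio
        rng = np.random.default_rng(6)
        pts = rng.standard_normal((12, 3))
        d = dm_from_points(pts)
        ours = permanova(d, ["A"] * 6 + ["B"] * 6, n_perm=99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d.values, d.labels),
            grouping=["A"] * 6 + ["B"] * 6, permutations=99)
        assert ours.statistic == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_separated_clusters_minimum_p(self):
        rng = np.random.default_rng(7)
        pts = np.vstack([rng.standard_normal((6, 2)) * 0.1,
                         rng.standard_normal((6, 2)) * 0.1 + 100.0])
        res = permanova(dm_from_points(pts), ["A"] * 6 + ["B"] * 6,
                        n_perm=999, seed=2)
        # near-minimal: only permutations recreating the split (or its
        # mirror, ~2/924 of draws) can tie the observed pseudo-F
        assert 1.0 / 1000.0 <= res.p_value <= 6.0 / 1000.0

    def test_r2_and_ss_decomposition(self):
        from nightchorus.dissimilarity import _permanova_ss
        rng = np.random.default_rng(8)
        d = dm_from_points(rng.standard_normal((10, 3)))
        codes = np.array([0] * 5 + [1] * 5)
        ss_t, ss_w, ss_b = _permanova_ss(d.values ** 2, codes)
        assert ss_b + ss_w == pytest.approx(ss_t, abs=1e-9)
        res = permanova(d, ["A"] * 5 + ["B"] * 5, n_perm=99, seed=0)
        assert 0.0 <= res.r_squared <= 1.0

    def test_group_of_one_rejected(self):
        d = dm_from_points(np.random.default_rng(9).standard_normal((5, 2)))
        with pytest.raises(ValueError, match="2 members"):
            permanova(d, ["A"] * 4 + ["B"], n_perm=99, seed=0)


class TestPermdisp:
    def test_translated_copies_have_equal_dispersion(self):
        rng = np.random.default_rng(10)
        base = rng.standard_normal((6, 2))
        pts = np.vstack([base, base + 50.0])
        res = permdisp(dm_from_points(pts), ["A"] * 6 + ["B"] * 6,
                       n_perm=999, seed=3)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.5

    def test_scaled_group_detected(self):
        rng = np.random.default_rng(11)
        base = rng.standard_normal((6, 2))
        pts = np.vstack([base, base * 3.0 + 20.0])
        res = permdisp(dm_from_points(pts), ["A"] * 6 + ["B"] * 6,
                       n_perm=999, seed=4)
        assert res.p_value < 0.05

    def test_f_matches_skbio(self):
        import skbio
        rng = np.random.default_rng(12)
        d = dm_from_points(rng.standard_normal((12, 3)))
        groups = ["A"] * 6 + ["B"] * 6
        ours = permdisp(d, groups, n_perm=99, seed=0)
        ref = skbio.stats.distance.permdisp(
            skbio.DistanceMatrix(d.values, d.labels), grouping=groups,
            permutations=99, test="centroid")
        assert ours.statistic == pytest.approx(ref["test statistic"], rel=1e-6)

    def test_centroid_distances_non_negative(self):
        from nightchorus.dissimilarity import _centroid_distances
        # a non-Euclidean (Jaccard-like) matrix exercises the
        # negative-eigenvalue correction
        rng = np.random.default_rng(13)
        df = pd.DataFrame(rng.integers(0, 2, size=(10, 12)).astype(float),
                          index=[f"s{i}" for i in range(10)])
        d = jaccard_binary(df)
        z = _centroid_distances(d, np.array([0] * 5 + [1] * 5))
        assert np.all(z >= 0.0)


class TestMeanPairwise:
    def test_two_singleton_groups(self):
        d = DistanceMatrix(labels=["a", "b"],
                           values=np.array([[0.0, 0.4], [0.4, 0.0]]),
                           method="jaccard_binary")
        between, within = mean_pairwise_dissimilarity(d, ["A", "B"])
        assert between == pytest.approx(0.4)
        assert np.isnan(within["A"]) and np.isnan(within["B"])

    def test_constant_distances(self):
        n = 6
        vals = np.full((n, n), 0.3); np.fill_diagonal(vals, 0.0)
        d = DistanceMatrix(labels=[f"s{i}" for i in range(n)], values=vals,
                           method="ruzicka")
        between, within = mean_pairwise_dissimilarity(d, ["A"] * 3 + ["B"] * 3)
        assert between == pytest.approx(0.3)
        assert within["A"] == pytest.approx(0.3)

    def test_matches_bruteforce_on_4_sites(self):
        rng = np.random.default_rng(14)
        d = dm_from_points(rng.standard_normal((4, 2)))
        groups = ["A", "A", "B", "B"]
        between, within = mean_pairwise_dissimilarity(d, groups)
        v = d.values
        assert between == pytest.approx(
            np.mean([v[0, 2], v[0, 3], v[1, 2], v[1, 3]]))
        assert within["A"] == pytest.approx(v[0, 1])
        assert within["B"] == pytest.approx(v[2, 3])


class TestDistanceMatrixValidation:
    def test_asymmetry_rejected(self):
        vals = np.array([[0.0, 0.2], [0.3, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(labels=["a", "b"], values=vals, method="x")

    def test_nonzero_diagonal_rejected(self):
        vals = np.array([[0.1, 0.2], [0.2, 0.0]])
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(labels=["a", "b"], values=vals, method="x")
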