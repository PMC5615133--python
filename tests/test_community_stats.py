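import itertools

import numpy as np
import pandas as pd
import pytest

from coda_age import (
    ClrMatrix,
    CountTable,
    aitchison_distance,
    clr_from_counts,
    depth_diversity_check,
    group_dispersion,
    pairwise_permanova,
    permanova,
    shannon_diversity,
    smooth_age_trend,
)
from coda_age.community_stats import DiversityProfile, _multiset_permutations

from conftest import make_counts


def clr_of(arr):
    arr = np.asarray(arr, dtype=float)
    arr = arr - arr.mean(axis=1, keepdims=True)
    return ClrMatrix(
        pd.DataFrame(
            arr,
            index=[f"s{i}" for i in range(arr.shape[0])],
            columns=[f"o{j}" for j in range(arr.shape[1])],
        )
    )


def gaussian_dist(rng, shifts, n_per, dim=6, sigma=1.0):
    """Euclidean distances among Gaussian clouds with given mean shifts."""
    blobs = [rng.normal(mu, sigma, size=(n_per, dim)) for mu in shifts]
    X = np.vstack(blobs)
    labels = np.repeat([f"g{i}" for i in range(len(shifts))], n_per)
    d = np.linalg.norm(X[:, None] - X[None, :], axis=2)
    ids = [f"s{i}" for i in range(len(X))]
    return pd.DataFrame(d, index=ids, columns=ids), pd.Series(labels, index=ids)


class TestMultisetPermutations:
    def test_counts(self):
        perms = list(_multiset_permutations(["a", "a", "b", "b", "b"]))
        assert len(perms) == 10  # 5! / (2! 3!)
        assert len(set(perms)) == 10

    def test_matches_itertools_dedupe(self):
        items = ["x", "x", "y", "z"]
        expected = sorted(set(itertools.permutations(items)))
        assert sorted(_multiset_permutations(items)) == expected


class TestPermanova:
    def test_exact_matches_brute_force_oracle(self, rng):
        dist, labels = gaussian_dist(rng, [0.0, 1.0], n_per=3)
        res = permanova(dist, labels, method="exact")

        # independent oracle: enumerate label orderings, recompute F by the
        # textbook within/between decomposition
        d2 = dist.to_numpy() ** 2
        n = 6

        def brute_F(lab):
            lab = np.asarray(lab)
            sst = d2[np.triu_indices(n, 1)].sum() / n
            ssw = 0.0
            for g in np.unique(lab):
                ix = np.flatnonzero(lab == g)
                ssw += d2[np.ix_(ix, ix)][np.triu_indices(len(ix), 1)].sum() / len(ix)
            return ((sst - ssw) / 1) / (ssw / 4)

        obs = brute_F(labels.to_numpy())
        all_perms = sorted(set(itertools.permutations(labels.to_numpy())))
        assert len(all_perms) == 20
        p_oracle = np.mean([brute_F(p) >= obs - 1e-12 for p in all_perms])
        assert res.pseudo_F == pytest.approx(obs, rel=1e-12)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)
        assert res.n_permutations == 20

    def test_monte_carlo_converges_to_exact(self, rng):
        dist, labels = gaussian_dist(rng, [0.0, 1.5], n_per=3)
        exact = permanova(dist, labels, method="exact")
        mc = permanova(dist, labels, n_permutations=4999, seed=1)
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / 4999)
        assert abs(mc.p_value - exact.p_value) < 3 * se + 2 / 4999

    def test_saturated_significance(self, rng):
        dist, labels = gaussian_dist(rng, [0.0, 50.0], n_per=10)
        res = permanova(dist, labels, n_permutations=199, seed=0)
        assert res.p_value == pytest.approx(1 / 200)

    def test_r2_bounds_and_floor(self, rng):
        dist, labels = gaussian_dist(rng, [0.0, 2.0], n_per=8)
        res = permanova(dist, labels, n_permutations=99, seed=0)
        assert 0.0 <= res.R2 <= 1.0
        assert res.p_value >= 1 / 100

    def test_r2_monotone_in_shift(self, rng):
        r2s = []
        for shift in (0.5, 2.0, 8.0):
            dist, labels = gaussian_dist(
                np.random.default_rng(7), [0.0, shift], n_per=10
            )
            r2s.append(permanova(dist, labels, n_permutations=9, seed=0).R2)
        assert r2s[0] < r2s[1] < r2s[2]

    def test_one_group_errors(self, rng):
        dist, labels = gaussian_dist(rng, [0.0], n_per=5)
        with pytest.raises(ValueError, match="2 groups"):
            permanova(dist, labels)

    def test_tiny_group_errors(self, rng):
        dist, labels = gaussian_dist(rng, [0.0, 1.0], n_per=3)
        labels.iloc[0:2] = "g1"
        with pytest.raises(ValueError, match="fewer than 2"):
            permanova(dist, labels)

    def test_deterministic_given_seed(self, rng):
        dist, labels = gaussian_dist(rng, [0.0, 1.0], n_per=6)
        a = permanova(dist, labels, n_permutations=99, seed=5)
        b = permanova(dist, labels, n_permutations=99, seed=5)
        assert a.p_value == b.p_value


class TestPairwisePermanova:
    def test_three_groups_three_results(self, rng):
        dist, labels = gaussian_dist(rng, [0.0, 1.0, 2.0], n_per=4)
        results = pairwise_permanova(dist, labels, n_permutations=49, seed=0)
        assert len(results) == 3
        assert {tuple(r.groups) for r in results} == {
            ("g0", "g1"), ("g0", "g2"), ("g1", "g2")
        }

    def test_invariant_to_other_groups(self, rng):
        dist, labels = gaussian_dist(rng, [0.0, 1.0, 5.0], n_per=4)
        full = pairwise_permanova(dist, labels, pairs=[("g0", "g1")],
                                  n_permutations=99, seed=3)[0]
        keep = labels.isin(["g0", "g1"])
        sub = dist.loc[keep[keep].index, keep[keep].index]
        alone = permanova(sub, labels[keep], n_permutations=99, seed=3)
        assert full.pseudo_F == pytest.approx(alone.pseudo_F, rel=1e-12)
        assert full.p_value == alone.p_value

    def test_planted_null_pair_not_significant(self, rng):
        hits = 0
        for rep in range(20):
            local = np.random.default_rng(1000 + rep)
            dist, labels = gaussian_dist(local, [0.0, 0.0, 4.0], n_per=6)
            res = pairwise_permanova(dist, labels, pairs=[("g0", "g1")],
                                     n_permutations=99, seed=rep)[0]
            hits += res.p_value <= 0.01
        assert hits <= 2


class TestGroupDispersion:
    def test_identical_samples_zero(self):
        arr = np.tile([1.0, -1.0, 0.0], (6, 1))
        clr = clr_of(arr)
        labels = pd.Series(["a"] * 3 + ["b"] * 3, index=clr.values.index)
        disp = group_dispersion(clr, labels).frame.set_index("group")
        assert disp.loc["a", "mcd"] == 0.0
        assert disp.loc["a", "iqr"] == 0.0

    def test_sigma_doubling_doubles_mcd(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1.0, size=(200, 10))
        b = rng.normal(0, 2.0, size=(200, 10))
        clr = clr_of(np.vstack([a, b]))
        labels = pd.Series(["a"] * 200 + ["b"] * 200, index=clr.values.index)
        disp = group_dispersion(clr, labels).frame.set_index("group")
        ratio = disp.loc["b", "mcd"] / disp.loc["a", "mcd"]
        assert ratio == pytest.approx(2.0, rel=0.10)

    def test_sample_order_invariance(self, rng):
        t = make_counts(rng, 12, 10)
        clr = clr_from_counts(t)
        labels = pd.Series(["a", "b"] * 6, index=clr.values.index)
        d1 = group_dispersion(clr, labels).frame
        perm = list(np.random.default_rng(1).permutation(t.sample_ids))
        clr2 = ClrMatrix(clr.values.loc[perm], log_base=clr.log_base)
        d2 = group_dispersion(clr2, labels.loc[perm]).frame
        pd.testing.assert_frame_equal(
            d1.sort_values("group").reset_index(drop=True),
            d2.sort_values("group").reset_index(drop=True),
        )

    def test_empty_group_errors(self):
        clr = clr_of(np.random.default_rng(0).normal(size=(4, 5)))
        labels = pd.Series(["a", "a", "a", "b"], index=clr.values.index)
        with pytest.raises(ValueError, match="fewer than 2"):
            group_dispersion(clr, labels)


class TestShannon:
    def test_uniform_closed_form(self):
        k = 7
        t = CountTable(
            pd.DataFrame(np.full((3, k), 10), columns=[f"o{j}" for j in range(k)],
                         index=["s1", "s2", "s3"])
        )
        prof = shannon_diversity(t)
        np.testing.assert_allclose(prof.frame["shannon"], np.log(k), atol=1e-12)

    def test_single_otu_zero(self):
        t = CountTable(
            pd.DataFrame([[50, 0], [50, 0]], columns=["a", "b"], index=["s1", "s2"])
        )
        np.testing.assert_allclose(shannon_diversity(t).frame["shannon"], 0.0)

    def test_matches_independent_summation(self, rng):
        t = make_counts(rng, 10, 30, depth=500)
        prof = shannon_diversity(t)
        for s in t.sample_ids:
            row = t.counts.loc[s]
            p = row[row > 0] / row.sum()
            expected = -(p * np.log(p)).sum()
            assert prof.frame.loc[s, "shannon"] == pytest.approx(expected, abs=1e-12)

    def test_invariance_otu_order_and_depth_scaling(self, rng):
        t = make_counts(rng, 5, 10)
        h1 = shannon_diversity(t).frame["shannon"]
        perm = list(rng.permutation(t.otu_ids))
        h2 = shannon_diversity(t.select_otus(perm)).frame["shannon"]
        np.testing.assert_allclose(h1, h2, atol=1e-12)
        t3 = CountTable(t.counts * 9)
        h3 = shannon_diversity(t3).frame["shannon"]
        np.testing.assert_allclose(h1, h3, atol=1e-12)

    def test_bounded_by_log_richness(self, rng):
        t = make_counts(rng, 10, 25, depth=100)
        prof = shannon_diversity(t).frame
        richness = (t.counts > 0).sum(axis=1)
        assert (prof["shannon"] <= np.log(richness) + 1e-12).all()


def _profile(depth, H):
    return DiversityProfile(
        pd.DataFrame({"depth": depth, "shannon": H},
                     index=[f"s{i}" for i in range(len(depth))])
    )


class TestDepthDiversityCheck:
    def test_forced_proportional_flags(self):
        depth = np.arange(100, 160)
        res = depth_diversity_check(_profile(depth, depth * 0.01),
                                    n_permutations=199, seed=0)
        assert res.depth_confounded
        assert res.spearman_r == pytest.approx(1.0)

    def test_independent_not_flagged(self):
        rng = np.random.default_rng(0)
        res = depth_diversity_check(
            _profile(rng.integers(1000, 2000, 60), rng.normal(3, 0.2, 60)),
            n_permutations=199, seed=0,
        )
        assert not res.depth_confounded

    def test_monotone_rescaling_invariance(self):
        rng = np.random.default_rng(1)
        depth = rng.integers(1000, 9000, 40)
        H = rng.normal(3, 0.3, 40)
        a = depth_diversity_check(_profile(depth, H), n_permutations=99, seed=2)
        b = depth_diversity_check(_profile(depth ** 2, H), n_permutations=99, seed=2)
        assert a.spearman_r == pytest.approx(b.spearman_r, abs=1e-12)
        assert a.p_value == b.p_value

    def test_constant_depth_errors(self):
        with pytest.raises(ValueError, match="constant"):
            depth_diversity_check(_profile(np.full(20, 500), np.arange(20.0)))

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="10"):
            depth_diversity_check(_profile(np.arange(5), np.arange(5.0)))


class TestSmoothAgeTrend:
    def test_linear_exact(self):
        ages = np.linspace(0, 50, 40)
        vals = 0.3 * ages - 2.0
        out = smooth_age_trend(vals, ages, span=0.75)
        np.testing.assert_allclose(out["smoothed"], 0.3 * out["age"] - 2.0, atol=1e-6)

    def test_constant_curve(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(0, 80, 50)
        out = smooth_age_trend(np.full(50, 4.2), ages)
        np.testing.assert_allclose(out["smoothed"], 4.2, atol=1e-10)

    def test_cross_implementation_oracle(self):
        # naive tricube local-linear regression, written independently
        rng = np.random.default_rng(0)
        ages = rng.uniform(0, 10, 300)
        vals = np.sin(ages) + rng.normal(0, 0.1, 300)
        grid = np.linspace(0.5, 9.5, 50)
        span = 0.3
        out = smooth_age_trend(vals, ages, span=span, grid=grid)

        def naive(x0):
            d = np.abs(ages - x0)
            h = np.sort(d)[int(np.ceil(span * len(ages))) - 1]
            w = np.clip(1 - (d / max(h, 1e-12)) ** 3, 0, None) ** 3
            X = np.stack([np.ones_like(ages), ages - x0], 1)
            beta = np.linalg.lstsq((X * w[:, None]).T @ X, X.T @ (w * vals),
                                   rcond=None)[0]
            return beta[0]

        oracle = np.array([naive(x) for x in grid])
        assert np.abs(out["smoothed"].to_numpy() - oracle).max() < 0.05

    def test_integer_grid_default(self):
        ages = np.repeat([20, 30, 40, 50], 5)
        out = smooth_age_trend(np.tile([1.0, 2, 3, 4, 5], 4), ages)
        assert out["age"].tolist() == list(range(20, 51))

    def test_degenerate_age_range(self):
        with pytest.raises(ValueError, match="distinct ages"):
            smooth_age_trend(np.arange(12.0), np.full(12, 30))

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="10"):
            smooth_age_trend([1.0, 2.0], [1, 2])
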