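import itertools

import numpy as np
import pytest
from scipy import stats

from paleokin.genotype_io import MISSING, IndividualMeta
from paleokin.popgen_stats import (DistanceMatrix, PopgenError, d_statistic,
                                   diversity_permutation_test,
                                   euclidean_distances, fisher_exact,
                                   genetic_distance_from_f3, mantel_test,
                                   outgroup_f3, relative_filter,
                                   within_building_test)


def _coords(n, block=1_000_000):
    chroms = np.array(["1"] * n)
    pos = np.arange(1, n + 1) * (block // 10)
    return chroms, pos


class TestOutgroupF3:
    def test_single_snp_contribution(self):
        # two blocks so the jackknife is defined; both carry the 0.25 signal
        f = np.array([0.5, 0.5])
        g = np.array([1, 1], dtype=np.int8)
        chroms = np.array(["1", "2"])
        pos = np.array([100, 100])
        res = outgroup_f3(f, g, g, chroms, pos, block_size=1000)
        assert res.f3 == pytest.approx(0.25)

    def test_duplicate_beats_unrelated(self):
        rng = np.random.default_rng(0)
        n = 5000
        f = rng.uniform(0.1, 0.9, n)
        a = (rng.random(n) < f).astype(np.int8)
        b = (rng.random(n) < f).astype(np.int8)
        chroms, pos = _coords(n)
        same = outgroup_f3(f, a, a, chroms, pos).f3
        diff = outgroup_f3(f, a, b, chroms, pos).f3
        assert same > diff

    def test_jackknife_matches_leave_one_block_oracle(self):
        rng = np.random.default_rng(1)
        n = 50
        f = rng.uniform(0.2, 0.8, n)
        a = (rng.random(n) < f).astype(np.int8)
        b = (rng.random(n) < f).astype(np.int8)
        chroms = np.array(["1"] * n)
        pos = np.concatenate([np.arange(10) + 1 + k * 1000 for k in range(5)])
        res = outgroup_f3(f, a, b, chroms, pos, block_size=1000)
        # direct oracle: recompute the weighted-jackknife variance by hand
        num = (f - a) * (f - b)
        blocks = np.repeat(np.arange(5), 10)
        est = num.mean()
        loo = np.array([num[blocks != j].mean() for j in range(5)])
        m = np.full(5, 10.0)
        h = 50.0 / m
        theta_j = 5 * est - np.sum((1 - m / 50.0) * loo)
        tau = h * est - (h - 1) * loo
        se = np.sqrt(np.sum((tau - theta_j) ** 2 / (h - 1)) / 5)
        assert res.se == pytest.approx(se, rel=1e-9)
        assert res.n_blocks == 5

    def test_no_usable_snps(self):
        with pytest.raises(PopgenError):
            outgroup_f3(np.array([np.nan]), np.array([1], dtype=np.int8),
                        np.array([1], dtype=np.int8), np.array(["1"]),
                        np.array([1]))


class TestDStatistic:
    def _data(self, seed=0, n=4000, admix=0.0):
        rng = np.random.default_rng(seed)
        fw = rng.uniform(0.1, 0.9, n)
        fx = np.clip(fw + rng.normal(0, 0.2, n), 0.01, 0.99)
        w = (rng.random(n) < fw).astype(float)
        x = (rng.random(n) < fx).astype(float)
        y = (rng.random(n) < fw).astype(float)
        z = (rng.random(n) < fw).astype(float)
        if admix > 0:   # gene flow from x into z
            take = rng.random(n) < admix
            z[take] = (rng.random(take.sum()) < fx[take]).astype(float)
        return fw, w, x, y, z

    def test_identical_sister_groups_give_zero(self):
        n = 100
        rng = np.random.default_rng(2)
        w = rng.random(n)
        x = rng.random(n)
        y = (rng.random(n) < 0.5).astype(float)
        chroms, pos = _coords(n)
        res = d_statistic(w, x, y, y.copy(), chroms, pos, block_size=1_000_000)
        assert res.d == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry(self):
        fw, w, x, y, z = self._data(seed=3)
        chroms, pos = _coords(len(w))
        d1 = d_statistic(w, x, y, z, chroms, pos).d
        d2 = d_statistic(w, x, z, y, chroms, pos).d
        assert d1 == pytest.approx(-d2, rel=1e-9)

    def test_gene_flow_detected_with_direction(self):
        fw, w, x, y, z = self._data(seed=4, n=20_000, admix=0.4)
        chroms, pos = _coords(len(w))
        res = d_statistic(w, x, y, z, chroms, pos)
        assert res.significant
        # and the signal flips sign when the admixed taxon swaps position
        res_swapped = d_statistic(w, x, z, y, chroms, pos)
        assert np.sign(res.z) == -np.sign(res_swapped.z)


def _dm(rng, n, kind="genetic", ids=None):
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    return DistanceMatrix(ids or [f"i{k}" for k in range(n)], m, kind)


class TestDiversityPermutation:
    def test_identical_structure_p_one(self):
        n = 8
        vals = np.zeros((n, n))
        vals[:4, :4] = 0.5
        vals[4:, 4:] = 0.5
        vals[:4, 4:] = 0.7
        vals[4:, :4] = 0.7
        np.fill_diagonal(vals, 0)
        dm = DistanceMatrix([f"i{k}" for k in range(n)], vals)
        obs, p = diversity_permutation_test([f"i{k}" for k in range(4)],
                                            [f"i{k}" for k in range(4, 8)], dm,
                                            n_perm=500, seed=0)
        assert obs == pytest.approx(0.0)
        assert p == 1.0

    def test_detects_diversity_difference(self):
        n = 12
        vals = np.full((n, n), 0.5)
        vals[:6, :6] = 0.1      # group A far less diverse
        np.fill_diagonal(vals, 0)
        dm = DistanceMatrix([f"i{k}" for k in range(n)], vals)
        _, p = diversity_permutation_test([f"i{k}" for k in range(6)],
                                          [f"i{k}" for k in range(6, 12)], dm,
                                          n_perm=2000, seed=1)
        assert p < 0.05

    def test_overlapping_groups_rejected(self):
        rng = np.random.default_rng(2)
        dm = _dm(rng, 6)
        with pytest.raises(PopgenError):
            diversity_permutation_test(["i0", "i1"], ["i1", "i2"], dm)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(3)
        dm = _dm(rng, 8)
        a = diversity_permutation_test([f"i{k}" for k in range(4)],
                                       [f"i{k}" for k in range(4, 8)], dm,
                                       n_perm=500, seed=9)
        b = diversity_permutation_test([f"i{k}" for k in range(4)],
                                       [f"i{k}" for k in range(4, 8)], dm,
                                       n_perm=500, seed=9)
        assert a == b


class TestMantel:
    def test_identity_r_one(self):
        rng = np.random.default_rng(4)
        s = _dm(rng, 5, "spatial")
        g = DistanceMatrix(s.ids, s.values.copy(), "genetic")
        r, _ = mantel_test(s, g, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_exact_enumeration_matches_sampled(self):
        rng = np.random.default_rng(5)
        s = _dm(rng, 4, "spatial")
        g = _dm(rng, 4, "genetic")
        r_e, p_e = mantel_test(s, g, exact=True)
        _, p_s = mantel_test(s, g, n_perm=9_999, seed=1)
        # sampled p ~ Binomial(n_perm, p_e); 4 sd tolerance
        tol = 4 * np.sqrt(p_e * (1 - p_e) / 10_000) + 1e-4
        assert abs(p_s - p_e) < tol

    def test_constant_matrix_rejected(self):
        rng = np.random.default_rng(6)
        g = _dm(rng, 4)
        const = DistanceMatrix(g.ids, np.ones((4, 4)) - np.eye(4), "spatial")
        with pytest.raises(PopgenError, match="constant"):
            mantel_test(const, g, n_perm=9, seed=0)


class TestWithinBuilding:
    def test_singleton_buildings_rejected(self):
        rng = np.random.default_rng(7)
        sim = _dm(rng, 3)
        with pytest.raises(PopgenError, match="within-building"):
            within_building_test({"i0": "A", "i1": "B", "i2": "C"}, sim)

    def test_clustered_similarity_detected(self):
        n = 9
        vals = np.full((n, n), 0.2)
        for b in range(3):          # three buildings of three, high within-sim
            idx = slice(3 * b, 3 * b + 3)
            vals[idx, idx] = 0.9
        np.fill_diagonal(vals, 0)
        sim = DistanceMatrix([f"i{k}" for k in range(n)], vals)
        buildings = {f"i{k}": f"B{k // 3}" for k in range(n)}
        _, p = within_building_test(buildings, sim, n_perm=2000, seed=0)
        assert p < 0.01


class TestFisherExact:
    @pytest.mark.parametrize("table, or_1dp, p_printed", [
        ([[8, 2], [6, 14]], 8.6, 0.019),
        ([[8, 2], [8, 14]], 6.6, 0.054),
        ([[4, 3], [2, 19]], 11.1, 0.02),
    ])
    def test_reported_contingency_results(self, table, or_1dp, p_printed):
        res = fisher_exact(table)
        assert round(res.odds_ratio, 1) == or_1dp
        assert round(res.p_value, len(str(p_printed).split(".")[1])) == p_printed

    def test_flat_table(self):
        res = fisher_exact([[1, 1], [1, 1]])
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_noncentral_hypergeometric_oracle(self):
        """Conditional-MLE OR and probability-ordering p recomputed from
        first principles for random small tables."""
        rng = np.random.default_rng(8)
        for _ in range(25):
            n = int(rng.integers(8, 41))
            a_ = int(rng.integers(0, n + 1))
            rest = n - a_
            b_ = int(rng.integers(0, rest + 1))
            c_ = int(rng.integers(0, rest - b_ + 1))
            d_ = rest - b_ - c_
            t = np.array([[a_, b_], [c_, d_]])
            if min(t.sum(axis=0).min(), t.sum(axis=1).min()) == 0:
                continue
            res = fisher_exact(t)
            p_oracle = _fisher_p_oracle(t)
            or_oracle = _cond_mle_oracle(t)
            assert res.p_value == pytest.approx(p_oracle, abs=1e-9)
            if np.isfinite(or_oracle) and or_oracle > 0:
                assert res.odds_ratio == pytest.approx(or_oracle, rel=1e-4)


def _fisher_p_oracle(t):
    a, b = t[0]
    c, d = t[1]
    row1, col1, n = a + b, a + c, t.sum()
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    pmf = {k: stats.hypergeom.pmf(k, n, col1, row1) for k in range(lo, hi + 1)}
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7)))


def _cond_mle_oracle(t):
    from scipy.optimize import minimize_scalar
    a = t[0, 0]
    row1, col1, n = t[0].sum(), t[:, 0].sum(), t.sum()
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    ks = np.arange(lo, hi + 1)
    if a == lo:
        return 0.0 if a < hi else np.nan
    if a == hi:
        return np.inf
    base = stats.hypergeom.logpmf(ks, n, col1, row1)

    def negll(logpsi):
        w = base + ks * logpsi
        m = w.max()
        return -(base[np.searchsorted(ks, a)] + a * logpsi
                 - (m + np.log(np.exp(w - m).sum())))

    res = minimize_scalar(negll, bounds=(-15, 15), method="bounded",
                          options={"xatol": 1e-10})
    return float(np.exp(res.x))


class TestEuclidean:
    def test_three_four_five(self):
        metas = [IndividualMeta(id="a", x=0.0, y=0.0),
                 IndividualMeta(id="b", x=3.0, y=4.0)]
        dm = euclidean_distances(metas)
        assert dm.values[0, 1] == pytest.approx(5.0)
        assert dm.values[0, 0] == 0.0

    def test_translation_invariance(self):
        rng = np.random.default_rng(9)
        pts = rng.random((6, 2)) * 10
        metas = [IndividualMeta(id=f"i{k}", x=float(x), y=float(y))
                 for k, (x, y) in enumerate(pts)]
        shifted = [IndividualMeta(id=f"i{k}", x=float(x + 100), y=float(y - 50))
                   for k, (x, y) in enumerate(pts)]
        np.testing.assert_allclose(euclidean_distances(metas).values,
                                   euclidean_distances(shifted).values)

    def test_missing_coordinates(self):
        with pytest.raises(PopgenError):
            euclidean_distances([IndividualMeta(id="a", x=1.0)])


class TestRelativeFilter:
    def test_keeps_higher_coverage(self):
        kept = relative_filter(["s1", "s2"], [("s1", "s2")],
                               {"s1": 0.08, "s2": 0.09})
        assert kept == ["s2"]

    def test_no_relatives_identity(self):
        ids = ["a", "b", "c"]
        assert relative_filter(ids, [], {"a": 1, "b": 2, "c": 3}) == ids

    def test_chain_resolves_to_maximal_independent_set(self):
        ids = list("abcdef")
        rng = np.random.default_rng(10)
        for rep in range(20):
            edges = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]
                     if rng.random() < 0.4]
            cov = {i: float(rng.random()) for i in ids}
            kept = relative_filter(ids, edges, cov)
            kept_set = set(kept)
            # independent
            assert not any(a in kept_set and b in kept_set for a, b in edges)
            # maximal: nobody outside could be added
            for i in set(ids) - kept_set:
                assert any((i in e) and (set(e) - {i}) <= kept_set
                           for e in edges)


def test_genetic_distance_from_f3_symmetric_lookup():
    dm = genetic_distance_from_f3(["a", "b"], {("b", "a"): 0.8})
    assert dm.values[0, 1] == pytest.approx(0.2)
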