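import numpy as np
import pandas as pd
import pytest

from paleokin.kinship_core import (KinshipError, KinshipEstimate,
                                   apply_snp_thresholds, bootstrap_theta,
                                   classify_degree, mismatch_theta,
                                   ml_cotterman, pair_overlap, theta_from_k)
from paleokin.pedigree_sim import build_range_table, merge_range_tables
from paleokin.synthetic_data import (SimConfig, degrade, diploid_matrix,
                                     generate_panel, simulate_founders)

from conftest import make_panel, pseudo_gm


@pytest.mark.parametrize("k1, k2, expected", [
    (1.0, 0.0, 0.25),    # parent-offspring ideal
    (0.0, 1.0, 0.50),    # identical twins ideal
    (0.5, 0.25, 0.25),   # full-sibling ideal
])
def test_theta_from_k(k1, k2, expected):
    assert theta_from_k(k1, k2) == pytest.approx(expected)


def test_kinship_estimate_invariants():
    with pytest.raises(KinshipError, match="!= 1"):
        KinshipEstimate(("a", "b"), 0.5, 0.5, 0.5, 0.25, 100)
    with pytest.raises(KinshipError, match="inconsistent"):
        KinshipEstimate(("a", "b"), 0.0, 1.0, 0.0, 0.3, 100)


class TestMismatchTheta:
    def test_window_arithmetic(self):
        panel = make_panel([(1, 10, "A", "C", 0.5), (1, 20, "G", "T", 0.5),
                            (1, 30, "T", "G", 0.5)])
        gm = pseudo_gm(["a", "b", "c", "d"],
                       [[0, 1, 0], [0, 0, 1], [0, 0, 0], [1, 1, 1]])
        profiles = mismatch_theta(gm, panel, [("a", "b"), ("c", "d")])
        assert profiles[0].p0 == pytest.approx(2 / 3)   # one 1-Mb window

    def test_normalisation_by_median(self):
        # pair P0 values {0.20, 0.25, 0.30}: first pair -> 0.8, theta 0.2
        panel = make_panel([(1, 10 + i, "A", "C", 0.5) for i in range(20)])
        calls = np.zeros((6, 20), dtype=np.int8)
        calls[1, :4] = 1    # a-b mismatch 0.20
        calls[3, :5] = 1    # c-d mismatch 0.25
        calls[5, :6] = 1    # e-f mismatch 0.30
        gm = pseudo_gm(list("abcdef"), calls)
        profiles = mismatch_theta(gm, panel, [("a", "b"), ("c", "d"), ("e", "f")])
        assert profiles[0].normalized_p0 == pytest.approx(0.8)
        assert profiles[0].theta_proxy == pytest.approx(0.2)
        assert profiles[1].theta_proxy == pytest.approx(0.0)

    def test_needs_background(self):
        panel = make_panel([(1, 10, "A", "C", 0.5)])
        gm = pseudo_gm(["a", "b"], [[0], [1]])
        with pytest.raises(KinshipError, match="median"):
            mismatch_theta(gm, panel, [("a", "b")])

    def test_no_overlap_raises(self):
        panel = make_panel([(1, 10, "A", "C", 0.5), (1, 20, "G", "T", 0.5)])
        gm = pseudo_gm(list("abcd"), [[0, -1], [-1, 1], [0, 0], [1, 1]])
        with pytest.raises(KinshipError, match="shares no SNPs"):
            mismatch_theta(gm, panel, [("a", "b"), ("c", "d")])


def _trio_matrices(seed=0, n_snps=2000, eps=0.0, pseudo=False):
    from paleokin.pedigree_sim import Pedigree, drop_pedigree
    ped = Pedigree()
    ped.add("M", "F")
    ped.add("F", "M")
    ped.add("U1", "F")
    ped.add("U2", "M")
    ped.add("C", "F", mother="M", father="F")
    panel = generate_panel(SimConfig(seed=seed, n_snps_auto=n_snps, n_snps_x=0))
    auto_f, x_f = simulate_founders(panel, ped, seed + 1)
    auto, x = drop_pedigree(ped, auto_f, x_f, panel,
                            np.random.default_rng(seed + 2))
    gm = diploid_matrix(ped, auto, None)
    if pseudo:
        gm = degrade(gm, 1.0, eps, seed + 3)
    return panel, gm


class TestMlCotterman:
    def test_duplicate_individual_is_identical(self):
        panel, gm = _trio_matrices(seed=5)
        dup = gm.calls[[0, 0, 1, 2, 3, 4]]
        gm2 = type(gm)(["C", "Cdup", "F", "M", "U1", "U2"], dup, "diploid")
        est = ml_cotterman(gm2, panel, ("C", "Cdup"), eps=0.0)
        assert est.k2 > 0.95
        assert est.theta_auto == pytest.approx(0.5, abs=0.02)

    def test_unrelated_k0_near_one(self):
        panel, gm = _trio_matrices(seed=6, n_snps=5000)
        est = ml_cotterman(gm, panel, ("U1", "U2"), eps=0.0)
        assert est.k0 >= 0.9
        assert est.theta_auto < 0.03

    def test_loglik_monotone(self):
        panel, gm = _trio_matrices(seed=7, n_snps=500, pseudo=True, eps=0.01)
        _, traj = ml_cotterman(gm, panel, ("C", "M"), eps=0.01,
                               return_trajectory=True)
        assert np.all(np.diff(traj) >= -1e-9)

    def test_invariance_to_snp_order_and_allele_flip(self):
        from paleokin.kinship_core import _em_simplex, _pair_likelihood_matrix
        panel, gm = _trio_matrices(seed=8, n_snps=1000, pseudo=True)
        base = ml_cotterman(gm, panel, ("C", "M"), eps=0.005).theta_auto
        # SNP order: the likelihood is a sum over sites, so permuting the
        # per-site likelihood rows must leave the estimate unchanged
        lik = _pair_likelihood_matrix(gm, panel, ("C", "M"), 0.005)
        perm = np.random.default_rng(0).permutation(lik.shape[0])
        k, _, _, _ = _em_simplex(lik[perm], tol=1e-9, max_iter=5000)
        assert theta_from_k(k[1], k[2]) == pytest.approx(base, abs=1e-9)
        # allele-label swap: genotype g -> 1 - g with frequency 1 - p
        flipped = gm.calls.copy()
        obs = flipped != -1
        flipped[obs] = 1 - flipped[obs]
        gm_f = type(gm)(list(gm.individuals), flipped, "pseudohaploid")
        table_f = panel.table.copy()
        table_f["bg_freq"] = 1.0 - table_f["bg_freq"]
        panel_f = type(panel)(table_f)
        assert ml_cotterman(gm_f, panel_f, ("C", "M"),
                            eps=0.005).theta_auto == pytest.approx(base, abs=1e-6)

    def test_grid_search_oracle_small(self):
        # deeper 20-toy sweep lives in the acceptance suite
        from paleokin.kinship_core import _diploid_pair_likelihoods, _em_simplex
        rng = np.random.default_rng(11)
        for _ in range(3):
            lik = _sample_toy_likelihoods(rng, n=50)
            k_em, _, _, traj = _em_simplex(lik, tol=1e-9, max_iter=5000)
            assert np.all(np.diff(traj) >= -1e-9)
            k_grid = _grid_argmax(lik, step=0.001)
            assert np.abs(k_em - k_grid).max() < 0.005


def _sample_toy_likelihoods(rng, n=50):
    from paleokin.kinship_core import _diploid_pair_likelihoods
    p = rng.uniform(0.1, 0.9, n)
    k_true = rng.dirichlet([1.0, 1.0, 1.0])
    tab = _diploid_pair_likelihoods(p, 0.0)
    m = rng.choice(3, size=n, p=k_true)
    gi = np.empty(n, int)
    gj = np.empty(n, int)
    for s in range(n):
        probs = tab[s, :, :, m[s]].ravel()
        c = rng.choice(9, p=probs / probs.sum())
        gi[s], gj[s] = divmod(c, 3)
    return tab[np.arange(n), gi, gj, :]


def _grid_argmax(lik, step=0.001):
    chunks = []
    for a in np.arange(0.0, 1.0 + step / 2, step):
        b = np.arange(0.0, 1.0 - a + step / 2, step)
        chunks.append(np.stack([1.0 - a - b, np.full_like(b, a), b], axis=1))
    grid = np.clip(np.vstack(chunks), 0.0, 1.0)
    with np.errstate(divide="ignore"):
        ll = np.log(lik @ grid.T).sum(axis=0)
    return grid[np.argmax(ll)]


class TestBootstrap:
    def test_zero_variance_data(self):
        panel = make_panel([(1, 10 * (i + 1), "A", "C", 0.5) for i in range(30)])
        gm = pseudo_gm(["a", "b"], np.ones((2, 30)))
        lo, hi = bootstrap_theta(gm, panel, ("a", "b"), n_boot=20, seed=0)
        assert hi - lo == pytest.approx(0.0, abs=1e-9)

    def test_ci_contains_point_estimate(self):
        panel, gm = _trio_matrices(seed=9, n_snps=800, pseudo=True)
        est = ml_cotterman(gm, panel, ("C", "M"), eps=0.005)
        lo, hi = bootstrap_theta(gm, panel, ("C", "M"), n_boot=100, seed=1,
                                 eps=0.005)
        assert lo <= est.theta_auto <= hi


class TestThresholds:
    def test_paper_boundaries(self):
        overlaps = {("Asikli2", "M10_352"): (3_044, None),
                    ("a", "b"): (5_000, 800),
                    ("c", "d"): (12_000, 799)}
        retained, excluded = apply_snp_thresholds(overlaps)
        assert [p for p, _ in excluded] == [("Asikli2", "M10_352")]
        assert retained[("a", "b")] == {"auto": True, "x": True}
        assert retained[("c", "d")] == {"auto": True, "x": False}

    def test_pair_overlap_counts(self):
        gm = pseudo_gm(["a", "b"], [[0, 1, -1, 1], [1, -1, 0, 0]])
        assert pair_overlap(gm, ("a", "b")) == 2


class TestClassifyDegree:
    @pytest.fixture
    def ranges(self):
        return merge_range_tables([
            build_range_table({"theta_auto": {
                "parent-offspring": np.linspace(0.22, 0.28, 50),
                "siblings": np.linspace(0.21, 0.29, 50),
                "2nd degree": np.linspace(0.09, 0.16, 50),
                "3rd degree": np.linspace(0.04, 0.08, 50),
                "unrelated": np.linspace(0.0, 0.04, 50),
            }}, n_snps=5000),
        ])

    def test_zero_theta_unrelated(self, ranges):
        assert classify_degree(0.0, 5000, ranges).degree == "unrelated"

    def test_first_degree_unique(self, ranges):
        call = classify_degree(0.25, 157_000, ranges)
        assert call.degree == "1st" and not call.ambiguous

    def test_ambiguous_when_intervals_overlap(self):
        rt = build_range_table({"theta_auto": {
            "parent-offspring": np.linspace(0.15, 0.30, 50),
            "2nd degree": np.linspace(0.08, 0.20, 50),
            "unrelated": np.linspace(0.0, 0.05, 50),
        }}, n_snps=5000)
        call = classify_degree(0.18, 5000, rt)
        assert call.ambiguous and set(call.candidates) == {"1st", "2nd"}

    def test_inbred_flag_above_all_intervals(self, ranges):
        call = classify_degree(0.45, 5000, ranges)
        assert "possible inbred/identical" in call.flags

    def test_gap_assigns_nearest_with_flag(self, ranges):
        call = classify_degree(0.185, 5000, ranges)
        assert "out_of_range" in call.flags
        assert call.degree in ("1st", "2nd")


def test_mismatch_and_ml_rank_together():
    """The windowed-mismatch proxy and the EM estimator order a mixed cohort
    consistently (rank correlation over PO, 2nd-degree and unrelated pairs)."""
    from scipy.stats import spearmanr
    from paleokin.pedigree_sim import three_generation_pedigree, drop_pedigree
    panel = generate_panel(SimConfig(seed=21, n_snps_auto=5000, n_snps_x=0))
    ped = three_generation_pedigree(2, 2)
    auto_f, x_f = simulate_founders(panel, ped, 1)
    auto, _ = drop_pedigree(ped, auto_f, x_f, panel, np.random.default_rng(2))
    gm = degrade(diploid_matrix(ped, auto, None), 1.0, 0.005, 3)
    ids = sorted(ped.members)
    pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
    profiles = mismatch_theta(gm, panel, pairs)
    ml = [ml_cotterman(gm, panel, p, eps=0.005).theta_auto for p in pairs]
    rho = spearmanr([p.theta_proxy for p in profiles], ml).statistic
    assert rho >= 0.9
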