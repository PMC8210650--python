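"""Kinship and Cotterman-coefficient estimation from sparse genotype data.

Two complementary estimators:

* :func:`mismatch_theta` — a non-parametric windowed mismatch-rate statistic
  (P0) on pseudo-haploid data: the genome-wide mismatch rate of a pair,
  normalised by the cohort median (the level of an average unrelated pair),
  gives ``theta_proxy = 1 - P0/median``.
* :func:`ml_cotterman` — maximum-likelihood estimation of the Cotterman
  coefficients (k0, k1, k2), the probabilities a pair shares 0, 1 or 2
  alleles identical-by-descent at a locus, by expectation-maximisation over
  the 2-simplex.  The kinship coefficient follows as theta = k1/4 + k2/2.

For pseudo-haploid inputs the observation per site is a single sampled
allele per individual; such data constrain theta but leave (k0, k1, k2)
identifiable only up to the line of constant theta — documented in the
methods note and reflected in how downstream classification uses theta.

Autosomal estimates are reported only for pairs with >= 5,000 overlapping
SNPs and X estimates only with >= 800, thresholds below which kinship
estimates on ancient data are empirically unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, SnpPanel
from .pedigree_sim import RangeTable

AUTOSOMAL_SNP_THRESHOLD = 5_000
X_SNP_THRESHOLD = 800


class KinshipError(ValueError):
    pass


def theta_from_k(k1: float, k2: float) -> float:
    """Kinship coefficient from Cotterman coefficients: theta = k1/4 + k2/2."""
    return k1 / 4.0 + k2 / 2.0


@dataclass
class KinshipEstimate:
    pair: tuple[str, str]
    k0: float
    k1: float
    k2: float
    theta_auto: float
    n_snps_auto: int
    theta_x: float | None = None
    n_snps_x: int | None = None
    ci_auto: tuple[float, float] | None = None
    ci_x: tuple[float, float] | None = None
    method: str = "ml"
    loglik: float | None = None
    n_iter: int | None = None

    def __post_init__(self) -> None:
        total = self.k0 + self.k1 + self.k2
        if abs(total - 1.0) > 1e-6:
            raise KinshipError(f"k0+k1+k2 = {total} != 1")
        if abs(self.theta_auto - theta_from_k(self.k1, self.k2)) > 1e-9:
            raise KinshipError("theta inconsistent with stored k's")


@dataclass
class MismatchProfile:
    pair: tuple[str, str]
    window_rates: np.ndarray
    window_counts: np.ndarray
    p0: float
    normalized_p0: float | None = None
    theta_proxy: float | None = None


# ---------------------------------------------------------------------------
# windowed mismatch rate (P0)
# ---------------------------------------------------------------------------

def mismatch_theta(gm: GenotypeMatrix, panel: SnpPanel,
                   pairs: Sequence[tuple[str, str]],
                   window_bp: int = 1_000_000,
                   snp_weighted: bool = False) -> list[MismatchProfile]:
    """Windowed mismatch-rate kinship proxy on pseudo-haploid data.

    P0 per pair is the unweighted mean of per-window mismatch rates over
    non-overlapping ``window_bp`` windows (windows with no jointly called
    SNPs are skipped; ``snp_weighted`` switches to a SNP-count-weighted
    mean).  Each P0 is normalised by the median P0 over all supplied pairs
    and ``theta_proxy = 1 - normalized_p0``.
    """
    if gm.ploidy_mode != "pseudohaploid":
        raise KinshipError("mismatch_theta expects pseudo-haploid calls")
    if len(pairs) < 2:
        raise KinshipError("need >= 2 pairs: the median defines the unrelated level")
    chroms = panel.chromosomes
    pos = panel.positions
    # global window index: windows start at position 1 within each chromosome
    window_id = np.zeros(panel.n_snps, dtype=np.int64)
    offset = 0
    for chrom in pd.unique(chroms):
        m = chroms == chrom
        w = (pos[m] - 1) // window_bp
        window_id[m] = offset + w
        offset += int(w.max()) + 1 if m.any() else 0

    profiles = []
    for a, b in pairs:
        ga, gb = gm.row(a), gm.row(b)
        ok = (ga != MISSING) & (gb != MISSING)
        if not ok.any():
            raise KinshipError(f"pair ({a}, {b}) shares no SNPs")
        mism = (ga != gb)[ok].astype(float)
        wid = window_id[ok]
        order = np.argsort(wid, kind="stable")
        wid, mism = wid[order], mism[order]
        uniq, start = np.unique(wid, return_index=True)
        counts = np.diff(np.append(start, len(wid)))
        sums = np.add.reduceat(mism, start)
        rates = sums / counts
        p0 = (float(np.sum(sums) / np.sum(counts)) if snp_weighted
              else float(np.mean(rates)))
        profiles.append(MismatchProfile(pair=(a, b), window_rates=rates,
                                        window_counts=counts, p0=p0))
    median_p0 = float(np.median([p.p0 for p in profiles]))
    if median_p0 == 0:
        raise KinshipError("median P0 is zero; cohort has no variation")
    for p in profiles:
        p.normalized_p0 = p.p0 / median_p0
        p.theta_proxy = 1.0 - p.normalized_p0
    return profiles


# ---------------------------------------------------------------------------
# genotype-pair likelihoods
# ---------------------------------------------------------------------------

def _diploid_pair_likelihoods(freq: np.ndarray, eps: float) -> np.ndarray:
    """P(observed g_i, g_j | m alleles IBD) for diploid 0/1/2 calls.

    Returns array (n_snps, 3, 3, 3): [snp, gi, gj, m].  ``eps`` is a
    per-allele read error: each of the two allele observations flips
    independently with probability eps.
    """
    p = np.asarray(freq, dtype=float)
    q = 1.0 - p
    n = p.size
    # true-genotype pair probabilities per IBD state
    joint = np.zeros((n, 3, 3, 3))
    hw = np.stack([q * q, 2 * p * q, p * p], axis=1)      # (n, 3)
    # m = 0: independent HWE genotypes
    joint[:, :, :, 0] = hw[:, :, None] * hw[:, None, :]
    # m = 1: one shared allele
    joint[:, 0, 0, 1] = q ** 3
    joint[:, 0, 1, 1] = q * q * p
    joint[:, 1, 0, 1] = q * q * p
    joint[:, 1, 1, 1] = p * q            # p*q*(p + q)
    joint[:, 1, 2, 1] = p * p * q
    joint[:, 2, 1, 1] = p * p * q
    joint[:, 2, 2, 1] = p ** 3
    # m = 2: identical genotypes under HWE
    joint[:, 0, 0, 2] = q * q
    joint[:, 1, 1, 2] = 2 * p * q
    joint[:, 2, 2, 2] = p * p
    if eps > 0:
        e = _genotype_error_matrix(eps)  # (3, 3): P(obs | true)
        joint = np.einsum("nghm,ag,bh->nabm", joint, e, e)
    return joint


def _genotype_error_matrix(eps: float) -> np.ndarray:
    a = 1.0 - eps
    # observed counts of alt alleles when each of two allele reads flips w.p. eps
    return np.array([
        [a * a, 2 * a * eps, eps * eps],
        [a * eps, a * a + eps * eps, a * eps],
        [eps * eps, 2 * a * eps, a * a],
    ]).T


def _pseudohaploid_pair_likelihoods(freq: np.ndarray, eps: float) -> np.ndarray:
    """P(observed single alleles a_i, a_j | m IBD) for pseudo-haploid calls.

    The sampled alleles are themselves IBD with probability delta_m = m/4 for
    m in {0, 1, 2}; conditional on IBD they are one draw from Bernoulli(p)
    seen twice, otherwise two independent draws.  Observation error flips
    each observed allele with probability eps.

    Returns (n_snps, 2, 2, 3): [snp, a_i, a_j, m].
    """
    p = np.asarray(freq, dtype=float)
    q = 1.0 - p
    # observed-allele probability accounting for flip error
    p_obs = p * (1 - eps) + q * eps
    q_obs = 1.0 - p_obs
    n = p.size
    shared = np.zeros((n, 2, 2))
    # same underlying allele a ~ Bern(p), observed twice with independent flips
    shared[:, 0, 0] = q * (1 - eps) ** 2 + p * eps ** 2
    shared[:, 1, 1] = p * (1 - eps) ** 2 + q * eps ** 2
    shared[:, 0, 1] = (1 - eps) * eps
    shared[:, 1, 0] = (1 - eps) * eps
    indep = np.empty((n, 2, 2))
    indep[:, 0, 0] = q_obs * q_obs
    indep[:, 0, 1] = q_obs * p_obs
    indep[:, 1, 0] = p_obs * q_obs
    indep[:, 1, 1] = p_obs * p_obs
    delta = np.array([0.0, 0.25, 0.5])
    return (delta[None, None, None, :] * shared[:, :, :, None]
            + (1 - delta)[None, None, None, :] * indep[:, :, :, None])


def _pair_likelihood_matrix(gm: GenotypeMatrix, panel: SnpPanel,
                            pair: tuple[str, str], eps: float) -> np.ndarray:
    """Per-SNP likelihoods L[snp, m] at jointly called SNPs of the pair."""
    a, b = pair
    ga, gb = gm.row(a), gm.row(b)
    freq = panel.bg_freq
    ok = (ga != MISSING) & (gb != MISSING) & ~np.isnan(freq)
    if not ok.any():
        raise KinshipError(f"pair ({a}, {b}): no jointly called SNPs with bg_freq")
    f = np.clip(freq[ok], 1e-6, 1 - 1e-6)
    if gm.ploidy_mode == "diploid":
        tab = _diploid_pair_likelihoods(f, eps)
    else:
        tab = _pseudohaploid_pair_likelihoods(f, eps)
    idx = np.arange(ok.sum())
    return tab[idx, ga[ok], gb[ok], :]


def _em_step(lik: np.ndarray, k: np.ndarray) -> np.ndarray:
    mix = lik @ k
    w = lik * k / mix[:, None]         # responsibilities (n, 3)
    k = w.mean(axis=0)
    return k / k.sum()


def _loglik(lik: np.ndarray, k: np.ndarray) -> float:
    return float(np.sum(np.log(lik @ k)))


def _em_simplex(lik: np.ndarray, tol: float, max_iter: int):
    """EM for mixture weights k over per-SNP component likelihoods (n, 3).

    Uses squared extrapolation (SQUAREM) to accelerate the slow approach to
    simplex boundaries; an extrapolated step is only accepted when it does
    not decrease the log-likelihood, so the recorded trajectory stays
    monotone.  Convergence combines the log-likelihood gain (< tol) with a
    KKT stationarity check — max_m mean_i(L_im / mix_i) - 1 vanishes at the
    constrained MLE — which terminates boundary cases whose likelihood gain
    criterion alone would stop too early or creep for thousands of
    iterations.  Returns (k, loglik, n_iter, trajectory of logliks).
    """
    k = np.full(3, 1.0 / 3.0)
    logliks = [_loglik(lik, k)]
    for it in range(1, max_iter + 1):
        k1 = _em_step(lik, k)
        k2 = _em_step(lik, k1)
        r = k1 - k
        v = (k2 - k1) - r
        vnorm = float(np.linalg.norm(v))
        accepted = k2
        if vnorm > 0:
            alpha = -float(np.linalg.norm(r)) / vnorm
            cand = k - 2.0 * alpha * r + alpha * alpha * v
            cand = np.clip(cand, 1e-12, None)
            cand /= cand.sum()
            # one stabilising EM step, then keep only if no worse than plain EM
            cand = _em_step(lik, cand)
            if _loglik(lik, cand) >= _loglik(lik, k2):
                accepted = cand
        mix = lik @ accepted
        ll = float(np.sum(np.log(mix)))
        kkt = float((lik / mix[:, None]).mean(axis=0).max()) - 1.0
        delta = float(np.max(np.abs(accepted - k)))
        k = accepted
        logliks.append(ll)
        if (kkt < 1e-8 or delta < 1e-12
                or (ll - logliks[-2] < tol and kkt < 1e-5)):
            break
    return k, logliks[-1], it, np.asarray(logliks)


def ml_cotterman(gm: GenotypeMatrix, panel: SnpPanel, pair: tuple[str, str],
                 eps: float = 0.005, tol: float = 1e-9, max_iter: int = 5000,
                 return_trajectory: bool = False):
    """Constrained MLE of (k0, k1, k2) for one pair by EM.

    Maximises sum over jointly called SNPs of
    ``log sum_m k_m P(g_i, g_j | m IBD, freq, eps)`` over the 2-simplex.
    """
    lik = _pair_likelihood_matrix(gm, panel, pair, eps)
    k, ll, n_iter, traj = _em_simplex(lik, tol, max_iter)
    if n_iter >= max_iter:
        grad = np.abs(lik / (lik @ k)[:, None]).mean(axis=0)
        raise KinshipError(
            f"EM did not converge in {max_iter} iterations "
            f"(mean scaled gradient {grad})")
    est = KinshipEstimate(pair=pair, k0=float(k[0]), k1=float(k[1]), k2=float(k[2]),
                          theta_auto=theta_from_k(float(k[1]), float(k[2])),
                          n_snps_auto=lik.shape[0], loglik=ll, n_iter=n_iter)
    if return_trajectory:
        return est, traj
    return est


def estimate_theta(gm: GenotypeMatrix, panel: SnpPanel, pair: tuple[str, str],
                   eps: float = 0.005) -> float:
    """Convenience: theta from the EM Cotterman fit."""
    return ml_cotterman(gm, panel, pair, eps=eps).theta_auto


def bootstrap_theta(gm: GenotypeMatrix, panel: SnpPanel, pair: tuple[str, str],
                    n_boot: int = 100, seed: int = 0, eps: float = 0.005,
                    level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap CI for theta by resampling SNP columns."""
    lik = _pair_likelihood_matrix(gm, panel, pair, eps)
    rng = np.random.default_rng(seed)
    n = lik.shape[0]
    thetas = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        k, _, _, _ = _em_simplex(lik[idx], tol=1e-8, max_iter=5000)
        thetas[b] = theta_from_k(k[1], k[2])
    alpha = (1.0 - level) / 2.0
    return (float(np.quantile(thetas, alpha)), float(np.quantile(thetas, 1 - alpha)))


# ---------------------------------------------------------------------------
# thresholds and degree classification
# ---------------------------------------------------------------------------

def pair_overlap(gm: GenotypeMatrix, pair: tuple[str, str],
                 mask: np.ndarray | None = None) -> int:
    ga, gb = gm.row(pair[0]), gm.row(pair[1])
    ok = (ga != MISSING) & (gb != MISSING)
    if mask is not None:
        ok &= mask
    return int(ok.sum())


def apply_snp_thresholds(overlaps: Mapping[tuple[str, str], tuple[int, int | None]],
                         auto_min: int = AUTOSOMAL_SNP_THRESHOLD,
                         x_min: int = X_SNP_THRESHOLD):
    """Partition pairs by the overlap thresholds (inclusive).

    ``overlaps[pair] = (n_auto, n_x or None)``.  Returns
    ``(retained, excluded)`` where ``retained[pair] = {'auto': bool, 'x': bool}``
    and ``excluded`` lists (pair, reason) for pairs failing the autosomal
    threshold.  A pair failing only the X threshold keeps its autosomal
    estimate with the X estimate suppressed.
    """
    retained: dict[tuple[str, str], dict[str, bool]] = {}
    excluded: list[tuple[tuple[str, str], str]] = []
    for pair, (n_auto, n_x) in overlaps.items():
        if n_auto < auto_min:
            excluded.append((pair, f"autosomal overlap {n_auto} < {auto_min}"))
            continue
        retained[pair] = {"auto": True,
                          "x": n_x is not None and n_x >= x_min}
    return retained, excluded


@dataclass
class DegreeCall:
    degree: str                       # '1st', '2nd', '3rd', 'unrelated'
    candidates: list[str] = field(default_factory=list)
    ambiguous: bool = False
    flags: list[str] = field(default_factory=list)


_DEGREE_ORDER = ("unrelated", "3rd", "2nd", "1st")


def classify_degree(theta: float, n_snps: int, range_table: RangeTable,
                    statistic: str = "theta_auto") -> DegreeCall:
    """Assign a relatedness degree by the simulated theta intervals.

    The degree whose simulated interval contains ``theta`` wins; multiple
    containing intervals are all reported with an ambiguity flag.  A theta
    above every interval gets the 'possible inbred/identical' flag (values
    above first-degree expectations can reflect inbreeding or duplicate
    sampling); a theta inside a gap is assigned the degree with the nearest
    interval edge and flagged 'out_of_range'.
    """
    from .pedigree_sim import DEGREE_OF_CLASS

    intervals: dict[str, tuple[float, float]] = {}
    for rel_class in range_table.classes(statistic):
        degree = DEGREE_OF_CLASS.get(rel_class, rel_class)
        if degree not in _DEGREE_ORDER:
            continue
        lo, hi = range_table.lookup(statistic, rel_class, n_snps)
        if degree in intervals:
            lo = min(lo, intervals[degree][0])
            hi = max(hi, intervals[degree][1])
        intervals[degree] = (lo, hi)

    hits = [d for d, (lo, hi) in intervals.items() if lo <= theta <= hi]
    if hits:
        hits.sort(key=_DEGREE_ORDER.index)
        return DegreeCall(degree=hits[-1], candidates=hits,
                          ambiguous=len(hits) > 1,
                          flags=(["ambiguous"] if len(hits) > 1 else []))
    top = max(hi for _, hi in intervals.values())
    if theta > top:
        return DegreeCall(degree="1st", candidates=["1st"],
                          flags=["possible inbred/identical"])
    nearest = min(intervals,
                  key=lambda d: min(abs(theta - intervals[d][0]),
                                    abs(theta - intervals[d][1])))
    return DegreeCall(degree=nearest, candidates=[nearest], flags=["out_of_range"])
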