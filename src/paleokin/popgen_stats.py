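"""f3/D statistics, resampling tests on burial data, and Fisher exact tests.

The outgroup f3 statistic f3(O; A, B) measures the shared genetic drift of A
and B relative to a distant outgroup; 1 - f3 serves as a pairwise genetic
distance.  Standard errors come from a weighted block jackknife over
contiguous physical blocks, which respects linkage.  The D statistic
(ABBA-BABA) tests four-taxon allele-sharing asymmetry with |Z| >= 3 as the
nominal significance cutoff.

Resampling machinery: a group-membership permutation test for within-group
diversity differences, a one-sided Mantel test correlating spatial and
genetic distance matrices, and a building-assignment permutation test for
within-building genetic similarity.  Contingency analyses use the two-sided
Fisher exact test with the conditional-MLE odds ratio (the convention of the
R implementation).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .genotype_io import MISSING, IndividualMeta

logger = logging.getLogger(__name__)


class PopgenError(ValueError):
    pass


# ---------------------------------------------------------------------------
# weighted block jackknife
# ---------------------------------------------------------------------------

def _block_ids(chromosomes: np.ndarray, positions: np.ndarray,
               block_size: int) -> np.ndarray:
    """Contiguous physical blocks of ``block_size`` bp, numbered genome-wide."""
    ids = np.zeros(len(positions), dtype=np.int64)
    offset = 0
    for chrom in np.unique(chromosomes):
        m = chromosomes == chrom
        b = (positions[m] - 1) // block_size
        # renumber to consecutive ids so empty blocks don't count
        _, b = np.unique(b, return_inverse=True)
        ids[m] = offset + b
        offset += b.max() + 1
    return ids


def block_jackknife_ratio(num: np.ndarray, den: np.ndarray,
                          block_ids: np.ndarray) -> tuple[float, float, int]:
    """Estimate ``sum(num)/sum(den)`` with a weighted block-jackknife SE.

    Weights are per-block denominators (for f3 the per-block SNP counts).
    Returns (estimate, SE, n_blocks).
    """
    uniq = np.unique(block_ids)
    g = len(uniq)
    if g < 2:
        raise PopgenError("need >= 2 jackknife blocks")
    num_b = np.array([num[block_ids == b].sum() for b in uniq])
    den_b = np.array([den[block_ids == b].sum() for b in uniq])
    tot_num, tot_den = num_b.sum(), den_b.sum()
    if tot_den == 0:
        raise PopgenError("degenerate denominator")
    est = tot_num / tot_den
    loo = (tot_num - num_b) / (tot_den - den_b)
    m = den_b.astype(float)          # block weights
    big_m = m.sum()
    h = big_m / m
    theta_j = g * est - np.sum((1.0 - m / big_m) * loo)
    tau = h * est - (h - 1.0) * loo
    var = np.sum((tau - theta_j) ** 2 / (h - 1.0)) / g
    return float(est), float(np.sqrt(var)), g


@dataclass
class F3Result:
    outgroup: str
    a: str
    b: str
    f3: float
    se: float
    n_snps: int
    n_blocks: int


def outgroup_f3(outgroup_freqs: np.ndarray, geno_a: np.ndarray, geno_b: np.ndarray,
                chromosomes: np.ndarray, positions: np.ndarray,
                block_size: int = 5_000_000, n_outgroup_chroms: int | None = None,
                labels: tuple[str, str, str] = ("outgroup", "A", "B")) -> F3Result:
    """Outgroup f3(O; A, B) for two pseudo-haploid individuals.

    Per SNP the contribution is ``(f_O - g_A)(f_O - g_B)`` with g in {0, 1};
    when ``n_outgroup_chroms`` is given, the finite-sample heterozygosity
    correction ``f_O(1-f_O)/(n-1)`` is subtracted from the outgroup term.
    """
    ok = ((geno_a != MISSING) & (geno_b != MISSING) & ~np.isnan(outgroup_freqs))
    if not ok.any():
        raise PopgenError("no SNPs usable in all three roles")
    f = outgroup_freqs[ok]
    ga = geno_a[ok].astype(float)
    gb = geno_b[ok].astype(float)
    num = (f - ga) * (f - gb)
    if n_outgroup_chroms is not None:
        num = num - f * (1.0 - f) / (n_outgroup_chroms - 1)
    den = np.ones_like(num)
    blocks = _block_ids(chromosomes[ok], positions[ok], block_size)
    est, se, g = block_jackknife_ratio(num, den, blocks)
    return F3Result(outgroup=labels[0], a=labels[1], b=labels[2], f3=est, se=se,
                    n_snps=int(ok.sum()), n_blocks=g)


@dataclass
class DStatResult:
    labels: tuple[str, str, str, str]
    d: float
    se: float
    z: float
    n_snps: int
    n_blocks: int

    @property
    def significant(self) -> bool:
        return abs(self.z) >= 3.0


def d_statistic(w: np.ndarray, x: np.ndarray, y: np.ndarray, z: np.ndarray,
                chromosomes: np.ndarray, positions: np.ndarray,
                block_size: int = 5_000_000,
                labels: tuple[str, str, str, str] = ("W", "X", "Y", "Z")) -> DStatResult:
    """ABBA-BABA D statistic over allele frequencies or 0/1 genotypes.

    D = sum[(w - x)(y - z)] / sum[(w + x - 2wx)(y + z - 2yz)]; inputs may be
    frequencies in [0, 1] or pseudo-haploid calls with MISSING (-1) masked.
    Z score from the weighted block jackknife; |Z| >= 3 flags significance.
    """
    arrs = [np.asarray(v, dtype=float) for v in (w, x, y, z)]
    ok = np.ones(arrs[0].size, dtype=bool)
    for v in arrs:
        ok &= (v != MISSING) & ~np.isnan(v)
    if not ok.any():
        raise PopgenError("no usable SNPs")
    wf, xf, yf, zf = (v[ok] for v in arrs)
    num = (wf - xf) * (yf - zf)
    den = (wf + xf - 2 * wf * xf) * (yf + zf - 2 * yf * zf)
    if den.sum() == 0:
        if np.all(num == 0):
            # y and z carry identical information: D = 0 by symmetry
            return DStatResult(labels=labels, d=0.0, se=0.0, z=0.0,
                               n_snps=int(ok.sum()), n_blocks=0)
        raise PopgenError("degenerate denominator (no informative SNPs)")
    blocks = _block_ids(chromosomes[ok], positions[ok], block_size)
    est, se, g = block_jackknife_ratio(num, den, blocks)
    zscore = est / se if se > 0 else np.inf * np.sign(est) if est else 0.0
    return DStatResult(labels=labels, d=est, se=se, z=float(zscore),
                       n_snps=int(ok.sum()), n_blocks=g)


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray
    kind: str = "genetic"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise PopgenError("distance matrix shape mismatch")
        if not np.allclose(v, v.T):
            raise PopgenError("distance matrix not symmetric")
        if np.any(np.diag(v) != 0):
            raise PopgenError("nonzero diagonal")
        self.values = v

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)], self.kind)

    def upper(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]


def euclidean_distances(inds: Sequence[IndividualMeta]) -> DistanceMatrix:
    """Planar Euclidean distances between burial coordinates."""
    ids, coords = [], []
    for m in inds:
        if m.x is None or m.y is None:
            raise PopgenError(f"individual {m.id} lacks coordinates")
        ids.append(m.id)
        coords.append((m.x, m.y))
    c = np.asarray(coords)
    diff = c[:, None, :] - c[None, :, :]
    return DistanceMatrix(ids, np.sqrt((diff ** 2).sum(axis=2)), kind="spatial")


def genetic_distance_from_f3(ids: Sequence[str],
                             f3_values: Mapping[tuple[str, str], float]) -> DistanceMatrix:
    """1 - f3 pairwise genetic distance matrix from outgroup-f3 values."""
    n = len(ids)
    mat = np.zeros((n, n))
    for i, a in enumerate(ids):
        for j in range(i + 1, n):
            b = ids[j]
            f3 = f3_values.get((a, b), f3_values.get((b, a)))
            if f3 is None:
                raise PopgenError(f"missing f3 for pair ({a}, {b})")
            mat[i, j] = mat[j, i] = 1.0 - f3
    return DistanceMatrix(list(ids), mat, kind="genetic")


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

def diversity_permutation_test(group_a: Sequence[str], group_b: Sequence[str],
                               dist: DistanceMatrix, n_perm: int = 10_000,
                               seed: int = 0) -> tuple[float, float]:
    """Two-group within-group diversity contrast by membership permutation.

    Observed statistic: |mean within-A distance - mean within-B distance|;
    the null permutes group membership over the union.  Note permutation
    tests of this design are conservative.
    """
    if set(group_a) & set(group_b):
        raise PopgenError("groups overlap")
    ids = list(group_a) + list(group_b)
    sub = dist.submatrix(ids)
    n_a = len(group_a)
    labels = np.zeros(len(ids), dtype=bool)
    labels[:n_a] = True

    def stat(lab: np.ndarray) -> float:
        wa = sub.values[np.ix_(lab, lab)]
        wb = sub.values[np.ix_(~lab, ~lab)]
        iu_a = np.triu_indices(lab.sum(), k=1)
        iu_b = np.triu_indices((~lab).sum(), k=1)
        return abs(float(wa[iu_a].mean()) - float(wb[iu_b].mean()))

    observed = stat(labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if stat(perm) >= observed:
            count += 1
    p = (count + 1) / (n_perm + 1)
    logger.info("diversity test: observed |delta|=%.4g, p=%.4g (conservative)",
                observed, p)
    return observed, p


def mantel_test(spatial: DistanceMatrix, genetic: DistanceMatrix,
                n_perm: int = 9_999, seed: int = 0,
                exact: bool = False) -> tuple[float, float]:
    """One-sided Mantel test for positive spatial-genetic correlation.

    Pearson r over upper-triangle entries; the null permutes rows/columns of
    one matrix jointly.  ``exact=True`` enumerates all permutations (small n).
    """
    if spatial.ids != genetic.ids:
        raise PopgenError("matrices must share ids in the same order")
    n = len(spatial.ids)
    if n < 4:
        raise PopgenError("need n >= 4 for a meaningful Mantel test")
    iu = np.triu_indices(n, k=1)
    x = spatial.values[iu]
    if np.std(x) == 0 or np.std(genetic.values[iu]) == 0:
        raise PopgenError("constant distance matrix: r undefined")

    def corr(mat: np.ndarray) -> float:
        return float(np.corrcoef(x, mat[iu])[0, 1])

    observed = corr(genetic.values)
    if exact:
        perms = itertools.permutations(range(n))
        rs = [corr(genetic.values[np.ix_(p, p)]) for p in perms]
        rs = np.asarray(rs)
        p = float(np.mean(rs >= observed - 1e-12))
        return observed, p
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p_idx = rng.permutation(n)
        if corr(genetic.values[np.ix_(p_idx, p_idx)]) >= observed - 1e-12:
            count += 1
    return observed, (count + 1) / (n_perm + 1)


def within_building_test(building_of: Mapping[str, str],
                         similarity: DistanceMatrix, n_perm: int = 10_000,
                         seed: int = 0) -> tuple[float, float]:
    """Permutation test for elevated within-building genetic similarity.

    ``similarity`` holds pairwise f3-like similarities (stored in a
    symmetric matrix; the zero diagonal is ignored).  The observed mean of
    within-building pair similarities is compared to the null obtained by
    randomly reassigning individuals to buildings preserving building sizes;
    one-sided p for higher-than-random similarity.
    """
    ids = [i for i in similarity.ids if i in building_of]
    buildings = np.asarray([building_of[i] for i in ids])
    if len(set(buildings)) < 2:
        raise PopgenError("need >= 2 buildings")
    sub = similarity.submatrix(ids)
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    within = (buildings[iu[0]] == buildings[iu[1]])
    if not within.any():
        raise PopgenError("no within-building pairs")
    vals = sub.values[iu]
    observed = float(vals[within].mean())
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pb = buildings[perm]
        w = pb[iu[0]] == pb[iu[1]]
        if float(vals[w].mean()) >= observed - 1e-12:
            count += 1
    return observed, (count + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------

@dataclass
class FisherResult:
    odds_ratio: float
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]


def fisher_exact(table: Sequence[Sequence[int]]) -> FisherResult:
    """Two-sided Fisher exact test with the conditional-MLE odds ratio.

    The odds ratio maximises the noncentral hypergeometric likelihood given
    the margins; the two-sided p sums the probabilities of all outcomes no
    more probable than the observed one.  Zero margins yield OR 0 or inf
    with exact p = 1.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise PopgenError("need a 2x2 table of non-negative counts")
    if t.sum() == 0:
        raise PopgenError("all-zero table")
    p = float(stats.fisher_exact(t, alternative="two-sided").pvalue)
    orr = _odds_ratio(t, kind="conditional").statistic
    if np.isnan(orr):
        orr = 1.0  # degenerate margin: the table carries no association signal
    return FisherResult(odds_ratio=float(orr), p_value=p,
                        table=((int(t[0, 0]), int(t[0, 1])),
                               (int(t[1, 0]), int(t[1, 1]))))


# ---------------------------------------------------------------------------
# relative filtering
# ---------------------------------------------------------------------------

def relative_filter(ids: Sequence[str], related_pairs: Sequence[tuple[str, str]],
                    coverage: Mapping[str, float]) -> list[str]:
    """Greedy maximal set with no retained 1st-3rd degree pair.

    Individuals are admitted in descending coverage order (ties broken by
    id) provided they are not related to anyone already kept — i.e. of each
    close pair the higher-coverage member survives.
    """
    related: dict[str, set[str]] = {i: set() for i in ids}
    for a, b in related_pairs:
        related[a].add(b)
        related[b].add(a)
    order = sorted(ids, key=lambda i: (-coverage.get(i, 0.0), i))
    kept: list[str] = []
    for i in order:
        if not related[i] & set(kept):
            kept.append(i)
    return [i for i in ids if i in kept]
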