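"""Pedigree structures, gamete simulation and simulation-calibrated ranges.

Founder genomes are transmitted down a pedigree: autosomes by a crossover
process on the genetic map (Poisson by default, gamma-renewal interference
optionally), the X chromosome by a four-segment model in which three cut
points are drawn among SNP locations on the maternal X and each of the four
segments is copied whole from one of the two maternal haplotypes.  Sons
receive only the maternal X gamete; daughters additionally receive their
father's single X unchanged.

Kinship-statistic distributions estimated on such simulated data, subsampled
to the SNP counts observed in real pairs, yield the quantile range tables
used to classify empirical estimates by degree of relatedness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, SnpPanel

RELATIONSHIP_CLASSES = (
    "identical", "parent-offspring", "siblings", "half-siblings", "avuncular",
    "grandparent-grandchild", "2nd degree", "3rd degree", "unrelated",
)

DEGREE_OF_CLASS = {
    "identical": "identical",
    "parent-offspring": "1st",
    "siblings": "1st",
    "half-siblings": "2nd",
    "avuncular": "2nd",
    "grandparent-grandchild": "2nd",
    "2nd degree": "2nd",
    "3rd degree": "3rd",
    "unrelated": "unrelated",
}


class PedigreeError(ValueError):
    pass


@dataclass
class Member:
    id: str
    sex: str                      # 'F' or 'M'
    mother: str | None = None
    father: str | None = None

    @property
    def is_founder(self) -> bool:
        return self.mother is None and self.father is None


@dataclass
class Pedigree:
    """Acyclic pedigree; every non-founder has one mother (F) and one father (M)."""

    members: dict[str, Member] = field(default_factory=dict)

    def add(self, id: str, sex: str, mother: str | None = None,
            father: str | None = None) -> None:
        if (mother is None) != (father is None):
            raise PedigreeError(f"{id}: need both parents or neither")
        self.members[id] = Member(id, sex, mother, father)

    def validate(self) -> None:
        for m in self.members.values():
            if m.mother is not None:
                if self.members[m.mother].sex != "F":
                    raise PedigreeError(f"mother of {m.id} is not female")
                if self.members[m.father].sex != "M":
                    raise PedigreeError(f"father of {m.id} is not male")
        self.topological_order()  # raises on cycles

    @property
    def founders(self) -> list[str]:
        return [m.id for m in self.members.values() if m.is_founder]

    def topological_order(self) -> list[str]:
        order: list[str] = []
        state: dict[str, int] = {}

        def visit(i: str) -> None:
            if state.get(i) == 2:
                return
            if state.get(i) == 1:
                raise PedigreeError("pedigree contains a cycle")
            state[i] = 1
            m = self.members[i]
            if m.mother is not None:
                visit(m.mother)
                visit(m.father)
            state[i] = 2
            order.append(i)

        for i in self.members:
            visit(i)
        return order

    # -- identity-by-descent path counting -------------------------------

    def kinship(self, a: str, b: str) -> float:
        """Autosomal kinship coefficient by recursive path counting."""
        depth = {i: d for d, i in enumerate(self.topological_order())}
        cache: dict[tuple[str, str], float] = {}

        def phi(i: str, j: str) -> float:
            key = (i, j) if i <= j else (j, i)
            if key in cache:
                return cache[key]
            if i == j:
                mi = self.members[i]
                f = 0.0 if mi.is_founder else phi(mi.mother, mi.father)
                val = 0.5 * (1.0 + f)
            else:
                # recurse on the member farther from the founders
                if depth[i] < depth[j]:
                    i, j = j, i
                mi = self.members[i]
                if mi.is_founder:
                    val = 0.0
                else:
                    val = 0.5 * (phi(mi.mother, j) + phi(mi.father, j))
            cache[key] = val
            return val

        return phi(a, b)

    def x_kinship(self, a: str, b: str) -> float:
        """X-chromosome kinship: males are haploid, transmit X only to daughters."""
        depth = {i: d for d, i in enumerate(self.topological_order())}
        cache: dict[tuple[str, str], float] = {}

        def phi(i: str, j: str) -> float:
            key = (i, j) if i <= j else (j, i)
            if key in cache:
                return cache[key]
            mi, mj = self.members[i], self.members[j]
            if i == j:
                if mi.sex == "M":
                    val = 1.0
                else:
                    f = 0.0 if mi.is_founder else phi(mi.mother, mi.father)
                    val = 0.5 * (1.0 + f)
            else:
                if depth[i] < depth[j]:
                    i, j = j, i
                    mi = self.members[i]
                if mi.is_founder:
                    val = 0.0
                elif mi.sex == "M":
                    val = phi(mi.mother, j)
                else:
                    val = 0.5 * (phi(mi.mother, j) + phi(mi.father, j))
            cache[key] = val
            return val

        return phi(a, b)

    # -- relationship labelling ------------------------------------------

    def relationship_class(self, a: str, b: str) -> str:
        """Pedigree relationship class for a pair, consistent with kinship."""
        if a == b:
            return "identical"
        ma, mb = self.members[a], self.members[b]
        if a in (mb.mother, mb.father) or b in (ma.mother, ma.father):
            return "parent-offspring"
        if (ma.mother is not None and mb.mother is not None):
            shared = int(ma.mother == mb.mother) + int(ma.father == mb.father)
            if shared == 2:
                return "siblings"
            if shared == 1:
                return "half-siblings"
        phi = self.kinship(a, b)
        if phi >= 0.25 * 0.999:
            return "parent-offspring"  # double relationships collapse upward
        if abs(phi - 0.125) < 0.03:
            if self._is_grandparent(a, b) or self._is_grandparent(b, a):
                return "grandparent-grandchild"
            if self._is_avuncular(a, b) or self._is_avuncular(b, a):
                return "avuncular"
            return "2nd degree"
        if abs(phi - 0.0625) < 0.02:
            return "3rd degree"
        return "unrelated"

    def _grandparents(self, i: str) -> set[str]:
        out: set[str] = set()
        m = self.members[i]
        for p in (m.mother, m.father):
            if p is not None:
                pm = self.members[p]
                out.update(x for x in (pm.mother, pm.father) if x is not None)
        return out

    def _is_grandparent(self, a: str, b: str) -> bool:
        return a in self._grandparents(b)

    def _is_avuncular(self, a: str, b: str) -> bool:
        # a is sibling of one of b's parents
        mb = self.members[b]
        for p in (mb.mother, mb.father):
            if p is None:
                continue
            mp = self.members[p]
            ma = self.members[a]
            if (mp.mother is not None and ma.mother is not None
                    and mp.mother == ma.mother and mp.father == ma.father):
                return True
        return False

    def pairs_by_class(self) -> dict[str, list[tuple[str, str]]]:
        ids = sorted(self.members)
        out: dict[str, list[tuple[str, str]]] = {}
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                out.setdefault(self.relationship_class(a, b), []).append((a, b))
        return out


def three_generation_pedigree(n_children: int = 3,
                              grandchildren_per_couple: int = 2) -> Pedigree:
    """Default simulation pedigree: founder couple, their children married to
    unrelated founders, and grandchildren — yields parent-offspring, sibling,
    half-absent, avuncular, grandparent and unrelated pairs."""
    ped = Pedigree()
    ped.add("F0", "F")
    ped.add("M0", "M")
    for c in range(n_children):
        sex = "F" if c % 2 == 0 else "M"
        ped.add(f"C{c}", sex, mother="F0", father="M0")
        spouse_sex = "M" if sex == "F" else "F"
        ped.add(f"S{c}", spouse_sex)
        mother = f"C{c}" if sex == "F" else f"S{c}"
        father = f"S{c}" if sex == "F" else f"C{c}"
        for g in range(grandchildren_per_couple):
            ped.add(f"G{c}_{g}", "F" if g % 2 == 0 else "M",
                    mother=mother, father=father)
    ped.validate()
    return ped


# ---------------------------------------------------------------------------
# gamete formation
# ---------------------------------------------------------------------------

def autosomal_gamete(parent_phased: np.ndarray, genetic_pos_cM: np.ndarray,
                     chromosomes: np.ndarray, rng: np.random.Generator,
                     interference_shape: float | None = None) -> np.ndarray:
    """Form a haploid autosomal gamete from a phased parent.

    ``parent_phased`` is (2, n_snps).  Per chromosome, crossover positions
    follow a Poisson process on the cM map (rate 1 per Morgan); with
    ``interference_shape`` set, a stationary gamma-renewal process with that
    shape (mean inter-event distance 1 Morgan) models crossover interference.
    Segments alternate between the two parental haplotypes starting from a
    fair-coin choice.
    """
    if parent_phased.ndim != 2 or parent_phased.shape[0] != 2:
        raise PedigreeError("parent must be phased: array of shape (2, n_snps)")
    gamete = np.empty(parent_phased.shape[1], dtype=parent_phased.dtype)
    for chrom in pd.unique(chromosomes):
        idx = np.flatnonzero(chromosomes == chrom)
        cm = genetic_pos_cM[idx]
        length_m = (cm[-1] - cm[0]) / 100.0 if len(cm) > 1 else 0.0
        cuts_m = _crossover_positions(length_m, rng, interference_shape)
        cuts_cm = cm[0] + cuts_m * 100.0
        # which haplotype each SNP comes from: alternate at each crossover
        seg_index = np.searchsorted(cuts_cm, cm, side="right")
        hap = (int(rng.integers(2)) + seg_index) % 2
        gamete[idx] = parent_phased[hap, idx]
    return gamete


def _crossover_positions(length_morgan: float, rng: np.random.Generator,
                         shape: float | None) -> np.ndarray:
    if length_morgan <= 0:
        return np.empty(0)
    if shape is None:
        n = rng.poisson(length_morgan)
        return np.sort(rng.uniform(0.0, length_morgan, size=n))
    # stationary gamma renewal: first event from the equilibrium delay
    positions = []
    x = _equilibrium_gamma_delay(shape, rng)
    while x < length_morgan:
        positions.append(x)
        x += rng.gamma(shape, 1.0 / shape)
    return np.asarray(positions)


def _equilibrium_gamma_delay(shape: float, rng: np.random.Generator) -> float:
    # stationary forward recurrence time of a gamma(shape, 1/shape) renewal
    # process: uniform position within a length-biased interval, and the
    # length-biased gamma(shape) is gamma(shape + 1)
    t = rng.gamma(shape + 1.0, 1.0 / shape)
    return rng.uniform(0.0, t)


def x_gamete(mother_phased_x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Maternal X gamete by the four-segment model.

    Three distinct cut points are drawn among SNP locations, dividing the
    chromosome into four segments; each segment is copied whole from one of
    the two maternal haplotypes chosen independently with probability 1/2.
    """
    if mother_phased_x.ndim != 2 or mother_phased_x.shape[0] != 2:
        raise PedigreeError("mother X must be phased: shape (2, n_snps)")
    n = mother_phased_x.shape[1]
    if n < 4:
        raise PedigreeError("need at least 4 X SNPs for the four-segment model")
    cuts = np.sort(rng.choice(np.arange(1, n), size=3, replace=False))
    seg_index = np.searchsorted(cuts, np.arange(n), side="right")
    haps = rng.integers(0, 2, size=4)
    return mother_phased_x[haps[seg_index], np.arange(n)]


def drop_pedigree(pedigree: Pedigree, founder_auto: Mapping[str, np.ndarray],
                  founder_x: Mapping[str, np.ndarray], panel: SnpPanel,
                  rng: np.random.Generator,
                  interference_shape: float | None = None):
    """Transmit founder genomes to every pedigree member.

    ``founder_auto[id]`` is (2, n_auto) phased; ``founder_x[id]`` is (2, n_x)
    for females and (1, n_x) for males.  Returns ``(auto, x)`` dicts with the
    same shapes for all members.
    """
    auto_mask = panel.autosomal_mask()
    chroms = panel.chromosomes[auto_mask]
    cm = panel.table["genetic_pos_cM"].to_numpy()[auto_mask]
    auto: dict[str, np.ndarray] = {}
    x: dict[str, np.ndarray] = {}
    for i in pedigree.topological_order():
        m = pedigree.members[i]
        if m.is_founder:
            auto[i] = np.asarray(founder_auto[i])
            x[i] = np.atleast_2d(np.asarray(founder_x[i]))
            continue
        maternal = autosomal_gamete(auto[m.mother], cm, chroms, rng, interference_shape)
        paternal = autosomal_gamete(auto[m.father], cm, chroms, rng, interference_shape)
        auto[i] = np.stack([maternal, paternal])
        if x[m.mother].shape[1] == 0:     # panel without X SNPs
            x[i] = np.empty((1 if m.sex == "M" else 2, 0), dtype=np.int8)
            continue
        mat_x = x_gamete(x[m.mother], rng)
        if m.sex == "M":
            x[i] = mat_x[None, :]
        else:
            father_x = x[m.father]
            x[i] = np.stack([mat_x, father_x[0]])
    return auto, x


def realized_kinship(hap_a: np.ndarray, hap_b: np.ndarray) -> float:
    """Realized kinship between two sets of IBD-labelled haplotypes.

    Inputs are (ploidy, n_snps) arrays of founder-haplotype labels; the
    result is the mean over SNPs of the probability that one allele drawn
    from each individual carries the same label.
    """
    pa, n = hap_a.shape
    pb = hap_b.shape[0]
    match = np.zeros(n)
    for i in range(pa):
        for j in range(pb):
            match += hap_a[i] == hap_b[j]
    return float(np.mean(match) / (pa * pb))


def subsample_snps(gm: GenotypeMatrix, n: int, seed: int,
                   panel: SnpPanel | None = None):
    """Uniformly subsample ``n`` SNP columns without replacement (sorted order)."""
    if n > gm.n_snps:
        raise PedigreeError(f"cannot subsample {n} of {gm.n_snps} SNPs")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(gm.n_snps, size=n, replace=False))
    sub = GenotypeMatrix(list(gm.individuals), gm.calls[:, idx], gm.ploidy_mode)
    if panel is None:
        return sub
    mask = np.zeros(gm.n_snps, dtype=bool)
    mask[idx] = True
    return sub, panel.subset(mask)


# ---------------------------------------------------------------------------
# range tables and ratio moments
# ---------------------------------------------------------------------------

@dataclass
class RangeTable:
    """Simulation-derived quantile bounds per (statistic, class, SNP count).

    ``table`` columns: statistic, relationship_class, n_snps, lower, upper,
    n_samples.  Related classes carry two-sided 95% bounds (0.025/0.975
    quantiles); the unrelated class has lower bound 0 and upper the 0.95
    quantile (single tail, zero as the natural lower edge).
    """

    table: pd.DataFrame

    def lookup(self, statistic: str, rel_class: str, n_snps: int) -> tuple[float, float]:
        sub = self.table[(self.table["statistic"] == statistic)
                         & (self.table["relationship_class"] == rel_class)]
        if sub.empty:
            raise KeyError(f"no range for ({statistic}, {rel_class})")
        # conservative: the nearest tabulated SNP count not exceeding n_snps
        le = sub[sub["n_snps"] <= n_snps]
        row = (le.loc[le["n_snps"].idxmax()] if not le.empty
               else sub.loc[sub["n_snps"].idxmin()])
        return float(row["lower"]), float(row["upper"])

    def classes(self, statistic: str) -> list[str]:
        sub = self.table[self.table["statistic"] == statistic]
        return list(pd.unique(sub["relationship_class"]))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "RangeTable":
        return cls(pd.read_csv(path, sep="\t",
                               dtype={"relationship_class": str, "statistic": str}))


def build_range_table(estimates: Mapping[str, Mapping[str, Sequence[float]]],
                      n_snps: int, min_samples: int = 20,
                      quantiles: tuple[float, float] = (0.025, 0.975)) -> RangeTable:
    """Build a RangeTable from per-class simulated estimates.

    ``estimates[statistic][relationship_class]`` is a sample of estimates at
    ``n_snps`` SNPs.  The unrelated class uses [0, q0.95].
    """
    rows = []
    for statistic, per_class in estimates.items():
        for rel_class, sample in per_class.items():
            sample = np.asarray(sample, dtype=float)
            if sample.size == 0:
                raise PedigreeError(f"empty estimate class {rel_class}")
            if sample.size < min_samples:
                raise PedigreeError(
                    f"class {rel_class}: {sample.size} < {min_samples} estimates")
            if rel_class == "unrelated":
                lower, upper = 0.0, float(np.quantile(sample, 0.95))
            else:
                lower = float(np.quantile(sample, quantiles[0]))
                upper = float(np.quantile(sample, quantiles[1]))
            rows.append({"statistic": statistic, "relationship_class": rel_class,
                         "n_snps": n_snps, "lower": lower, "upper": upper,
                         "n_samples": sample.size})
    return RangeTable(pd.DataFrame(rows))


def merge_range_tables(tables: Iterable[RangeTable]) -> RangeTable:
    return RangeTable(pd.concat([t.table for t in tables], ignore_index=True))


@dataclass
class RatioMoments:
    """Moments of the autosomal/X kinship-coefficient ratio per class."""

    mean: float
    variance: float
    mu_theta_a: float
    mu_inv_theta_x: float
    mu_theta_a_sq: float
    mu_inv_theta_x_sq: float
    n_excluded: int = 0


def ratio_moments(theta_a_samples: Sequence[float], theta_x_samples: Sequence[float],
                  theta_x_floor: float = 1e-3) -> RatioMoments:
    """Mean and variance of theta_auto / theta_X treating the two simulated
    samples as independent:

        mu(a/x)  = mu(a) * mu(1/x)
        var(a/x) = mu(a^2) * mu(1/x^2) - [mu(a) * mu(1/x)]^2

    X samples below ``theta_x_floor`` are excluded (1/x undefined at 0) and
    the exclusion count is reported.
    """
    a = np.asarray(theta_a_samples, dtype=float)
    x = np.asarray(theta_x_samples, dtype=float)
    keep = x >= theta_x_floor
    n_excluded = int((~keep).sum())
    x = x[keep]
    if x.size == 0:
        raise PedigreeError("all theta_X samples below the floor")
    inv = 1.0 / x
    mu_a = float(np.mean(a))
    mu_inv = float(np.mean(inv))
    mu_a2 = float(np.mean(a ** 2))
    mu_inv2 = float(np.mean(inv ** 2))
    mean = mu_a * mu_inv
    variance = mu_a2 * mu_inv2 - mean ** 2
    return RatioMoments(mean=mean, variance=variance, mu_theta_a=mu_a,
                        mu_inv_theta_x=mu_inv, mu_theta_a_sq=mu_a2,
                        mu_inv_theta_x_sq=mu_inv2, n_excluded=n_excluded)
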