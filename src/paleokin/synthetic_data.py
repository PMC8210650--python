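"""Synthetic cohorts with known ground truth.

Generates every input the pipeline consumes: a SNP panel with background
allele frequencies, pedigree-structured phased genotypes, ancient-DNA-like
degradation (coverage-dependent missingness, pseudo-haploidization, allele
flip errors), maternal-line mtDNA sequences, burial layouts with optional
kin clustering, and radiocarbon measurements drawn around a calibration
curve.  Every generator is a pure function of (config, seed), and a full
dataset ships its truth tables (relationship per pair, building
assignments, true dates) so recovery can be tested end to end.

Founder haplotypes are drawn independently from the panel frequencies
rather than copied from a reference panel: there is no background linkage
disequilibrium, which is acceptable for single-SNP-likelihood estimators
but means LD-aware methods cannot be benchmarked on these data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import (MISSING, GenotypeMatrix, IndividualMeta,
                          RadiocarbonSample, SnpPanel)
from .pedigree_sim import Pedigree, drop_pedigree, three_generation_pedigree
from .radiocarbon import CalibrationCurve


class SyntheticDataError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the real analysis setting: an autosomal transversion
    panel at the minimum pair-overlap size (5,000 SNPs), an X panel at its
    800-SNP threshold, a MAF floor of 0.10 matching the X-panel filter, a
    per-allele error of 0.005, and per-individual retention spanning the
    coverage spread of low- to medium-coverage ancient genomes.
    """

    n_snps_auto: int = 5_000
    n_snps_x: int = 800
    maf_min: float = 0.10
    n_autosomes: int = 22
    autosome_length_bp: int = 130_000_000
    autosome_length_cM: float = 140.0
    x_length_bp: int = 155_000_000
    x_length_cM: float = 180.0
    pedigree_children: int = 3
    pedigree_grandchildren: int = 2
    retention: float | Mapping[str, float] = 1.0
    error_rate: float = 0.005
    mtdna_length: int = 1_000
    mtdna_error: float = 0.002
    mtdna_founder_divergence: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_min <= 0.5):
            raise SyntheticDataError("maf_min must lie in (0, 0.5]")
        probs = ([self.retention] if isinstance(self.retention, float)
                 else list(self.retention.values()))
        for p in [*probs, self.error_rate, self.mtdna_error]:
            if not (0.0 <= p <= 1.0):
                raise SyntheticDataError(f"probability {p} outside [0, 1]")


def generate_panel(config: SimConfig, seed: int | None = None) -> SnpPanel:
    """SNP panel with frequencies uniform on [maf_min, 1 - maf_min].

    Positions are uniform then sorted within chromosomes; genetic positions
    are proportional to bp.  Alleles are drawn among transversion pairs so
    the panel survives the transversion filter unchanged.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if config.n_snps_auto < 1:
        raise SyntheticDataError("n_snps_auto must be >= 1")
    rows = []
    transversion_pairs = [("A", "C"), ("C", "A"), ("G", "T"), ("T", "G")]
    per_chrom = np.array_split(np.arange(config.n_snps_auto), config.n_autosomes)
    for c, idx in enumerate(per_chrom, start=1):
        pos = np.sort(rng.choice(config.autosome_length_bp, size=len(idx),
                                 replace=False)) + 1
        for k, p in enumerate(pos):
            ref, alt = transversion_pairs[rng.integers(4)]
            rows.append({
                "snp_id": f"rs{c}_{k}", "chromosome": str(c), "position_bp": int(p),
                "genetic_pos_cM": p / config.autosome_length_bp * config.autosome_length_cM,
                "ref_allele": ref, "alt_allele": alt,
                "bg_freq": rng.uniform(config.maf_min, 1.0 - config.maf_min),
            })
    if config.n_snps_x:
        pos = np.sort(rng.choice(config.x_length_bp, size=config.n_snps_x,
                                 replace=False)) + 1
        for k, p in enumerate(pos):
            ref, alt = transversion_pairs[rng.integers(4)]
            rows.append({
                "snp_id": f"rsX_{k}", "chromosome": "X", "position_bp": int(p),
                "genetic_pos_cM": p / config.x_length_bp * config.x_length_cM,
                "ref_allele": ref, "alt_allele": alt,
                "bg_freq": rng.uniform(config.maf_min, 1.0 - config.maf_min),
            })
    return SnpPanel(pd.DataFrame(rows))


def simulate_founders(panel: SnpPanel, pedigree: Pedigree, seed: int):
    """Phased founder genomes: haplotype alleles ~ Bernoulli(bg_freq).

    Returns ``(auto, x)`` dicts keyed by founder id; autosomes are (2, n)
    arrays, X is (2, n_x) for females and (1, n_x) for males.  Hardy-
    Weinberg holds in expectation because haplotypes are independent.
    """
    rng = np.random.default_rng(seed)
    auto_mask = panel.autosomal_mask()
    f_auto = panel.bg_freq[auto_mask]
    f_x = panel.bg_freq[panel.x_mask()]
    auto: dict[str, np.ndarray] = {}
    x: dict[str, np.ndarray] = {}
    for fid in pedigree.founders:
        auto[fid] = (rng.random((2, f_auto.size)) < f_auto).astype(np.int8)
        n_hap = 2 if pedigree.members[fid].sex == "F" else 1
        x[fid] = (rng.random((n_hap, f_x.size)) < f_x).astype(np.int8)
    return auto, x


def diploid_matrix(pedigree: Pedigree, auto: Mapping[str, np.ndarray],
                   x: Mapping[str, np.ndarray] | None = None) -> GenotypeMatrix:
    """Collapse phased member genomes into an (unphased) diploid matrix.

    Male X entries are stored haploid (0/1).  Column order: autosomes then X,
    matching the panel layout of :func:`generate_panel`.
    """
    ids = sorted(auto)
    cols = []
    for i in ids:
        g = auto[i].sum(axis=0)
        if x is not None:
            gx = x[i].sum(axis=0) if x[i].shape[0] == 2 else x[i][0]
            g = np.concatenate([g, gx])
        cols.append(g)
    return GenotypeMatrix(ids, np.vstack(cols).astype(np.int8), ploidy_mode="diploid")


def degrade(gm: GenotypeMatrix, retention: float | Mapping[str, float],
            error_rate: float, seed: int) -> GenotypeMatrix:
    """Ancient-DNA-like degradation of a diploid matrix.

    Each call is observed with the individual's retention probability
    (emulating coverage-dependent SNP overlap), observed calls are
    pseudo-haploidized (one random allele), and the sampled allele flips
    with probability ``error_rate``.
    """
    if gm.ploidy_mode != "diploid":
        raise SyntheticDataError("degrade expects a diploid matrix")
    rng = np.random.default_rng(seed)
    calls = np.full_like(gm.calls, MISSING)
    for i, ind in enumerate(gm.individuals):
        keep_p = retention if isinstance(retention, float) else retention.get(ind, 1.0)
        row = gm.calls[i]
        seen = (rng.random(row.size) < keep_p) & (row != MISSING)
        hap = row.copy()
        het = seen & (row == 1)
        hap[row == 2] = 1
        hap[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
        if error_rate > 0:
            flip = seen & (rng.random(row.size) < error_rate)
            hap[flip] = 1 - hap[flip]
        calls[i, seen] = hap[seen]
    return GenotypeMatrix(list(gm.individuals), calls, ploidy_mode="pseudohaploid")


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def generate_mtdna(pedigree: Pedigree, length: int, error: float, seed: int,
                   founder_divergence: float = 0.01) -> dict[str, str]:
    """Observed mtDNA consensus sequence per individual.

    Maternal founders carry sequences diverged from a common root at the
    stated per-site rate; children copy the maternal sequence exactly; the
    observed sequence of every individual then receives independent
    per-site errors (so a mother-child pair mismatches at ~2*error).
    """
    rng = np.random.default_rng(seed)
    root = rng.integers(0, 4, size=length)
    true_seq: dict[str, np.ndarray] = {}
    for i in pedigree.topological_order():
        m = pedigree.members[i]
        if m.mother is not None:
            true_seq[i] = true_seq[m.mother]
        else:
            true_seq[i] = _mutate(root, founder_divergence, rng)
    return {i: _to_str(_mutate(s, error, rng)) for i, s in true_seq.items()}


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return seq.copy()
    out = seq.copy()
    hit = rng.random(seq.size) < rate
    # substitute with one of the three other bases uniformly
    out[hit] = (seq[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return out


def _to_str(seq: np.ndarray) -> str:
    return _BASES[seq].tobytes().decode()


def generate_burials(pedigree: Pedigree, n_buildings: int,
                     clustering_strength: float, seed: int,
                     site: str = "SYN", site_extent: float = 50.0,
                     jitter: float = 2.0) -> list[IndividualMeta]:
    """Assign individuals to buildings and burial coordinates.

    Buildings sit at random positions on a ``site_extent`` x ``site_extent``
    plane.  Each connected component of the first-degree-relative graph is
    anchored to one building; every individual stays with its component's
    building with probability ``clustering_strength`` and otherwise draws a
    building uniformly — so at strength 1 every first-degree pair is
    co-assigned and at strength 0 assignment is independent of kinship.
    Burial coordinates are the building centre plus Gaussian jitter.
    """
    if n_buildings < 1:
        raise SyntheticDataError("n_buildings must be >= 1")
    rng = np.random.default_rng(seed)
    centers = rng.uniform(0, site_extent, size=(n_buildings, 2))
    ids = sorted(pedigree.members)
    first_degree: dict[str, set[str]] = {i: set() for i in ids}
    for i in ids:
        m = pedigree.members[i]
        for p in (m.mother, m.father):
            if p is not None and p in first_degree:
                first_degree[i].add(p)
                first_degree[p].add(i)
        for j in ids:
            if j != i and pedigree.relationship_class(i, j) == "siblings":
                first_degree[i].add(j)
    component: dict[str, int] = {}
    for i in ids:
        if i in component:
            continue
        stack, comp = [i], len(set(component.values()))
        while stack:
            j = stack.pop()
            if j in component:
                continue
            component[j] = comp
            stack.extend(first_degree[j] - set(component))
    anchor = {c: int(rng.integers(n_buildings))
              for c in set(component.values())}
    assignment: dict[str, int] = {}
    for i in ids:
        if rng.random() < clustering_strength:
            assignment[i] = anchor[component[i]]
        else:
            assignment[i] = int(rng.integers(n_buildings))
    metas = []
    for i in ids:
        b = assignment[i]
        xy = centers[b] + rng.normal(0, jitter, size=2)
        sex = "XX" if pedigree.members[i].sex == "F" else "XY"
        metas.append(IndividualMeta(id=i, site=site, building=f"B{b + 1}",
                                    x=float(xy[0]), y=float(xy[1]), sex=sex))
    return metas


def generate_radiocarbon(true_dates_cal_bp: Mapping[str, float],
                         curve: CalibrationCurve, sigma: float,
                         seed: int) -> dict[str, RadiocarbonSample]:
    """Measured conventional ages: curve mean at the true date plus noise."""
    rng = np.random.default_rng(seed)
    out = {}
    for ind, date in true_dates_cal_bp.items():
        if not (curve.cal_bp.min() <= date <= curve.cal_bp.max()):
            raise SyntheticDataError(f"true date {date} outside curve support")
        age = curve.curve_age(date) + rng.normal(0.0, sigma) if sigma > 0 \
            else curve.curve_age(date)
        out[ind] = RadiocarbonSample(lab_id=f"SYN-{ind}", age_bp=float(age),
                                     sigma=max(sigma, 1e-9))
    return out


@dataclass
class SyntheticDataset:
    """A complete cohort plus its ground truth."""

    config: SimConfig
    panel: SnpPanel
    pedigree: Pedigree
    diploid: GenotypeMatrix
    observed: GenotypeMatrix
    mtdna: dict[str, str]
    metadata: list[IndividualMeta]
    truth_pairs: pd.DataFrame = field(repr=False)


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate a full synthetic cohort under one seed."""
    rng_seeds = np.random.SeedSequence(config.seed).spawn(6)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in rng_seeds]
    panel = generate_panel(config, seed=seeds[0])
    pedigree = three_generation_pedigree(config.pedigree_children,
                                         config.pedigree_grandchildren)
    auto_f, x_f = simulate_founders(panel, pedigree, seeds[1])
    rng = np.random.default_rng(seeds[2])
    auto, x = drop_pedigree(pedigree, auto_f, x_f, panel, rng)
    diploid = diploid_matrix(pedigree, auto, x)
    observed = degrade(diploid, config.retention, config.error_rate, seeds[3])
    mtdna = generate_mtdna(pedigree, config.mtdna_length, config.mtdna_error,
                           seeds[4], config.mtdna_founder_divergence)
    metadata = generate_burials(pedigree, n_buildings=3, clustering_strength=0.8,
                                seed=seeds[5])
    for m in metadata:
        m.mtdna_sequence = mtdna[m.id]
    ids = sorted(pedigree.members)
    rows = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            rows.append({"id_a": a, "id_b": b,
                         "relationship": pedigree.relationship_class(a, b),
                         "kinship": pedigree.kinship(a, b),
                         "x_kinship": pedigree.x_kinship(a, b)})
    return SyntheticDataset(config=config, panel=panel, pedigree=pedigree,
                            diploid=diploid, observed=observed, mtdna=mtdna,
                            metadata=metadata, truth_pairs=pd.DataFrame(rows))
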