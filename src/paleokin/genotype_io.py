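"""Genotype containers and I/O for sparse ancient-DNA SNP data.

The central objects are :class:`SnpPanel` (SNP metadata plus background
allele frequencies), :class:`GenotypeMatrix` (individuals x SNPs calls with
explicit missingness) and :class:`IndividualMeta` (per-sample archaeological
and molecular metadata).  Genotype-cleaning rules standard in ancient-DNA
work are provided as pure functions: pseudo-haploidization, transversion
filtering, post-mortem damage masking, and X-panel preparation (PAR removal
and a minor-allele-frequency floor).

Conventions: SNP positions are 1-based inclusive; pseudo-autosomal-region
(PAR) intervals are half-open ``[start, end)`` in bp.  Missing calls are the
explicit sentinel ``MISSING`` (-1) internally, ``9`` in EIGENSTRAT files and
``./.`` in VCF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING: int = -1

#: unordered allele pairs that are transitions (purine<->purine etc.)
_TRANSITIONS = {frozenset({"C", "T"}), frozenset({"A", "G"})}
#: unordered allele pairs that cannot be strand-resolved when merging panels
_STRAND_AMBIGUOUS = {frozenset({"A", "T"}), frozenset({"C", "G"})}

AUTOSOMES = tuple(str(c) for c in range(1, 23))


class GenotypeIOError(ValueError):
    """Raised for malformed genotype files or inconsistent dimensions."""


@dataclass(frozen=True)
class SnpPanel:
    """SNP metadata table.

    ``table`` columns: ``snp_id``, ``chromosome`` (str, '1'..'22' or 'X'),
    ``position_bp`` (1-based int), ``genetic_pos_cM`` (float),
    ``ref_allele``, ``alt_allele`` (single bases), ``bg_freq`` (alt-allele
    frequency in the background panel, NaN when unknown).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {
            "snp_id", "chromosome", "position_bp", "genetic_pos_cM",
            "ref_allele", "alt_allele", "bg_freq",
        }
        missing_cols = required - set(self.table.columns)
        if missing_cols:
            raise GenotypeIOError(f"SnpPanel table lacks columns {sorted(missing_cols)}")
        for chrom, sub in self.table.groupby("chromosome", sort=False):
            pos = sub["position_bp"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise GenotypeIOError(f"positions not strictly increasing on chromosome {chrom}")
        same = self.table["ref_allele"] == self.table["alt_allele"]
        if same.any():
            raise GenotypeIOError("ref and alt alleles must differ")

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> np.ndarray:
        return self.table["chromosome"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.table["position_bp"].to_numpy()

    @property
    def bg_freq(self) -> np.ndarray:
        return self.table["bg_freq"].to_numpy(dtype=float)

    def autosomal_mask(self) -> np.ndarray:
        return np.isin(self.chromosomes, AUTOSOMES)

    def x_mask(self) -> np.ndarray:
        return self.chromosomes == "X"

    def subset(self, mask: np.ndarray) -> "SnpPanel":
        return SnpPanel(self.table.loc[np.asarray(mask)].reset_index(drop=True))


@dataclass
class GenotypeMatrix:
    """Calls for ``individuals`` (rows) at the SNPs of an associated panel.

    ``calls`` is an int8 array; diploid autosomal entries are 0/1/2 counts of
    the alt allele, pseudo-haploid (and male X) entries are 0/1, missing is
    ``MISSING``.  ``ploidy_mode`` is 'diploid' or 'pseudohaploid' for the
    matrix as a whole; male X entries are haploid in either mode.
    """

    individuals: list[str]
    calls: np.ndarray
    ploidy_mode: str = "diploid"

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2 or self.calls.shape[0] != len(self.individuals):
            raise GenotypeIOError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.individuals)} individuals"
            )
        if self.ploidy_mode not in ("diploid", "pseudohaploid"):
            raise GenotypeIOError(f"unknown ploidy_mode {self.ploidy_mode!r}")
        if self.ploidy_mode == "pseudohaploid" and np.any(self.calls == 2):
            raise GenotypeIOError("pseudo-haploid matrix contains a '2' call")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def row(self, individual: str) -> np.ndarray:
        return self.calls[self.individuals.index(individual)]

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.individuals), self.calls[:, np.asarray(mask)],
                              self.ploidy_mode)

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.individuals.index(i) for i in ids]
        return GenotypeMatrix(list(ids), self.calls[idx], self.ploidy_mode)


@dataclass
class RadiocarbonSample:
    lab_id: str
    age_bp: float
    sigma: float


@dataclass
class IndividualMeta:
    """Archaeological/molecular metadata for one individual."""

    id: str
    site: str = ""
    building: str | None = None
    x: float | None = None
    y: float | None = None
    sex: str = "unknown"            # 'XX', 'XY' or 'unknown'
    age_class: str = "unknown"      # neonate..old adult
    mtdna_sequence: str | None = None
    mtdna_haplogroup: str | None = None
    coverage: float | None = None
    radiocarbon: list[RadiocarbonSample] = field(default_factory=list)


# ---------------------------------------------------------------------------
# EIGENSTRAT I/O
# ---------------------------------------------------------------------------

def read_eigenstrat(geno_path, snp_path, ind_path):
    """Read an EIGENSTRAT .geno/.snp/.ind triplet.

    Returns ``(SnpPanel, GenotypeMatrix, list[IndividualMeta])``.  Genotype
    digits are 0/1/2 alt-allele counts with 9 for missing; the .geno file is
    one row per SNP, one column per individual.
    """
    inds: list[IndividualMeta] = []
    with open(ind_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            sex_code = parts[1] if len(parts) > 1 else "U"
            sex = {"M": "XY", "F": "XX"}.get(sex_code, "unknown")
            inds.append(IndividualMeta(id=parts[0], sex=sex,
                                       site=parts[2] if len(parts) > 2 else ""))

    rows = []
    with open(snp_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 6:
                raise GenotypeIOError(f".snp line has {len(parts)} fields: {line!r}")
            rows.append({
                "snp_id": parts[0],
                "chromosome": _norm_chrom(parts[1]),
                "genetic_pos_cM": float(parts[2]) * 100.0,  # .snp stores Morgans
                "position_bp": int(parts[3]),
                "ref_allele": parts[4],
                "alt_allele": parts[5],
                "bg_freq": np.nan,
            })
    panel = SnpPanel(pd.DataFrame(rows))

    geno = np.empty((panel.n_snps, len(inds)), dtype=np.int8)
    n_rows = 0
    with open(geno_path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            if i >= panel.n_snps:
                raise GenotypeIOError(".geno has more rows than .snp")
            if len(line) != len(inds):
                raise GenotypeIOError(
                    f".geno row {i + 1} has {len(line)} characters, expected {len(inds)}"
                )
            try:
                geno[i] = [int(c) for c in line]
            except ValueError as err:
                raise GenotypeIOError(f".geno row {i + 1}: non-digit genotype") from err
            n_rows += 1
    if n_rows != panel.n_snps:
        raise GenotypeIOError(".geno has fewer rows than .snp")

    calls = geno.T.copy()
    calls[calls == 9] = MISSING
    if np.any((calls > 2) | (calls < MISSING)):
        raise GenotypeIOError("genotype digit outside {0,1,2,9}")
    mode = "pseudohaploid" if not np.any(calls == 2) else "diploid"
    gm = GenotypeMatrix([m.id for m in inds], calls, ploidy_mode=mode)
    logger.info("read_eigenstrat: %d individuals x %d SNPs", gm.n_individuals, gm.n_snps)
    return panel, gm, inds


def write_eigenstrat(prefix, panel: SnpPanel, gm: GenotypeMatrix,
                     inds: Sequence[IndividualMeta] | None = None) -> None:
    prefix = str(prefix)
    calls = gm.calls.T.copy()
    calls[calls == MISSING] = 9
    with open(prefix + ".geno", "w") as fh:
        for row in calls:
            fh.write("".join(str(int(c)) for c in row) + "\n")
    with open(prefix + ".snp", "w") as fh:
        for r in panel.table.itertuples():
            fh.write(f"{r.snp_id}\t{r.chromosome}\t{r.genetic_pos_cM / 100.0:.8f}\t"
                     f"{r.position_bp}\t{r.ref_allele}\t{r.alt_allele}\n")
    sex_code = {"XY": "M", "XX": "F"}
    meta = {m.id: m for m in inds} if inds else {}
    with open(prefix + ".ind", "w") as fh:
        for ind_id in gm.individuals:
            m = meta.get(ind_id)
            code = sex_code.get(m.sex, "U") if m else "U"
            pop = (m.site or "POP") if m else "POP"
            fh.write(f"{ind_id}\t{code}\t{pop}\n")


def _norm_chrom(c: str) -> str:
    c = c.removeprefix("chr")
    return "X" if c in ("23", "X") else c


# ---------------------------------------------------------------------------
# minimal VCF (GT only)
# ---------------------------------------------------------------------------

def write_vcf(path, panel: SnpPanel, gm: GenotypeMatrix) -> None:
    """Write a minimal GT-only VCF; diploid 0/0,0/1,1/1, haploid 0,1, missing ./."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.individuals) + "\n")
        diploid = gm.ploidy_mode == "diploid"
        gt_map = ({0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."} if diploid
                  else {0: "0", 1: "1", MISSING: "."})
        for j, r in enumerate(panel.table.itertuples()):
            gts = "\t".join(gt_map[int(g)] for g in gm.calls[:, j])
            fh.write(f"{r.chromosome}\t{r.position_bp}\t{r.snp_id}\t{r.ref_allele}\t"
                     f"{r.alt_allele}\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path):
    """Read a minimal GT-only VCF into (SnpPanel, GenotypeMatrix).

    Uses cyvcf2 when available, otherwise a plain-text fallback sufficient
    for the dialect :func:`write_vcf` emits.
    """
    try:
        from cyvcf2 import VCF  # noqa: PLC0415
    except ImportError:
        return _read_vcf_text(path)

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    rows, cols = [], []
    for var in vcf:
        rows.append({
            "snp_id": var.ID or f"{var.CHROM}_{var.POS}",
            "chromosome": _norm_chrom(var.CHROM),
            "position_bp": var.POS,
            "genetic_pos_cM": 0.0,
            "ref_allele": var.REF,
            "alt_allele": var.ALT[0] if var.ALT else "N",
            "bg_freq": np.nan,
        })
        gts = var.genotypes  # [allele0, allele1, phased]
        col = np.full(len(individuals), MISSING, dtype=np.int8)
        for i, g in enumerate(gts):
            alleles = [a for a in g[:-1] if a >= 0]
            if alleles:
                col[i] = sum(alleles)
        cols.append(col)
    panel = SnpPanel(pd.DataFrame(rows))
    calls = np.column_stack(cols) if cols else np.empty((len(individuals), 0), np.int8)
    mode = "pseudohaploid" if not np.any(calls == 2) else "diploid"
    return panel, GenotypeMatrix(individuals, calls, ploidy_mode=mode)


def _read_vcf_text(path):
    individuals, rows, cols = [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                individuals = parts[9:]
                continue
            rows.append({
                "snp_id": parts[2], "chromosome": _norm_chrom(parts[0]),
                "position_bp": int(parts[1]), "genetic_pos_cM": 0.0,
                "ref_allele": parts[3], "alt_allele": parts[4], "bg_freq": np.nan,
            })
            col = np.full(len(individuals), MISSING, dtype=np.int8)
            for i, gt in enumerate(parts[9:]):
                alleles = [int(a) for a in gt.replace("|", "/").split("/") if a != "."]
                if alleles:
                    col[i] = sum(alleles)
            cols.append(col)
    panel = SnpPanel(pd.DataFrame(rows))
    calls = np.column_stack(cols) if cols else np.empty((len(individuals), 0), np.int8)
    mode = "pseudohaploid" if not np.any(calls == 2) else "diploid"
    return panel, GenotypeMatrix(individuals, calls, ploidy_mode=mode)


# ---------------------------------------------------------------------------
# metadata TSV
# ---------------------------------------------------------------------------

META_COLUMNS = ["id", "site", "building", "x", "y", "sex", "age_class",
                "mtdna_haplogroup", "coverage"]


def write_metadata(path, inds: Sequence[IndividualMeta]) -> None:
    rows = []
    for m in inds:
        rows.append({
            "id": m.id, "site": m.site, "building": m.building, "x": m.x, "y": m.y,
            "sex": m.sex, "age_class": m.age_class,
            "mtdna_haplogroup": m.mtdna_haplogroup, "coverage": m.coverage,
        })
    pd.DataFrame(rows, columns=META_COLUMNS).to_csv(path, sep="\t", index=False)


def read_metadata(path) -> list[IndividualMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "building": str})
    out = []
    for r in df.itertuples():
        out.append(IndividualMeta(
            id=r.id, site=r.site if isinstance(r.site, str) else "",
            building=r.building if isinstance(r.building, str) else None,
            x=None if pd.isna(r.x) else float(r.x),
            y=None if pd.isna(r.y) else float(r.y),
            sex=r.sex if isinstance(r.sex, str) else "unknown",
            age_class=r.age_class if isinstance(r.age_class, str) else "unknown",
            mtdna_haplogroup=(r.mtdna_haplogroup
                              if isinstance(r.mtdna_haplogroup, str) else None),
            coverage=None if pd.isna(r.coverage) else float(r.coverage),
        ))
    return out


# ---------------------------------------------------------------------------
# genotype-cleaning rules
# ---------------------------------------------------------------------------

def pseudo_haploidize(gm: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Collapse diploid calls to one randomly drawn allele per site.

    Homozygotes map deterministically (0->0, 2->1); heterozygotes map to 0 or
    1 with probability 1/2 each; missing stays missing.
    """
    if gm.ploidy_mode != "diploid":
        raise GenotypeIOError("input is already (pseudo-)haploid")
    rng = np.random.default_rng(seed)
    calls = gm.calls.copy()
    het = calls == 1
    calls[calls == 2] = 1
    calls[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
    return GenotypeMatrix(list(gm.individuals), calls, ploidy_mode="pseudohaploid")


def filter_transversions(panel: SnpPanel, gm: GenotypeMatrix | None = None):
    """Keep only transversion SNPs (drop C/T and A/G pairs).

    Post-mortem deamination makes transition sites unreliable in ancient
    data, so analyses run on transversions only.
    """
    pairs = [frozenset({r, a}) for r, a in
             zip(panel.table["ref_allele"], panel.table["alt_allele"])]
    keep = np.array([p not in _TRANSITIONS for p in pairs])
    if not keep.any():
        logger.warning("filter_transversions: no transversion SNPs remain")
    logger.info("filter_transversions: retained %d / %d SNPs", keep.sum(), len(keep))
    sub_panel = panel.subset(keep)
    if gm is None:
        return sub_panel, None
    return sub_panel, gm.subset_snps(keep)


def drop_strand_ambiguous(panel: SnpPanel, gm: GenotypeMatrix | None = None):
    """Drop A/T and C/G SNPs, which cannot be strand-matched across panels."""
    pairs = [frozenset({r, a}) for r, a in
             zip(panel.table["ref_allele"], panel.table["alt_allele"])]
    keep = np.array([p not in _STRAND_AMBIGUOUS for p in pairs])
    logger.info("drop_strand_ambiguous: retained %d / %d SNPs", keep.sum(), len(keep))
    sub_panel = panel.subset(keep)
    if gm is None:
        return sub_panel, None
    return sub_panel, gm.subset_snps(keep)


def mask_damage(gm: GenotypeMatrix, panel: SnpPanel) -> GenotypeMatrix:
    """Mask calls consistent with post-mortem deamination.

    An observed T at a reference-C site, or an observed A at a reference-G
    site, is coded missing; every other call is unchanged.  Only applies to
    pseudo-haploid matrices, where each call is a single observed allele.
    """
    if gm.ploidy_mode != "pseudohaploid":
        raise GenotypeIOError("damage masking is defined for pseudo-haploid calls")
    ref = panel.table["ref_allele"].to_numpy()
    alt = panel.table["alt_allele"].to_numpy()
    calls = gm.calls.copy()
    # the observed base is ref when call==0, alt when call==1; damage mimics
    # C->T and G->A only where the reference genome carries the C/G
    for damaged, ref_base in (("T", "C"), ("A", "G")):
        site = (ref == ref_base) & (alt == damaged)
        calls[:, site] = np.where(calls[:, site] == 1, MISSING, calls[:, site])
    return GenotypeMatrix(list(gm.individuals), calls, ploidy_mode="pseudohaploid")


def prepare_x_panel(panel: SnpPanel, par_regions: Iterable[tuple[int, int]],
                    maf_min: float = 0.10) -> SnpPanel:
    """Restrict an X panel: drop PAR SNPs, apply a MAF floor when known.

    ``par_regions`` are half-open [start, end) bp intervals.  SNPs with
    ``bg_freq`` present are kept only when min(f, 1-f) >= ``maf_min``
    (inclusive); SNPs with unknown frequency are kept.
    """
    par_regions = list(par_regions)
    is_x = panel.x_mask()
    if is_x.any() and par_regions is None:
        raise GenotypeIOError("X SNPs present but no PAR definition supplied")
    pos = panel.positions
    in_par = np.zeros(panel.n_snps, dtype=bool)
    for start, end in par_regions:
        in_par |= is_x & (pos >= start) & (pos < end)
    freq = panel.bg_freq
    with np.errstate(invalid="ignore"):
        maf = np.minimum(freq, 1.0 - freq)
    low_maf = is_x & ~np.isnan(freq) & (maf < maf_min - 1e-12)
    keep = ~(in_par | low_maf)
    logger.info("prepare_x_panel: dropped %d PAR SNPs, %d low-MAF SNPs",
                int((in_par & is_x).sum()), int(low_maf.sum()))
    return panel.subset(keep)
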