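"""End-to-end orchestration: simulate, calibrate, estimate, classify, report.

A run proceeds simulate -> calibrate ranges -> estimate kinship -> classify
relationships -> site statistics (co-burial contingency, spatial tests) ->
radiocarbon consistency, from a single seeded configuration; every numeric
output is reproducible from (config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import kinship_core, popgen_stats, relationship_classifier
from .genotype_io import IndividualMeta
from .kinship_core import (AUTOSOMAL_SNP_THRESHOLD, X_SNP_THRESHOLD,
                           classify_degree, ml_cotterman, pair_overlap)
from .pedigree_sim import (DEGREE_OF_CLASS, RangeTable, build_range_table,
                           drop_pedigree, merge_range_tables, ratio_moments,
                           three_generation_pedigree)
from .popgen_stats import FisherResult, fisher_exact
from .radiocarbon import ward_wilson
from .synthetic_data import (SimConfig, SyntheticDataset, degrade,
                             generate_dataset, generate_panel, simulate_founders)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0
    auto_snp_min: int = AUTOSOMAL_SNP_THRESHOLD
    x_snp_min: int = X_SNP_THRESHOLD
    eps: float = 0.005
    n_calibration_reps: int = 30
    n_perm: int = 9_999
    output_dir: str | None = None


# ---------------------------------------------------------------------------
# range calibration
# ---------------------------------------------------------------------------

_FIRST_DEGREE_X_LABELS = {
    ("parent-offspring", "F", "M"): None,   # direction ambiguous; resolved below
    ("siblings", "F", "F"): "sisters",
    ("siblings", "M", "M"): "brothers",
    ("siblings", "F", "M"): "brother-sister",
}


def calibrate_ranges(config: RunConfig, n_snps_auto: int | None = None,
                     pairs_per_class: int = 2) -> tuple[RangeTable, dict]:
    """Simulate pedigrees and build theta range tables at the working SNP count.

    Returns the merged range table (autosomal theta per relationship class;
    X theta per first-degree label) and the raw per-class estimate samples.
    """
    sim = config.sim
    n_auto = n_snps_auto or sim.n_snps_auto
    panel = generate_panel(sim, seed=config.seed)
    auto_mask = panel.autosomal_mask()
    ped = three_generation_pedigree(3, 2)
    by_class = ped.pairs_by_class()
    samples_auto: dict[str, list[float]] = {}
    samples_x: dict[str, list[float]] = {}
    rng = np.random.default_rng(config.seed + 1)
    for rep in range(config.n_calibration_reps):
        auto_f, x_f = simulate_founders(panel, ped, int(rng.integers(2 ** 31)))
        auto, x = drop_pedigree(ped, auto_f, x_f, panel,
                                np.random.default_rng(int(rng.integers(2 ** 31))))
        from .synthetic_data import diploid_matrix
        diploid = diploid_matrix(ped, auto, x)
        observed = degrade(diploid, 1.0, sim.error_rate, int(rng.integers(2 ** 31)))
        gm_auto = observed.subset_snps(auto_mask)
        panel_auto = panel.subset(auto_mask)
        gm_x = observed.subset_snps(panel.x_mask())
        panel_x = panel.subset(panel.x_mask())
        for rel_class, pairs in by_class.items():
            if rel_class == "identical":
                continue
            chosen = [pairs[int(rng.integers(len(pairs)))]
                      for _ in range(min(pairs_per_class, len(pairs)))]
            for pair in chosen:
                est = ml_cotterman(gm_auto, panel_auto, pair, eps=config.eps)
                samples_auto.setdefault(rel_class, []).append(est.theta_auto)
        for pair, label in _first_degree_x_pairs(ped):
            est = ml_cotterman(gm_x, panel_x, pair, eps=config.eps)
            samples_x.setdefault(label, []).append(est.theta_auto)
    tables = [build_range_table({"theta_auto": samples_auto}, n_snps=n_auto,
                                min_samples=10)]
    if samples_x:
        tables.append(build_range_table({"theta_x": samples_x},
                                        n_snps=sim.n_snps_x, min_samples=10))
    return merge_range_tables(tables), {"auto": samples_auto, "x": samples_x}


def _first_degree_x_pairs(ped) -> list[tuple[tuple[str, str], str]]:
    out = []
    ids = sorted(ped.members)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            rel = ped.relationship_class(a, b)
            if DEGREE_OF_CLASS.get(rel) != "1st":
                continue
            sa, sb = ped.members[a].sex, ped.members[b].sex
            if rel == "parent-offspring":
                parent, child = (a, b) if _is_parent(ped, a, b) else (b, a)
                label = {("F", "M"): "mother-son", ("F", "F"): "mother-daughter",
                         ("M", "M"): "father-son", ("M", "F"): "father-daughter"}[
                    (ped.members[parent].sex, ped.members[child].sex)]
            else:
                label = {("F", "F"): "sisters", ("M", "M"): "brothers"}.get(
                    tuple(sorted((sa, sb))), "brother-sister")
            out.append(((a, b), label))
    return out


def _is_parent(ped, a: str, b: str) -> bool:
    mb = ped.members[b]
    return a in (mb.mother, mb.father)


# ---------------------------------------------------------------------------
# co-burial contingency
# ---------------------------------------------------------------------------

def with_relative_counts(metadata: Sequence[IndividualMeta],
                         related_pairs: Sequence[tuple[str, str]]) -> dict[str, tuple[int, int]]:
    """Per site: (individuals with an identified co-buried close relative,
    individuals without), among co-buried individuals.

    An individual counts as 'with relative' when at least one other
    individual in its building cluster is 1st-3rd-degree related to it.
    Only individuals sharing a building with someone else are counted.
    """
    related: dict[str, set[str]] = {}
    for a, b in related_pairs:
        related.setdefault(a, set()).add(b)
        related.setdefault(b, set()).add(a)
    clusters: dict[tuple[str, str], list[str]] = {}
    for m in metadata:
        if m.building is not None:
            clusters.setdefault((m.site, m.building), []).append(m.id)
    counts: dict[str, list[int]] = {}
    for (site, _), members in clusters.items():
        if len(members) < 2:
            continue
        for ind in members:
            has_rel = bool(related.get(ind, set()) & (set(members) - {ind}))
            c = counts.setdefault(site, [0, 0])
            c[0 if has_rel else 1] += 1
    return {s: (c[0], c[1]) for s, c in counts.items()}


def coburial_contingency(counts: Mapping[str, tuple[int, int]],
                         group_a: Sequence[str],
                         group_b: Sequence[str]) -> FisherResult:
    """2x2 Fisher test of with/without-relative frequencies between two
    site groups (e.g. Aceramic vs Ceramic period sites)."""
    a_with = sum(counts[s][0] for s in group_a if s in counts)
    a_without = sum(counts[s][1] for s in group_a if s in counts)
    b_with = sum(counts[s][0] for s in group_b if s in counts)
    b_without = sum(counts[s][1] for s in group_b if s in counts)
    return fisher_exact([[a_with, a_without], [b_with, b_without]])


# ---------------------------------------------------------------------------
# the full run
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline on a synthetic cohort; returns the report
    bundle as a dict and (optionally) writes TSV outputs."""
    report: dict = {"config": asdict(config), "stages": []}
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def stage(name: str):
        report["stages"].append(name)
        logger.info("pipeline stage: %s", name)

    try:
        stage("simulate")
        sim = SimConfig(**{**asdict(config.sim), "seed": config.seed})
        data: SyntheticDataset = generate_dataset(sim)

        stage("ranges")
        ranges, _ = calibrate_ranges(config)

        stage("estimate")
        kin_rows = []
        panel_auto = data.panel.subset(data.panel.autosomal_mask())
        gm_auto = data.observed.subset_snps(data.panel.autosomal_mask())
        panel_x = data.panel.subset(data.panel.x_mask())
        gm_x = data.observed.subset_snps(data.panel.x_mask())
        ids = sorted(data.pedigree.members)
        estimates = {}
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                pair = (a, b)
                n_auto = pair_overlap(gm_auto, pair)
                n_x = pair_overlap(gm_x, pair)
                if n_auto < config.auto_snp_min:
                    kin_rows.append({"id_a": a, "id_b": b, "n_snps_auto": n_auto,
                                     "excluded": f"overlap {n_auto} < {config.auto_snp_min}"})
                    continue
                est = ml_cotterman(gm_auto, panel_auto, pair, eps=config.eps)
                theta_x = (ml_cotterman(gm_x, panel_x, pair, eps=config.eps).theta_auto
                           if n_x >= config.x_snp_min else None)
                call = classify_degree(est.theta_auto, n_auto, ranges)
                estimates[pair] = (est, theta_x, call)
                kin_rows.append({
                    "id_a": a, "id_b": b, "n_snps_auto": n_auto, "n_snps_x": n_x,
                    "theta_auto": est.theta_auto, "theta_x": theta_x,
                    "k0": est.k0, "k1": est.k1, "k2": est.k2,
                    "degree": call.degree, "flags": ";".join(call.flags),
                    "excluded": "",
                })
        kin_table = pd.DataFrame(kin_rows)

        stage("classify")
        meta_by_id = {m.id: m for m in data.metadata}
        call_rows = []
        for pair, (est, theta_x, deg) in estimates.items():
            if deg.degree not in ("1st", "2nd"):
                continue
            a, b = pair
            mism = relationship_classifier.mtdna_mismatch(
                data.mtdna[a], data.mtdna[b])
            ev = relationship_classifier.PairEvidence(
                pair=pair, degree=deg.degree, theta_auto=est.theta_auto,
                theta_x=theta_x,
                sexes=(meta_by_id[a].sex, meta_by_id[b].sex),
                mtdna_mismatch_rate=mism)
            ceiling = 2.0 * max(2.0 * sim.mtdna_error, 1.0 / sim.mtdna_length)
            call = relationship_classifier.score_candidates(
                ev, range_table=ranges, mtdna_mismatch_ceiling=ceiling)
            call_rows.append({"id_a": a, "id_b": b, "degree": deg.degree,
                              "winners": "/".join(call.winners),
                              "verdict": call.verdict})
        call_table = pd.DataFrame(call_rows)

        stage("sitestats")
        related_pairs = [pair for pair, (_, _, deg) in estimates.items()
                         if deg.degree in ("1st", "2nd", "3rd")]
        counts = with_relative_counts(data.metadata, related_pairs)
        sitestats: dict = {"with_relative_counts": counts}
        coverage = {m.id: (m.coverage if m.coverage is not None else 1.0)
                    for m in data.metadata}
        unrelated_ids = popgen_stats.relative_filter(ids, related_pairs, coverage)
        if len(unrelated_ids) >= 4:
            sub_meta = [meta_by_id[i] for i in unrelated_ids]
            spatial = popgen_stats.euclidean_distances(sub_meta)
            f3_vals = {}
            chroms = panel_auto.chromosomes
            pos = panel_auto.positions
            freqs = panel_auto.bg_freq
            for i, a in enumerate(unrelated_ids):
                for b in unrelated_ids[i + 1:]:
                    res = popgen_stats.outgroup_f3(
                        freqs, gm_auto.row(a), gm_auto.row(b), chroms, pos,
                        labels=("background", a, b))
                    f3_vals[(a, b)] = res.f3
            genetic = popgen_stats.genetic_distance_from_f3(unrelated_ids, f3_vals)
            r, p_mantel = popgen_stats.mantel_test(
                spatial, genetic, n_perm=config.n_perm, seed=config.seed)
            sitestats["mantel"] = {"r": r, "p": p_mantel}
            buildings = {m.id: m.building for m in sub_meta if m.building}
            if len(set(buildings.values())) >= 2:
                similarity = popgen_stats.DistanceMatrix(
                    genetic.ids, np.where(np.eye(len(genetic.ids), dtype=bool),
                                          0.0, 1.0 - genetic.values),
                    kind="genetic")
                try:
                    obs, p_wb = popgen_stats.within_building_test(
                        buildings, similarity, n_perm=config.n_perm,
                        seed=config.seed)
                    sitestats["within_building"] = {"observed": obs, "p": p_wb}
                except popgen_stats.PopgenError:
                    sitestats["within_building"] = None  # no within pairs left

        stage("c14")
        c14_rows = []
        for m in data.metadata:
            if len(m.radiocarbon) >= 2:
                ww = ward_wilson(m.radiocarbon)
                c14_rows.append({"id": m.id, "T": ww.t_statistic, "df": ww.df,
                                 "critical_5pct": ww.critical_5pct,
                                 "consistent": ww.consistent})
        c14_table = pd.DataFrame(c14_rows)

        report.update({
            "kinship_table": kin_table, "relationship_calls": call_table,
            "sitestats": sitestats, "c14": c14_table,
            "range_table": ranges.table, "n_individuals": len(ids),
        })
        if outdir:
            kin_table.to_csv(outdir / "kinship.tsv", sep="\t", index=False)
            call_table.to_csv(outdir / "relationships.tsv", sep="\t", index=False)
            ranges.to_tsv(outdir / "ranges.tsv")
            c14_table.to_csv(outdir / "c14.tsv", sep="\t", index=False)
            with open(outdir / "manifest.yaml", "w") as fh:
                yaml.safe_dump({"seed": config.seed, "stages": report["stages"],
                                "n_individuals": len(ids)}, fh)
        return report
    except Exception as err:
        failed = report["stages"][-1] if report["stages"] else "setup"
        raise RuntimeError(f"pipeline stage '{failed}' failed: {err}") from err
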