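"""Resolve a degree-of-relatedness call into ranked pedigree labels.

A first-degree call, say, is compatible with several pedigree labels
(mother-son, sisters, ...).  Each label carries an expected signature:
required sexes, whether the pair lies on one maternal line (mtDNA shared),
the expected autosomal and X kinship coefficients, and an age/death-order
requirement for parent-offspring direction.  Candidates of the called
degree are screened by these hard constraints and survivors are ranked by
the squared standardised distance of the observed (theta_auto,
theta_auto/theta_X) from simulation-derived class moments.

X-chromosome expectations follow from its transmission: fathers pass their
single X to daughters only, so father-son pairs share no X (theta_X = 0)
while mother-son and father-daughter pairs reach theta_X = 1/2 and full
sisters 3/8 — which is what makes the X informative for telling first-degree
configurations apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .pedigree_sim import RangeTable, RatioMoments

AGE_ORDER = ["neonate", "infant", "child", "adolescent", "young adult",
             "middle adult", "old adult"]
_ADULT_CLASSES = {"young adult", "middle adult", "old adult", "adult"}


@dataclass(frozen=True)
class LabelSignature:
    label: str
    degree: str
    sexes: frozenset[str] | None        # frozenset of 'XX'/'XY' multiset as sorted tuple
    sex_pair: tuple[str, str] | None    # ordered requirement, None = any order/sex
    mtdna_shared: bool                  # maternal line runs through the pair
    theta_auto: float
    theta_x: float | None               # None: depends on unknown configuration
    parent_first: bool = False          # parent born earlier / dies no later


#: expected signatures per pedigree label; X values from transmission rules
LABEL_SIGNATURES: dict[str, LabelSignature] = {
    "mother-son": LabelSignature("mother-son", "1st", None, ("XX", "XY"),
                                 True, 0.25, 0.5, parent_first=True),
    "mother-daughter": LabelSignature("mother-daughter", "1st", None, ("XX", "XX"),
                                      True, 0.25, 0.25, parent_first=True),
    "father-son": LabelSignature("father-son", "1st", None, ("XY", "XY"),
                                 False, 0.25, 0.0, parent_first=True),
    "father-daughter": LabelSignature("father-daughter", "1st", None, ("XY", "XX"),
                                      False, 0.25, 0.5, parent_first=True),
    "sisters": LabelSignature("sisters", "1st", None, ("XX", "XX"), True, 0.25, 0.375),
    "brothers": LabelSignature("brothers", "1st", None, ("XY", "XY"), True, 0.25, 0.5),
    "brother-sister": LabelSignature("brother-sister", "1st", None, ("XY", "XX"),
                                     True, 0.25, 0.25),
    "half-siblings": LabelSignature("half-siblings", "2nd", None, None,
                                    False, 0.125, None),
    "avuncular": LabelSignature("avuncular", "2nd", None, None, False, 0.125, None),
    "grandparent-grandchild": LabelSignature("grandparent-grandchild", "2nd",
                                             None, None, False, 0.125, None),
    "unrelated": LabelSignature("unrelated", "unrelated", None, None,
                                False, 0.0, 0.0),
}


def candidate_constraints(label: str) -> LabelSignature:
    """Expected evidence signature for a pedigree label."""
    try:
        return LABEL_SIGNATURES[label]
    except KeyError:
        raise KeyError(f"unknown relationship label {label!r}") from None


@dataclass
class PairEvidence:
    pair: tuple[str, str]
    degree: str
    theta_auto: float
    theta_x: float | None = None
    ci_auto: tuple[float, float] | None = None
    ci_x: tuple[float, float] | None = None
    sexes: tuple[str, str] = ("unknown", "unknown")
    age_classes: tuple[str, str] = ("unknown", "unknown")
    mtdna_mismatch_rate: float | None = None
    mtdna_haplogroups: tuple[str | None, str | None] = (None, None)
    mtdna_shared: bool | None = None
    death_order_prob: float | None = None   # P(first individual died first)


@dataclass
class RelationshipCall:
    pair: tuple[str, str]
    ranked: list[tuple[str, float]]
    winners: list[str]
    excluded: dict[str, list[str]] = field(default_factory=dict)
    verdict: str = "resolved"


def mtdna_mismatch(seq_a: str, seq_b: str, missing: str = "N-") -> float:
    """Pairwise mismatch rate over jointly called sites of two sequences."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    a = np.frombuffer(seq_a.upper().encode(), dtype="S1")
    b = np.frombuffer(seq_b.upper().encode(), dtype="S1")
    bad = np.zeros(a.size, dtype=bool)
    for ch in missing:
        c = ch.encode()
        bad |= (a == c) | (b == c)
    ok = ~bad
    if not ok.any():
        raise ValueError("no jointly called sites")
    return float(np.mean(a[ok] != b[ok]))


def mtdna_sharing(evidence: PairEvidence, mismatch_ceiling: float | None) -> bool | None:
    """Operational maternal-line sharing: identical haplogroup labels OR a
    mismatch rate below the ceiling.  Returns None when inconclusive."""
    if evidence.mtdna_shared is not None:
        return evidence.mtdna_shared
    hg_a, hg_b = evidence.mtdna_haplogroups
    if hg_a is not None and hg_b is not None and hg_a == hg_b:
        return True
    if evidence.mtdna_mismatch_rate is not None and mismatch_ceiling is not None:
        return evidence.mtdna_mismatch_rate <= mismatch_ceiling
    if hg_a is not None and hg_b is not None:
        return False
    return None


def score_candidates(evidence: PairEvidence,
                     range_table: RangeTable | None = None,
                     ratio_moments: Mapping[str, RatioMoments] | None = None,
                     theta_sd: Mapping[str, float] | None = None,
                     mtdna_mismatch_ceiling: float | None = None,
                     death_order_threshold: float = 0.9) -> RelationshipCall:
    """Screen and rank pedigree labels for one pair.

    Hard screens: label degree must match the call; sexes must match;
    maternal-line labels require mtDNA sharing when it is estimable;
    theta_X, when estimated, must fall inside the label's simulated interval;
    parent-offspring direction is imposed only when the death-order
    probability clears ``death_order_threshold`` (soft otherwise).  Survivors
    are ranked by squared standardised distance of the observed
    (theta_auto, theta_auto/theta_X) from the class expectations.
    """
    excluded: dict[str, list[str]] = {}
    scored: list[tuple[str, float]] = []
    shared = mtdna_sharing(evidence, mtdna_mismatch_ceiling)

    for label, sig in LABEL_SIGNATURES.items():
        if sig.degree != evidence.degree:
            continue
        reasons: list[str] = []
        if sig.sex_pair is not None and "unknown" not in evidence.sexes:
            want = tuple(sorted(sig.sex_pair))
            have = tuple(sorted(evidence.sexes))
            if want != have:
                reasons.append(f"sexes {evidence.sexes} incompatible with {sig.sex_pair}")
        if shared is not None:
            if sig.mtdna_shared and not shared:
                reasons.append("maternal line requires mtDNA sharing; pair differs")
            # sharing without a maternal path is uninformative in homogeneous
            # populations, so the converse is never disqualifying
        if sig.theta_x is not None and evidence.theta_x is not None:
            lo, hi = _x_interval(range_table, label, sig)
            if not (lo <= evidence.theta_x <= hi):
                reasons.append(
                    f"theta_X {evidence.theta_x:.3f} outside [{lo:.3f}, {hi:.3f}]")
        if sig.parent_first and not reasons:
            if not _valid_orientations(sig, evidence, death_order_threshold):
                reasons.append(
                    "no parent/child orientation consistent with sexes, "
                    "ages and death order")
        if reasons:
            excluded[label] = reasons
            continue
        score = _distance(evidence, sig, ratio_moments, theta_sd)
        # soft evidence enters the ranking, not the screens: observed mtDNA
        # sharing mildly favours maternal-line labels (sharing without a
        # maternal path stays possible in homogeneous populations), and a
        # confident death order favours the orientation whose parent died
        # first (a parent can outlive an offspring, so no exclusion)
        if shared is True and not sig.mtdna_shared:
            score += 0.5
        if sig.parent_first and evidence.death_order_prob is not None:
            orient = _valid_orientations(sig, evidence, death_order_threshold)
            p_parent_first = (evidence.death_order_prob if orient == [0]
                              else 1.0 - evidence.death_order_prob if orient == [1]
                              else None)
            if (p_parent_first is not None
                    and 1.0 - p_parent_first >= death_order_threshold):
                score += 0.75
        scored.append((label, score))

    scored.sort(key=lambda t: t[1])
    if not scored:
        return RelationshipCall(pair=evidence.pair, ranked=[], winners=[],
                                excluded=excluded, verdict="inconsistent evidence")
    best = scored[0][1]
    winners = [lbl for lbl, s in scored if s < best + 0.5]
    return RelationshipCall(pair=evidence.pair, ranked=scored, winners=winners,
                            excluded=excluded,
                            verdict="resolved" if len(winners) == 1 else "ambiguous")


def _x_interval(range_table: RangeTable | None, label: str,
                sig: LabelSignature) -> tuple[float, float]:
    # union of the simulated interval and a floor band around the pedigree
    # expectation: quantiles from small calibration samples run too narrow,
    # and theta_X at the 800-SNP threshold carries sampling noise of ~0.04
    lo_f, hi_f = max(0.0, sig.theta_x - 0.12), sig.theta_x + 0.12
    if range_table is None:
        return lo_f, hi_f
    try:
        lo, hi = range_table.lookup("theta_x", label, 800)
    except KeyError:
        return lo_f, hi_f
    return min(lo, lo_f), max(hi, hi_f)


def _valid_orientations(sig: LabelSignature, evidence: PairEvidence,
                        death_order_threshold: float) -> list[int]:
    """Pair-member indices that can play the parent for this label.

    An orientation is valid when the parent's sex matches the label, the
    parent is not a young subadult, and the parent reached adulthood if the
    child did.  When both orientations survive and the death order is
    confidently resolved (probability >= threshold), only the orientation
    whose parent died first is kept — a parent can outlive an offspring, so
    death order never vetoes the single remaining orientation.
    """
    parent_sex, child_sex = (sig.sex_pair if sig.sex_pair is not None
                             else (None, None))
    ages = evidence.age_classes
    sexes = evidence.sexes
    valid = []
    for pi in (0, 1):
        ci = 1 - pi
        if parent_sex is not None and "unknown" not in sexes:
            if sexes[pi] != parent_sex or sexes[ci] != child_sex:
                continue
        if ages[pi] in {"neonate", "infant", "child"}:
            continue
        p_adult = ages[pi] in _ADULT_CLASSES or ages[pi] == "unknown"
        c_adult = ages[ci] in _ADULT_CLASSES
        if c_adult and not p_adult:
            continue
        valid.append(pi)
    p = evidence.death_order_prob
    if len(valid) == 2 and p is not None:
        if p >= death_order_threshold:
            valid = [0]
        elif 1.0 - p >= death_order_threshold:
            valid = [1]
    return valid


def _distance(evidence: PairEvidence, sig: LabelSignature,
              moments: Mapping[str, RatioMoments] | None,
              theta_sd: Mapping[str, float] | None) -> float:
    sd_a = (theta_sd or {}).get(sig.label, 0.05)
    d = ((evidence.theta_auto - sig.theta_auto) / sd_a) ** 2
    if (evidence.theta_x is not None and evidence.theta_x > 1e-3
            and moments is not None and sig.label in moments):
        mom = moments[sig.label]
        if mom.variance > 0:
            ratio = evidence.theta_auto / evidence.theta_x
            d += (ratio - mom.mean) ** 2 / mom.variance
    elif evidence.theta_x is not None and sig.theta_x is not None:
        d += ((evidence.theta_x - sig.theta_x) / 0.1) ** 2
    return float(d)


def narrative(call: RelationshipCall) -> str:
    """Human-readable per-pair block mirroring a supplementary-table entry."""
    a, b = call.pair
    lines = [f"Pair {a}-{b}: {call.verdict}"]
    if call.winners:
        lines.append("  most likely: " + " / ".join(call.winners))
    for label, score in call.ranked:
        lines.append(f"  candidate {label}: score {score:.2f}")
    for label, reasons in call.excluded.items():
        for r in reasons:
            lines.append(f"  excluded {label}: {r}")
    return "\n".join(lines)
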