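"""Criterion combination: overlap exclusions, point totals, five-tier class.

Each assigned pathogenic criterion contributes +1/+2/+4/+8 points at
supporting/moderate/strong/very-strong strength; benign criteria subtract
the same magnitudes. The signed total maps onto five tiers:

    >= 10 pathogenic | 6..9 likely pathogenic | 0..5 VUS |
    -5..-1 likely benign | <= -6 benign

BA1 is standalone: when it fires the variant is benign outright; all
other criteria are still evaluated and reported but contribute no points.

Before summation, overlap exclusion rules drop the weaker member of any
assigned pair that would double-count the same evidence (e.g. PVS1 with
PP3). Ties on points keep the code in the earlier canonical strength
class (PVS < PS < PM < PP) so the outcome is deterministic and
order-independent.
"""
from __future__ import annotations

import csv
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Optional, Sequence, Union

from .models import (
    Classification,
    ClassificationResult,
    CriterionCall,
    EvidenceBundle,
    ExclusionRule,
    GeneConfig,
    State,
    Strength,
    code_class_rank,
)

#: Five-tier band edges of the point system (inclusive).
PATHOGENIC_MIN = 10
LIKELY_PATHOGENIC_MIN = 6
VUS_MIN = 0
LIKELY_BENIGN_MIN = -5


def load_exclusion_rules(path: Optional[Union[str, Path]] = None) -> list[ExclusionRule]:
    """Load overlap-exclusion pairs (shipped defaults when path is None)."""
    if path is None:
        res = importlib_resources.files("acmgrules.resources") / "exclusion_rules.tsv"
        fh = res.open(encoding="utf-8")
    else:
        fh = open(path, encoding="utf-8")
    rules = []
    with fh:
        for row in csv.DictReader((l for l in fh if not l.startswith("#")), delimiter="\t"):
            rules.append(ExclusionRule(
                code_a=row["code_a"].strip(),
                code_b=row["code_b"].strip(),
                rationale=(row.get("rationale") or "").strip(),
            ))
    seen = set()
    for r in rules:
        if r.pair in seen:
            raise ValueError(f"duplicate exclusion pair {sorted(r.pair)}")
        seen.add(r.pair)
    return rules


def apply_exclusion_rules(
    calls: Sequence[CriterionCall],
    rules: Sequence[ExclusionRule],
) -> tuple[list[CriterionCall], list[tuple[str, str, str]]]:
    """Drop the weaker member of each triggered exclusion pair.

    Returns the post-exclusion active (assigned) calls, in canonical
    order, and the drop ledger as (dropped_code, kept_code, rationale).
    The result is independent of input ordering.
    """
    assigned = {c.code: c for c in calls if c.state is State.ASSIGNED}
    dropped: list[tuple[str, str, str]] = []

    def sort_key(code: str):
        return (code_class_rank(code), code)

    for rule in sorted(rules, key=lambda r: tuple(sorted(r.pair))):
        a, b = rule.code_a, rule.code_b
        if a in assigned and b in assigned:
            ca, cb = assigned[a], assigned[b]
            if abs(ca.points) != abs(cb.points):
                loser = ca if abs(ca.points) < abs(cb.points) else cb
            else:
                # tie: keep the earlier canonical strength class
                loser = max((ca, cb), key=lambda c: sort_key(c.code))
            winner = cb if loser is ca else ca
            dropped.append((loser.code, winner.code,
                            rule.rationale or "overlap exclusion"))
            del assigned[loser.code]

    active = sorted(assigned.values(), key=lambda c: sort_key(c.code))
    return active, dropped


def total_points(active: Sequence[CriterionCall]) -> int:
    """Signed point sum over assigned calls."""
    for c in active:
        if c.state is not State.ASSIGNED:
            raise ValueError(f"{c.code}: only assigned calls carry points")
    return sum(c.points for c in active)


def classify_five_tier(points: int, ba1_standalone: bool = False) -> Classification:
    """Integer band lookup; BA1 short-circuits to benign."""
    if ba1_standalone:
        return Classification.BENIGN
    if points >= PATHOGENIC_MIN:
        return Classification.PATHOGENIC
    if points >= LIKELY_PATHOGENIC_MIN:
        return Classification.LIKELY_PATHOGENIC
    if points >= VUS_MIN:
        return Classification.VUS
    if points >= LIKELY_BENIGN_MIN:
        return Classification.LIKELY_BENIGN
    return Classification.BENIGN


def combine_calls(
    calls: Sequence[CriterionCall],
    rules: Sequence[ExclusionRule],
    variant_key: str = "",
) -> ClassificationResult:
    """Exclusions + point total + five-tier class for a list of calls."""
    all_calls = list(calls)
    warnings: list[str] = []
    for c in all_calls:
        warnings.extend(c.warnings)

    ba1 = next((c for c in all_calls
                if c.code == "BA1" and c.state is State.ASSIGNED), None)
    if ba1 is not None:
        # Standalone: other criteria remain reported but contribute nothing.
        active = [ba1]
        dropped: list[tuple[str, str, str]] = []
        pts = 0
        classification = classify_five_tier(pts, ba1_standalone=True)
        return ClassificationResult(
            calls=all_calls, active=active, dropped=dropped,
            total_points=pts, classification=classification,
            ba1_standalone=True, warnings=warnings, variant_key=variant_key,
        )

    active, dropped = apply_exclusion_rules(all_calls, rules)
    for code, kept, rationale in dropped:
        warnings.append(f"{code} dropped in favour of {kept}: {rationale}")
    pts = total_points(active)
    return ClassificationResult(
        calls=all_calls, active=active, dropped=dropped,
        total_points=pts, classification=classify_five_tier(pts),
        ba1_standalone=False, warnings=warnings, variant_key=variant_key,
    )


def combine(
    bundle: EvidenceBundle,
    cfg: GeneConfig,
    rules: Optional[Sequence[ExclusionRule]] = None,
    assay_table=None,
) -> ClassificationResult:
    """Run every criterion module on a bundle and combine the calls.

    Deterministic end-to-end: same bundle + config + rules => same result.
    Manual criteria merge like automated ones; a manual code colliding
    with an automated assignment overrides it with a logged warning.
    """
    # imported here to keep module dependencies acyclic
    from .codon_context import (
        evaluate_bp2,
        evaluate_functional,
        evaluate_pm1_pp2,
        evaluate_ps1_pm5,
        ingest_manual_criteria,
        load_assay_table,
    )
    from .lof_insilico import (
        evaluate_bp7,
        evaluate_pm4_bp3,
        evaluate_pp3_bp4,
        evaluate_pvs1,
    )
    from .population import evaluate_bs2, evaluate_population

    if rules is None:
        rules = load_exclusion_rules()
    if assay_table is None:
        assay_table = load_assay_table()

    calls: list[CriterionCall] = []
    calls.extend(evaluate_population(bundle, cfg))
    calls.append(evaluate_bs2(bundle, cfg))
    calls.append(evaluate_pvs1(bundle, cfg))
    pp3_bp4 = evaluate_pp3_bp4(bundle, cfg)
    calls.extend(pp3_bp4)
    bp4_call = next(c for c in pp3_bp4 if c.code == "BP4")
    bp4_splice = (
        bp4_call.state is State.ASSIGNED
        and bundle.predictions.spliceai_max() is not None
    )
    calls.append(evaluate_bp7(bundle, cfg, bp4_splice_assigned=bp4_splice))
    calls.extend(evaluate_pm4_bp3(bundle, cfg))
    calls.extend(evaluate_ps1_pm5(bundle, cfg))
    calls.extend(evaluate_functional(bundle, assay_table, cfg))
    calls.extend(evaluate_pm1_pp2(bundle, cfg))
    calls.append(evaluate_bp2(bundle, cfg))

    extra_warnings: list[str] = []
    manual_calls = ingest_manual_criteria(bundle.manual_criteria)
    by_code = {c.code: c for c in calls}
    for mc in manual_calls:
        if mc.code in by_code:
            prev = by_code[mc.code]
            if prev.state is State.ASSIGNED:
                extra_warnings.append(
                    f"manual {mc.code} ({mc.strength.value}) overrides the "
                    f"automated assignment ({prev.strength.value})"
                )
            calls[calls.index(prev)] = mc
            by_code[mc.code] = mc
        else:
            calls.append(mc)
            by_code[mc.code] = mc

    result = combine_calls(calls, rules, variant_key=bundle.descriptor.variant_key())
    result.warnings.extend(extra_warnings)
    return result
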