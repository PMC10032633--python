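"""Loss-of-function decision tree (PVS1) and in-silico criteria.

PVS1 strength assignment follows the ClinGen-style decision tree for
truncating, canonical-splice and start-loss variants:

* nonsense/frameshift: nonsense-mediated-decay (NMD) prediction by the
  50-nt junction rule decides between degradation (very strong when the
  truncation falls in the biologically relevant region) and the
  NMD-escape branch, where the fraction of protein lost (>10%) separates
  strong from moderate;
* canonical +-1/+-2 splice: a predicted splice-site *gain* has an
  uncertain transcript outcome, so the engine is conservative (supporting
  strength plus an RNA-assay warning); predicted exon skipping on the
  first or last exon gets a warning and no strength; otherwise the skip
  is propagated through the frame logic of the truncating branch;
* start-loss enters the moderate branch.

Gene modes refine the tree: the PTEN-style override forces very strong
for truncations 5' of a configured boundary, and the CDH1-style mode
consults a per-site strength table for canonical splice positions.

PP3/BP4 use REVEL (protein arm, missense only) and the maximum SpliceAI
delta (splice arm); BP7 additionally requires the nucleotide not to be
strongly conserved unless the gene's guideline dropped that condition.
"""
from __future__ import annotations

import csv
from importlib import resources as importlib_resources
from typing import Optional

from .models import (
    Consequence,
    CriterionCall,
    EvidenceBundle,
    GeneConfig,
    Pvs1Outcome,
    State,
    Strength,
    TranscriptModel,
    VariantDescriptor,
)

#: NMD escape zone: a premature stop within this many nt upstream of the
#: last exon-exon junction (or downstream of it) escapes degradation.
NMD_ESCAPE_WINDOW_NT = 50

#: Fraction of protein lost above which an NMD-escaping truncation is
#: treated as removing a substantial part of the protein.
PROTEIN_LOSS_FRACTION = 0.10

_TRUNCATING = (Consequence.NONSENSE, Consequence.FRAMESHIFT)
_PVS1_CONSEQUENCES = _TRUNCATING + (Consequence.STARTLOSS,)


def predict_nmd(d: VariantDescriptor, t: TranscriptModel) -> bool:
    """50-nt junction rule: the premature termination codon triggers NMD
    iff it lies more than 50 nt upstream of the last exon-exon junction of
    a multi-exon transcript. Single-exon transcripts never trigger NMD.
    """
    if d.intron_offset_start != 0 and d.intron_offset_end != 0:
        raise ValueError(
            "NMD prediction requires an exonic premature-termination position"
        )
    if t.single_exon:
        return False
    ptc = d.cdna_start
    return ptc < t.last_junction_cdna - NMD_ESCAPE_WINDOW_NT


def _load_site_table() -> dict[str, Strength]:
    """Per-site canonical-splice strengths (CDH1-style splicing table)."""
    table: dict[str, Strength] = {}
    path = importlib_resources.files("acmgrules.resources") / "cdh1_splice_sites.tsv"
    with path.open(encoding="utf-8") as fh:
        for row in csv.DictReader(
            (l for l in fh if not l.startswith("#")), delimiter="\t"
        ):
            table[row["site"].strip()] = Strength(row["strength"].strip())
    return table


_SITE_TABLE: Optional[dict[str, Strength]] = None


def site_strength_table() -> dict[str, Strength]:
    global _SITE_TABLE
    if _SITE_TABLE is None:
        _SITE_TABLE = _load_site_table()
    return _SITE_TABLE


def _fraction_lost(ptc_cdna: int, t: TranscriptModel) -> float:
    ptc_aa = max(1, (ptc_cdna + 2) // 3)
    return max(0.0, (t.protein_length - ptc_aa + 1) / t.protein_length)


def _in_relevant_region(cdna_pos: int, t: TranscriptModel) -> bool:
    return t.relevant_region_end is None or cdna_pos <= t.relevant_region_end


def _truncating_branch(
    ptc_cdna: int, d: VariantDescriptor, t: TranscriptModel, path: list[str]
) -> Strength:
    """Shared PTC logic for nonsense/frameshift and frame-disrupting skips."""
    probe = d.model_copy(update={
        "cdna_start": ptc_cdna, "intron_offset_start": 0, "intron_offset_end": 0,
    })
    if predict_nmd(probe, t):
        path.append("nmd:yes")
        if _in_relevant_region(ptc_cdna, t):
            path.append("region:relevant")
            return Strength.VERY_STRONG
        path.append("region:not_relevant")
        return Strength.STRONG
    path.append("nmd:no")
    if _fraction_lost(ptc_cdna, t) > PROTEIN_LOSS_FRACTION:
        path.append(f"protein_loss:>{PROTEIN_LOSS_FRACTION:.0%}")
        return Strength.STRONG
    path.append(f"protein_loss:<={PROTEIN_LOSS_FRACTION:.0%}")
    return Strength.MODERATE


def _splice_branch(
    bundle: EvidenceBundle, cfg: GeneConfig, path: list[str], warnings: list[str]
) -> Optional[Strength]:
    """Canonical +-1/+-2 branch; returns None for the warning-only outcome."""
    d, t = bundle.descriptor, bundle.transcript
    preds = bundle.predictions

    if cfg.pvs1_mode == "cdh1_site_specific":
        off = d.intron_offset_start or d.intron_offset_end
        key = f"{d.cdna_start}{off:+d}"
        table = site_strength_table()
        if key in table:
            path.append(f"site_table:{key}")
            return table[key]

    if preds.spliceai_max() is None:
        raise _MissingSplicePredictions()

    if preds.spliceai_max_is_gain():
        path.append("spliceai:gain")
        warnings.append(
            "splice-site gain predicted; RNA assay suggested before assigning "
            "a higher strength"
        )
        return Strength.SUPPORTING

    # predicted loss of the native site -> exon skipping of the flanking exon
    path.append("spliceai:loss")
    exon = t.exon_of_position(d.cdna_start)
    if exon is None:
        warnings.append("could not map the splice site to an exon; curator review needed")
        return None
    idx, first, last = exon
    path.append(f"exon:{idx}")
    if idx == 1 or idx == t.n_exons:
        warnings.append(
            f"predicted skipping of {'first' if idx == 1 else 'last'} exon "
            f"(exon {idx}); no PVS1 strength assigned, curator review needed"
        )
        return None
    exon_len = last - first + 1
    if exon_len % 3 == 0:
        path.append("skip:in_frame")
        if _fraction_lost(first, t) - _fraction_lost(last, t) > PROTEIN_LOSS_FRACTION \
                or (exon_len / 3) / t.protein_length > PROTEIN_LOSS_FRACTION:
            path.append(f"exon_fraction:>{PROTEIN_LOSS_FRACTION:.0%}")
            return Strength.STRONG
        path.append(f"exon_fraction:<={PROTEIN_LOSS_FRACTION:.0%}")
        return Strength.MODERATE
    path.append("skip:frameshift")
    return _truncating_branch(first, d, t, path)


class _MissingSplicePredictions(Exception):
    pass


def evaluate_pvs1(bundle: EvidenceBundle, cfg: GeneConfig) -> CriterionCall:
    """Walk the loss-of-function decision tree for one variant."""
    d, t = bundle.descriptor, bundle.transcript
    cons = bundle.consequence
    is_splice = bundle.flags.is_canonical_splice or (
        cons is Consequence.INTRONIC and d.is_canonical_splice_position
    )

    if cons not in _PVS1_CONSEQUENCES and not is_splice:
        return CriterionCall(
            "PVS1", State.NOT_APPLICABLE,
            explanation=f"consequence {cons.value} is not loss-of-function",
        )

    path: list[str] = []
    warnings: list[str] = []

    # PTEN-style override: truncations 5' of the boundary are very strong
    # regardless of the NMD branch.
    if (
        cfg.pvs1_mode == "pten_override"
        and cons in _TRUNCATING
        and cfg.pvs1_override_boundary is not None
        and d.cdna_start < cfg.pvs1_override_boundary
    ):
        path.append(f"override:<c.{cfg.pvs1_override_boundary}")
        return CriterionCall(
            "PVS1", State.ASSIGNED, Strength.VERY_STRONG,
            f"truncating variant 5' of c.{cfg.pvs1_override_boundary} "
            f"(gene-specific override); path: {' > '.join(path)}",
        )

    if cons in _TRUNCATING:
        path.append(cons.value)
        strength = _truncating_branch(d.cdna_start, d, t, path)
    elif is_splice:
        path.append("canonical_splice")
        try:
            strength = _splice_branch(bundle, cfg, path, warnings)
        except _MissingSplicePredictions:
            return CriterionCall(
                "PVS1", State.NOT_AUTOMATED,
                explanation="SpliceAI scores missing for a canonical splice variant",
            )
        if strength is None:
            return CriterionCall(
                "PVS1", State.WARNING, Strength.NONE,
                f"path: {' > '.join(path)}",
                warnings=warnings,
            )
    else:  # startloss
        path.append("startloss")
        strength = Strength.MODERATE

    return CriterionCall(
        "PVS1", State.ASSIGNED, strength,
        f"path: {' > '.join(path)}",
        warnings=warnings,
    )


def pvs1_outcome(call: CriterionCall) -> Pvs1Outcome:
    """Repackage a PVS1 call as a root-to-leaf tree walk record."""
    prefix = "path: "
    path = []
    for chunk in call.explanation.split(";"):
        chunk = chunk.strip()
        if chunk.startswith(prefix):
            path = chunk[len(prefix):].split(" > ")
    strength = call.strength if call.state is State.ASSIGNED else Strength.NONE
    return Pvs1Outcome(strength=strength, path=path, warnings=list(call.warnings))


# --------------------------------------------------------------------------
# PP3 / BP4
# --------------------------------------------------------------------------

def evaluate_pp3_bp4(bundle: EvidenceBundle, cfg: GeneConfig) -> list[CriterionCall]:
    """Computational prediction criteria.

    The splice arm compares the maximum SpliceAI delta with the gene's
    cut-offs (inclusive on both sides, with an indeterminate gap between
    them); the protein arm applies to missense variants only and uses
    REVEL. PP3 fires when any evaluable arm predicts impact; BP4 only
    when every evaluable arm supports benignity. For mismatch-repair
    genes the splice call requires SpliceAI and the dedicated splice
    prior to agree. Strength is conservatively kept at supporting.
    """
    preds = bundle.predictions
    s = preds.spliceai_max()
    is_missense = bundle.flags.is_missense or bundle.consequence is Consequence.MISSENSE
    revel = preds.revel if is_missense else None

    if s is None and revel is None:
        why = "no predictor scores available"
        return [
            CriterionCall("PP3", State.NOT_AUTOMATED, explanation=why),
            CriterionCall("BP4", State.NOT_AUTOMATED, explanation=why),
        ]

    arm_notes: list[str] = []
    pp3_fired = False
    bp4_votes: list[bool] = []

    if s is not None:
        if cfg.mmr_splice_combination:
            prior = preds.mmr_prior
            if s >= cfg.pp3_splice_min:
                if prior is None:
                    arm_notes.append(
                        f"SpliceAI {s:.2f} >= {cfg.pp3_splice_min:.2f} but the "
                        "mismatch-repair splice prior is missing; no splice call"
                    )
                elif prior >= cfg.mmr_prior_min:
                    pp3_fired = True
                    arm_notes.append(
                        f"SpliceAI {s:.2f} >= {cfg.pp3_splice_min:.2f} and "
                        f"splice prior {prior:.2f} >= {cfg.mmr_prior_min:.2f}"
                    )
                else:
                    arm_notes.append(
                        f"predictors disagree (SpliceAI {s:.2f} high, splice prior "
                        f"{prior:.2f} low); no splice call"
                    )
            elif s <= cfg.bp4_splice_max:
                if prior is not None and prior > cfg.mmr_prior_min:
                    arm_notes.append(
                        f"predictors disagree (SpliceAI {s:.2f} low, splice prior "
                        f"{prior:.2f} high); no splice call"
                    )
                else:
                    bp4_votes.append(True)
                    arm_notes.append(f"SpliceAI {s:.2f} <= {cfg.bp4_splice_max:.2f}")
            else:
                bp4_votes.append(False)
                arm_notes.append(f"SpliceAI {s:.2f} in the indeterminate gap")
        else:
            if s >= cfg.pp3_splice_min:
                pp3_fired = True
                arm_notes.append(f"SpliceAI max delta {s:.2f} >= {cfg.pp3_splice_min:.2f}")
            elif s <= cfg.bp4_splice_max:
                bp4_votes.append(True)
                arm_notes.append(f"SpliceAI max delta {s:.2f} <= {cfg.bp4_splice_max:.2f}")
            else:
                bp4_votes.append(False)
                arm_notes.append(f"SpliceAI max delta {s:.2f} in the indeterminate gap")

    if revel is not None:
        if revel >= cfg.pp3_protein_min:
            pp3_fired = True
            arm_notes.append(f"REVEL {revel:.2f} >= {cfg.pp3_protein_min:.2f}")
        elif revel <= cfg.bp4_protein_max:
            bp4_votes.append(True)
            arm_notes.append(f"REVEL {revel:.2f} <= {cfg.bp4_protein_max:.2f}")
        else:
            bp4_votes.append(False)
            arm_notes.append(f"REVEL {revel:.2f} in the indeterminate gap")

    note = "; ".join(arm_notes)
    if pp3_fired:
        return [
            CriterionCall("PP3", State.ASSIGNED, Strength.SUPPORTING, note),
            CriterionCall("BP4", State.DENIED, explanation=note),
        ]
    if bp4_votes and all(bp4_votes):
        return [
            CriterionCall("PP3", State.DENIED, explanation=note),
            CriterionCall("BP4", State.ASSIGNED, Strength.SUPPORTING, note),
        ]
    return [
        CriterionCall("PP3", State.DENIED, explanation=note),
        CriterionCall("BP4", State.DENIED, explanation=note),
    ]


def evaluate_bp7(bundle: EvidenceBundle, cfg: GeneConfig,
                 bp4_splice_assigned: bool) -> CriterionCall:
    """BP7: silent/deep-intronic variant with no predicted splice impact.

    Requires the BP4 splice arm to have fired; unless the gene's guideline
    dropped the condition, the nucleotide must additionally not be
    strongly conserved (phastCons below the configured maximum; a score of
    1 is treated as strongly conserved).
    """
    cons = bundle.consequence
    eligible = cons is Consequence.SYNONYMOUS or (
        cons is Consequence.INTRONIC
        and not bundle.descriptor.is_canonical_splice_position
    )
    if not eligible:
        return CriterionCall(
            "BP7", State.NOT_APPLICABLE,
            explanation=f"consequence {cons.value} is not synonymous/deep-intronic",
        )
    if not bp4_splice_assigned:
        return CriterionCall(
            "BP7", State.DENIED,
            explanation="BP4 (splice) not met; BP7 requires no predicted splice impact",
        )
    if cfg.bp7_requires_nonconserved:
        pc = bundle.predictions.phastcons
        if pc is None:
            return CriterionCall(
                "BP7", State.NOT_AUTOMATED,
                explanation="conservation check required but phastCons score missing",
            )
        if pc >= cfg.conservation_max_phastcons:
            return CriterionCall(
                "BP7", State.DENIED,
                explanation=(
                    f"nucleotide strongly conserved (phastCons {pc:.2f} >= "
                    f"{cfg.conservation_max_phastcons:.2f})"
                ),
            )
        return CriterionCall(
            "BP7", State.ASSIGNED, Strength.SUPPORTING,
            f"no predicted splice impact and phastCons {pc:.2f} < "
            f"{cfg.conservation_max_phastcons:.2f}",
        )
    return CriterionCall(
        "BP7", State.ASSIGNED, Strength.SUPPORTING,
        "no predicted splice impact (conservation condition not applied "
        f"for {cfg.gene_symbol})",
    )


def evaluate_pm4_bp3(bundle: EvidenceBundle, cfg: GeneConfig) -> list[CriterionCall]:
    """Protein-length-changing criteria.

    PM4: in-frame indel or stop-loss outside a repeat region; BP3:
    in-frame indel inside a repeat region. Mutually exclusive.
    """
    cons = bundle.consequence
    in_repeat = bundle.flags.in_repeat_region
    if cons is Consequence.INFRAME_INDEL:
        if in_repeat:
            return [
                CriterionCall("PM4", State.DENIED,
                              explanation="in-frame indel lies in a repeat region"),
                CriterionCall("BP3", State.ASSIGNED, Strength.SUPPORTING,
                              "in-frame indel in a repetitive region"),
            ]
        return [
            CriterionCall("PM4", State.ASSIGNED, Strength.MODERATE,
                          "protein-length change outside a repeat region"),
            CriterionCall("BP3", State.DENIED,
                          explanation="not in a repeat region"),
        ]
    if cons is Consequence.STOPLOSS:
        return [
            CriterionCall("PM4", State.ASSIGNED, Strength.MODERATE,
                          "stop-loss extends the protein"),
            CriterionCall("BP3", State.DENIED,
                          explanation="stop-loss is not an in-frame indel in a repeat"),
        ]
    return [
        CriterionCall("PM4", State.NOT_APPLICABLE,
                      explanation=f"consequence {cons.value} does not change protein length in-frame"),
        CriterionCall("BP3", State.NOT_APPLICABLE,
                      explanation=f"consequence {cons.value} is not an in-frame indel"),
    ]
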