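"""Codon-context criteria (PS1/PM5), curated functional assays (PS3/BS3),
gene applicability rules (PM1/PP2), allelic BP2 and manual-criteria intake.

PS1/PM5 compare the test variant against expert-panel-classified variants
at the same codon: PS1 for an identical amino-acid change reached through
a different nucleotide change, PM5 for a different substitution at the
same residue. The CDH1-style mode replaces the codon comparison with a
truncation rule: PM5 applies to nonsense/frameshift variants predicted or
proven to undergo nonsense-mediated decay, and to canonical splice
variants explicitly marked eligible.

PS3/BS3 are looked up in a curator-extensible assay table; absence of an
assay is never treated as evidence (the call stays not_automated).
"""
from __future__ import annotations

import csv
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Optional, Sequence, Union

from .lof_insilico import predict_nmd
from .models import (
    Consequence,
    CriterionCall,
    EvidenceBundle,
    FunctionalAssayRecord,
    GeneConfig,
    State,
    Strength,
)

#: Criteria that can only ever be supplied by a curator (segregation,
#: de-novo, allelic and phenotype evidence are not in public databases).
MANUAL_CODES = {"PP1", "BS4", "PS2", "PM6", "PP4", "BP5", "PM3", "PS4", "PS1",
                "PM5", "PS3", "BS3", "PM1", "PP2", "BP2", "PM4", "BP3", "BP7",
                "PP3", "BP4", "PM2", "BS1", "BS2", "BA1", "PVS1"}

#: Retired codes: classification by a reputable source without access to
#: the underlying evidence must not be used as a criterion.
RETIRED_CODES = {"PP5", "BP6"}


class ManualCriterionError(ValueError):
    """A supplied manual criterion is retired or unrecognized."""


# --------------------------------------------------------------------------
# PS1 / PM5
# --------------------------------------------------------------------------

def evaluate_ps1_pm5(bundle: EvidenceBundle, cfg: GeneConfig) -> list[CriterionCall]:
    if cfg.pm5_mode == "cdh1_truncating":
        return _ps1_pm5_truncating(bundle, cfg)
    if cfg.pm5_mode == "off":
        return [
            CriterionCall("PS1", State.NOT_APPLICABLE,
                          explanation=f"PS1 disabled for {cfg.gene_symbol}"),
            CriterionCall("PM5", State.NOT_APPLICABLE,
                          explanation=f"PM5 disabled for {cfg.gene_symbol}"),
        ]
    return _ps1_pm5_classic(bundle, cfg)


def _ps1_pm5_classic(bundle: EvidenceBundle, cfg: GeneConfig) -> list[CriterionCall]:
    ctx = bundle.codon_context
    if ctx is None:
        why = "no expert-panel codon context available"
        return [
            CriterionCall("PS1", State.NOT_AUTOMATED, explanation=why),
            CriterionCall("PM5", State.NOT_AUTOMATED, explanation=why),
        ]
    own = bundle.protein_change
    if own is None:
        why = "test variant has no protein change annotation"
        return [
            CriterionCall("PS1", State.NOT_AUTOMATED, explanation=why),
            CriterionCall("PM5", State.NOT_AUTOMATED, explanation=why),
        ]

    is_missense = (
        bundle.flags.is_missense or bundle.consequence is Consequence.MISSENSE
    )
    # Only expert-panel pathogenic entries are ever used.
    usable = [
        e for e in ctx.entries
        if e.expert_panel_reviewed and e.classification == "P"
        and e.protein_change is not None
    ]

    ps1_hit = None
    pm5_hit = None
    for entry in usable:
        ref, codon, alt = entry.protein_change
        if codon != own[1]:
            continue
        if (ref, alt) == (own[0], own[2]) and entry.cdna != bundle.descriptor.cdna:
            ps1_hit = entry
        elif alt != own[2]:
            pm5_hit = entry

    calls: list[CriterionCall] = []
    if cfg.ps1_enabled and ps1_hit is not None:
        calls.append(CriterionCall(
            "PS1", State.ASSIGNED, Strength.STRONG,
            f"expert-panel pathogenic variant {ps1_hit.cdna} causes the same "
            f"protein change {own[0]}{own[1]}{own[2]} via a different nucleotide change",
        ))
    elif not cfg.ps1_enabled:
        calls.append(CriterionCall(
            "PS1", State.NOT_APPLICABLE,
            explanation=f"PS1 no longer applies to {cfg.gene_symbol}",
        ))
    else:
        calls.append(CriterionCall(
            "PS1", State.DENIED,
            explanation="no expert-panel pathogenic variant with identical "
                        "protein change and different nucleotide change",
        ))

    ps1_assigned = calls[0].state is State.ASSIGNED
    if pm5_hit is not None and is_missense and not ps1_assigned:
        ref, codon, alt = pm5_hit.protein_change
        calls.append(CriterionCall(
            "PM5", State.ASSIGNED, Strength.MODERATE,
            f"expert-panel pathogenic variant {pm5_hit.cdna} changes the same "
            f"residue {ref}{codon} to {alt} (test variant: {own[2]})",
        ))
    elif ps1_assigned:
        calls.append(CriterionCall(
            "PM5", State.DENIED,
            explanation="PS1 already counts the codon-context evidence",
        ))
    elif not is_missense:
        calls.append(CriterionCall(
            "PM5", State.DENIED,
            explanation="classic PM5 applies to missense variants only",
        ))
    else:
        calls.append(CriterionCall(
            "PM5", State.DENIED,
            explanation="no expert-panel pathogenic variant at the same codon "
                        "with a different substitution",
        ))
    return calls


def _ps1_pm5_truncating(bundle: EvidenceBundle, cfg: GeneConfig) -> list[CriterionCall]:
    """CDH1-style rule: PM5 for truncations undergoing NMD; PS1 retired."""
    calls = [CriterionCall(
        "PS1", State.NOT_APPLICABLE,
        explanation=f"PS1 no longer applies to {cfg.gene_symbol}",
    )]
    cons = bundle.consequence
    if cons in (Consequence.NONSENSE, Consequence.FRAMESHIFT):
        proven = bundle.nmd_proven is True
        try:
            predicted = predict_nmd(bundle.descriptor, bundle.transcript)
        except ValueError:
            predicted = False
        if proven or predicted:
            how = "proven by RNA assay" if proven else "predicted (50-nt junction rule)"
            calls.append(CriterionCall(
                "PM5", State.ASSIGNED, Strength.MODERATE,
                f"{cons.value} variant with nonsense-mediated decay {how}",
            ))
        else:
            calls.append(CriterionCall(
                "PM5", State.DENIED,
                explanation="truncating variant predicted to escape nonsense-mediated decay",
            ))
    elif bundle.flags.is_canonical_splice and bundle.cdh1_pm5_splice_eligible:
        calls.append(CriterionCall(
            "PM5", State.ASSIGNED, Strength.MODERATE,
            "canonical splice variant marked eligible under the gene-specific rule",
        ))
    else:
        calls.append(CriterionCall(
            "PM5", State.DENIED,
            explanation="variant is neither an NMD-positive truncation nor an "
                        "eligible canonical splice variant",
        ))
    return calls


# --------------------------------------------------------------------------
# PS3 / BS3 functional assays
# --------------------------------------------------------------------------

def load_assay_table(path: Optional[Union[str, Path]] = None) -> list[FunctionalAssayRecord]:
    """Load the curated functional-assay table (shipped resource by default)."""
    if path is None:
        res = importlib_resources.files("acmgrules.resources") / "functional_assays.tsv"
        fh = res.open(encoding="utf-8")
    else:
        fh = open(path, encoding="utf-8")
    records = []
    with fh:
        for row in csv.DictReader((l for l in fh if not l.startswith("#")), delimiter="\t"):
            records.append(FunctionalAssayRecord(
                gene=row["gene"].strip(),
                variant_key=row["variant_key"].strip(),
                source_id=row["source_id"].strip(),
                result=row["result"].strip(),
                criterion=(row.get("criterion") or "").strip() or None,
                strength=Strength((row.get("strength") or "none").strip()),
                guideline_listed=(row.get("guideline_listed", "").strip().lower()
                                  in ("true", "1", "yes")),
            ))
    return records


def evaluate_functional(
    bundle: EvidenceBundle,
    assay_table: Sequence[FunctionalAssayRecord],
    cfg: GeneConfig,
) -> list[CriterionCall]:
    """PS3/BS3 by exact variant-key lookup in the curated assay table.

    Genes without calibrated assay literature stay not_automated, as does
    any variant with no matching record: absence of an assay is not
    evidence. Guideline-listed sources outrank others when strengths
    conflict; unresolvable conflicts suppress both calls with a warning.
    """
    gene = bundle.descriptor.gene_symbol
    if not cfg.ps3_bs3_covered:
        why = f"no calibrated functional-assay literature is used for {gene}"
        return [
            CriterionCall("PS3", State.NOT_AUTOMATED, explanation=why),
            CriterionCall("BS3", State.NOT_AUTOMATED, explanation=why),
        ]

    key = bundle.descriptor.variant_key()
    matches = [
        r for r in list(assay_table) + list(bundle.functional)
        if r.variant_key == key and r.criterion is not None
    ]
    if not matches:
        why = "no calibrated assay record for this variant"
        return [
            CriterionCall("PS3", State.NOT_AUTOMATED, explanation=why),
            CriterionCall("BS3", State.NOT_AUTOMATED, explanation=why),
        ]

    criteria = {r.criterion for r in matches}
    if criteria == {"PS3", "BS3"}:
        # guideline-listed sources take precedence
        listed = [r for r in matches if r.guideline_listed]
        listed_criteria = {r.criterion for r in listed}
        if len(listed_criteria) == 1:
            matches = listed
            criteria = listed_criteria
        else:
            warn = ("conflicting functional-assay records ("
                    + ", ".join(sorted(r.source_id for r in matches))
                    + "); both calls suppressed")
            return [
                CriterionCall("PS3", State.NOT_AUTOMATED, explanation=warn,
                              warnings=[warn]),
                CriterionCall("BS3", State.NOT_AUTOMATED, explanation=warn,
                              warnings=[warn]),
            ]

    chosen = matches[0]
    code = chosen.criterion
    if code == "BS3" and not cfg.bs3_covered:
        why = f"BS3 assay literature is not used for {gene}"
        return [
            CriterionCall("PS3", State.NOT_AUTOMATED,
                          explanation="no abnormal-result assay record"),
            CriterionCall("BS3", State.NOT_AUTOMATED, explanation=why),
        ]
    assigned = CriterionCall(
        code, State.ASSIGNED, chosen.strength,
        f"{chosen.result} result in calibrated assay ({chosen.source_id})",
    )
    other_code = "BS3" if code == "PS3" else "PS3"
    other = CriterionCall(
        other_code, State.DENIED,
        explanation=f"assay result is {chosen.result} ({chosen.source_id})",
    )
    pair = {c.code: c for c in (assigned, other)}
    return [pair["PS3"], pair["BS3"]]


# --------------------------------------------------------------------------
# PM1 / PP2 / BP2
# --------------------------------------------------------------------------

def evaluate_pm1_pp2(bundle: EvidenceBundle, cfg: GeneConfig) -> list[CriterionCall]:
    """Mutational-hotspot (PM1) and missense-constraint (PP2) criteria.

    PM1 is limited to missense and small in-frame indels inside a hotspot
    or well-characterized functional domain, and is inapplicable for
    genes whose guidelines exclude it. PP2 applies only where the gene's
    guideline enables it, and only to missense variants.
    """
    cons = bundle.consequence
    is_missense_like = cons in (Consequence.MISSENSE, Consequence.INFRAME_INDEL)

    calls: list[CriterionCall] = []
    if not cfg.pm1_applicable:
        calls.append(CriterionCall(
            "PM1", State.NOT_APPLICABLE,
            explanation=f"PM1 does not apply to {cfg.gene_symbol} guidelines",
        ))
    elif bundle.flags.in_pm1_region and is_missense_like:
        calls.append(CriterionCall(
            "PM1", State.ASSIGNED, Strength.MODERATE,
            "variant lies in a mutational hotspot / critical functional domain",
        ))
    elif bundle.flags.in_pm1_region:
        calls.append(CriterionCall(
            "PM1", State.DENIED,
            explanation=f"PM1 is restricted to missense and small in-frame "
                        f"indels; consequence is {cons.value}",
        ))
    else:
        calls.append(CriterionCall(
            "PM1", State.DENIED,
            explanation="variant is outside annotated hotspot/domain regions",
        ))

    if not cfg.pp2_enabled:
        calls.append(CriterionCall(
            "PP2", State.NOT_APPLICABLE,
            explanation=f"PP2 is not used for {cfg.gene_symbol}",
        ))
    elif cons is Consequence.MISSENSE:
        calls.append(CriterionCall(
            "PP2", State.ASSIGNED, Strength.SUPPORTING,
            "missense variant in a gene with low benign missense variation",
        ))
    else:
        calls.append(CriterionCall(
            "PP2", State.DENIED,
            explanation=f"PP2 applies to missense variants only; consequence is {cons.value}",
        ))
    return calls


def evaluate_bp2(bundle: EvidenceBundle, cfg: GeneConfig) -> CriterionCall:
    """BP2 from homozygote observations (gene-mode gated).

    Only supporting strength is ever assigned, and only where the gene
    mode allows it, because control-population homozygotes cannot be
    assumed healthy for adult-onset conditions.
    """
    if cfg.bp2_mode == "not_applicable":
        return CriterionCall(
            "BP2", State.NOT_APPLICABLE,
            explanation=f"BP2 does not apply to {cfg.gene_symbol} guidelines",
        )
    if cfg.bp2_mode == "homozygote_supporting":
        hom = bundle.homozygote_count_noncancer
        if hom is not None and hom >= 1:
            return CriterionCall(
                "BP2", State.ASSIGNED, Strength.SUPPORTING,
                f"variant observed in homozygosity ({hom} non-cancer homozygotes)",
            )
        return CriterionCall(
            "BP2", State.NOT_AUTOMATED,
            explanation="no homozygote observations; in-trans phase data are "
                        "not available in public databases",
        )
    return CriterionCall(
        "BP2", State.NOT_AUTOMATED,
        explanation="allelic data are seldom collected in public databases",
    )


# --------------------------------------------------------------------------
# manual criteria intake
# --------------------------------------------------------------------------

def ingest_manual_criteria(
    manual: Sequence[tuple[str, Strength]],
    registry: Optional[set[str]] = None,
) -> list[CriterionCall]:
    """Turn curator-supplied (code, strength) pairs into manual calls.

    Retired codes (PP5/BP6: reputable-source assertions without linked
    evidence) are rejected outright; unknown codes are rejected naming the
    offending token. Manual calls merge downstream exactly like automated
    ones.
    """
    recognized = registry if registry is not None else MANUAL_CODES
    calls = []
    for code, strength in manual:
        code = code.upper()
        if code in RETIRED_CODES:
            raise ManualCriterionError(
                f"{code} is retired: a reputable-source classification not "
                "linked to its supporting evidence must not be used"
            )
        if code not in recognized:
            raise ManualCriterionError(f"unrecognized criterion code {code!r}")
        strength = Strength(strength)
        calls.append(CriterionCall(
            code, State.ASSIGNED, strength,
            "supplied by curator", source="manual",
        ))
    return calls
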