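"""PS1/PM5 codon context, PS3/BS3 assays, PM1/PP2/BP2 applicability, manual intake."""
import pytest

from acmgrules.codon_context import (
    ManualCriterionError,
    evaluate_bp2,
    evaluate_functional,
    evaluate_pm1_pp2,
    evaluate_ps1_pm5,
    ingest_manual_criteria,
)
from acmgrules.evidence_io import config_for_gene
from acmgrules.fixtures import FIXTURE_TRANSCRIPTS
from acmgrules.hgvs import parse_cdna_description
from acmgrules.models import (
    BundleFlags,
    ClinVarContext,
    ClinVarEntry,
    Consequence,
    EvidenceBundle,
    FunctionalAssayRecord,
    State,
    Strength,
)

TP53_TX = FIXTURE_TRANSCRIPTS["TP53"]
CDH1_TX = FIXTURE_TRANSCRIPTS["CDH1"]


def _bundle(gene, cdna, cons, transcript, **kwargs):
    d = parse_cdna_description(cdna, gene_symbol=gene,
                               transcript_id=transcript.transcript_id)
    flags = BundleFlags(
        protein_consequence=cons,
        is_missense=cons is Consequence.MISSENSE,
        is_canonical_splice=d.is_canonical_splice_position,
        in_pm1_region=kwargs.pop("in_pm1_region", False),
    )
    return EvidenceBundle(descriptor=d, transcript=transcript, flags=flags, **kwargs)


def _entry(cdna, pc, classification="P", expert=True):
    return ClinVarEntry(cdna=cdna, protein_change=pc,
                        classification=classification,
                        expert_panel_reviewed=expert)


class TestPs1Pm5Classic:
    def _calls(self, configs, entries, cdna="c.817C>T", pc=("R", 273, "C"),
               cons=Consequence.MISSENSE):
        bundle = _bundle("TP53", cdna, cons, TP53_TX, protein_change=pc,
                         codon_context=ClinVarContext(entries=entries))
        return {c.code: c for c in evaluate_ps1_pm5(bundle, configs["TP53"])}

    def test_same_protein_change_different_nucleotide_is_ps1(self, configs):
        calls = self._calls(configs, [_entry("c.817C>A", ("R", 273, "C"))])
        assert calls["PS1"].state is State.ASSIGNED
        assert calls["PS1"].strength is Strength.STRONG
        assert calls["PM5"].state is State.DENIED

    def test_same_codon_different_substitution_is_pm5(self, configs):
        calls = self._calls(configs, [_entry("c.818G>A", ("R", 273, "H"))])
        assert calls["PM5"].state is State.ASSIGNED
        assert calls["PM5"].strength is Strength.MODERATE
        assert calls["PS1"].state is State.DENIED

    def test_ps1_and_pm5_never_coassigned(self, configs):
        calls = self._calls(configs, [
            _entry("c.817C>A", ("R", 273, "C")),
            _entry("c.818G>A", ("R", 273, "H")),
        ])
        assigned = [c for c in ("PS1", "PM5") if calls[c].state is State.ASSIGNED]
        assert assigned == ["PS1"]

    def test_non_expert_entries_ignored(self, configs):
        calls = self._calls(configs, [_entry("c.817C>A", ("R", 273, "C"),
                                             expert=False)])
        assert calls["PS1"].state is State.DENIED

    def test_likely_pathogenic_entries_ignored(self, configs):
        calls = self._calls(configs, [_entry("c.817C>A", ("R", 273, "C"),
                                             classification="LP")])
        assert calls["PS1"].state is State.DENIED

    def test_no_context_not_automated(self, configs):
        bundle = _bundle("TP53", "c.817C>T", Consequence.MISSENSE, TP53_TX,
                         protein_change=("R", 273, "C"))
        calls = {c.code: c for c in evaluate_ps1_pm5(bundle, configs["TP53"])}
        assert calls["PS1"].state is State.NOT_AUTOMATED
        assert calls["PM5"].state is State.NOT_AUTOMATED


class TestPm5Truncating:
    def test_nonsense_with_predicted_nmd_assigned(self, configs):
        bundle = _bundle("CDH1", "c.1003C>T", Consequence.NONSENSE, CDH1_TX)
        calls = {c.code: c for c in evaluate_ps1_pm5(bundle, configs["CDH1"])}
        assert calls["PM5"].state is State.ASSIGNED
        assert calls["PS1"].state is State.NOT_APPLICABLE

    def test_nmd_escape_denied_unless_proven(self, configs):
        # c.2620 is downstream of the 50-nt NMD boundary (junction 2300)
        bundle = _bundle("CDH1", "c.2620C>T", Consequence.NONSENSE, CDH1_TX)
        calls = {c.code: c for c in evaluate_ps1_pm5(bundle, configs["CDH1"])}
        assert calls["PM5"].state is State.DENIED
        proven = bundle.model_copy(update={"nmd_proven": True})
        calls = {c.code: c for c in evaluate_ps1_pm5(proven, configs["CDH1"])}
        assert calls["PM5"].state is State.ASSIGNED
        assert "proven" in calls["PM5"].explanation

    def test_eligible_canonical_splice_assigned(self, configs):
        bundle = _bundle("CDH1", "c.600+1G>A", Consequence.INTRONIC, CDH1_TX,
                         cdh1_pm5_splice_eligible=True)
        calls = {c.code: c for c in evaluate_ps1_pm5(bundle, configs["CDH1"])}
        assert calls["PM5"].state is State.ASSIGNED

    def test_uneligible_splice_denied(self, configs):
        bundle = _bundle("CDH1", "c.600+1G>A", Consequence.INTRONIC, CDH1_TX)
        calls = {c.code: c for c in evaluate_ps1_pm5(bundle, configs["CDH1"])}
        assert calls["PM5"].state is State.DENIED


def _assay(gene, key, source, result, criterion, strength, listed=True):
    return FunctionalAssayRecord(gene=gene, variant_key=key, source_id=source,
                                 result=result, criterion=criterion,
                                 strength=strength, guideline_listed=listed)


class TestFunctional:
    KEY = "TP53:NM_000546.6:c.892G>T"

    def test_abnormal_match_gives_ps3_with_source(self, configs):
        bundle = _bundle("TP53", "c.892G>T", Consequence.MISSENSE, TP53_TX)
        table = [_assay("TP53", self.KEY, "assayX", "abnormal", "PS3",
                        Strength.STRONG)]
        calls = {c.code: c for c in
                 evaluate_functional(bundle, table, configs["TP53"])}
        assert calls["PS3"].state is State.ASSIGNED
        assert calls["PS3"].strength is Strength.STRONG
        assert "assayX" in calls["PS3"].explanation
        assert calls["BS3"].state is State.DENIED

    def test_cdh1_and_pms2_not_automated(self, configs):
        for gene, tx in (("CDH1", CDH1_TX), ("PMS2", FIXTURE_TRANSCRIPTS["MLH1"])):
            bundle = _bundle(gene, "c.600G>A", Consequence.MISSENSE, tx)
            calls = {c.code: c for c in evaluate_functional(bundle, [],
                                                            configs[gene])}
            assert calls["PS3"].state is State.NOT_AUTOMATED
            assert calls["BS3"].state is State.NOT_AUTOMATED

    def test_pten_bs3_not_used(self, configs):
        bundle = _bundle("PTEN", "c.100A>G", Consequence.MISSENSE,
                         FIXTURE_TRANSCRIPTS["PTEN"])
        key = bundle.descriptor.variant_key()
        table = [_assay("PTEN", key, "assayY", "normal", "BS3", Strength.STRONG)]
        calls = {c.code: c for c in
                 evaluate_functional(bundle, table, configs["PTEN"])}
        assert calls["BS3"].state is State.NOT_AUTOMATED

    def test_no_match_is_not_automated_never_denied(self, configs):
        bundle = _bundle("TP53", "c.999G>A", Consequence.MISSENSE, TP53_TX)
        calls = {c.code: c for c in evaluate_functional(bundle, [],
                                                        configs["TP53"])}
        assert calls["PS3"].state is State.NOT_AUTOMATED
        assert calls["BS3"].state is State.NOT_AUTOMATED

    def test_conflicting_records_suppressed_with_warning(self, configs):
        bundle = _bundle("TP53", "c.892G>T", Consequence.MISSENSE, TP53_TX)
        table = [
            _assay("TP53", self.KEY, "assayA", "abnormal", "PS3", Strength.STRONG),
            _assay("TP53", self.KEY, "assayB", "normal", "BS3", Strength.STRONG),
        ]
        calls = {c.code: c for c in
                 evaluate_functional(bundle, table, configs["TP53"])}
        assert calls["PS3"].state is State.NOT_AUTOMATED
        assert calls["PS3"].warnings and "conflict" in calls["PS3"].warnings[0]

    def test_guideline_listed_source_outranks(self, configs):
        bundle = _bundle("TP53", "c.892G>T", Consequence.MISSENSE, TP53_TX)
        table = [
            _assay("TP53", self.KEY, "listed", "abnormal", "PS3",
                   Strength.STRONG, listed=True),
            _assay("TP53", self.KEY, "unlisted", "normal", "BS3",
                   Strength.STRONG, listed=False),
        ]
        calls = {c.code: c for c in
                 evaluate_functional(bundle, table, configs["TP53"])}
        assert calls["PS3"].state is State.ASSIGNED
        assert "listed" in calls["PS3"].explanation

    def test_lookup_is_pure(self, configs):
        bundle = _bundle("TP53", "c.892G>T", Consequence.MISSENSE, TP53_TX)
        table = [_assay("TP53", self.KEY, "assayX", "abnormal", "PS3",
                        Strength.STRONG)]
        first = evaluate_functional(bundle, table, configs["TP53"])
        second = evaluate_functional(bundle, table, configs["TP53"])
        assert first == second


class TestPm1Pp2Matrix:
    PM1_EXCLUDED = {"ATM", "CDH1", "MLH1", "MSH2", "MSH6", "PMS2"}

    @pytest.mark.parametrize("gene", ["ATM", "CDH1", "CHEK2", "MLH1", "MSH2",
                                      "MSH6", "PMS2", "PTEN", "TP53", "GENERAL"])
    def test_gene_matrix(self, configs, gene):
        cfg = config_for_gene(configs, gene)
        tx = FIXTURE_TRANSCRIPTS.get(gene, FIXTURE_TRANSCRIPTS["GENE1"])
        bundle = _bundle(gene, "c.100A>G", Consequence.MISSENSE, tx,
                         in_pm1_region=True)
        calls = {c.code: c for c in evaluate_pm1_pp2(bundle, cfg)}
        if gene in self.PM1_EXCLUDED:
            assert calls["PM1"].state is State.NOT_APPLICABLE
        else:
            assert calls["PM1"].state is State.ASSIGNED
        if gene == "PTEN":
            assert calls["PP2"].state is State.ASSIGNED
        else:
            assert calls["PP2"].state is State.NOT_APPLICABLE

    def test_pm1_restricted_to_missense_and_inframe(self, configs):
        bundle = _bundle("TP53", "c.100C>T", Consequence.NONSENSE, TP53_TX,
                         in_pm1_region=True)
        calls = {c.code: c for c in evaluate_pm1_pp2(bundle, configs["TP53"])}
        assert calls["PM1"].state is State.DENIED

    def test_pp2_requires_missense(self, configs):
        bundle = _bundle("PTEN", "c.100C>T", Consequence.NONSENSE,
                         FIXTURE_TRANSCRIPTS["PTEN"])
        calls = {c.code: c for c in evaluate_pm1_pp2(bundle, configs["PTEN"])}
        assert calls["PP2"].state is State.DENIED


class TestBp2:
    def test_mmr_not_applicable(self, configs):
        bundle = _bundle("MLH1", "c.100A>G", Consequence.MISSENSE,
                         FIXTURE_TRANSCRIPTS["MLH1"])
        assert evaluate_bp2(bundle, configs["MLH1"]).state is State.NOT_APPLICABLE

    def test_cdh1_homozygotes_give_supporting(self, configs):
        bundle = _bundle("CDH1", "c.2200G>A", Consequence.MISSENSE, CDH1_TX,
                         homozygote_count_noncancer=2)
        call = evaluate_bp2(bundle, configs["CDH1"])
        assert call.state is State.ASSIGNED
        assert call.strength is Strength.SUPPORTING

    def test_cdh1_without_homozygotes_not_automated(self, configs):
        bundle = _bundle("CDH1", "c.2200G>A", Consequence.MISSENSE, CDH1_TX,
                         homozygote_count_noncancer=0)
        assert evaluate_bp2(bundle, configs["CDH1"]).state is State.NOT_AUTOMATED

    def test_general_not_automated(self, configs):
        bundle = _bundle("GENE1", "c.100A>G", Consequence.MISSENSE,
                         FIXTURE_TRANSCRIPTS["GENE1"])
        cfg = config_for_gene(configs, "GENE1")
        assert evaluate_bp2(bundle, cfg).state is State.NOT_AUTOMATED


class TestManualIntake:
    def test_accepted_codes_become_manual_calls(self):
        calls = ingest_manual_criteria([("PP1", Strength.STRONG),
                                        ("PS4", Strength.MODERATE)])
        assert [(c.code, c.points, c.source) for c in calls] == [
            ("PP1", 4, "manual"), ("PS4", 2, "manual"),
        ]

    @pytest.mark.parametrize("code", ["PP5", "BP6"])
    def test_retired_codes_rejected(self, code):
        with pytest.raises(ManualCriterionError, match="retired"):
            ingest_manual_criteria([(code, Strength.SUPPORTING)])

    def test_unknown_code_rejected(self):
        with pytest.raises(ManualCriterionError, match="XX9"):
            ingest_manual_criteria([("XX9", Strength.SUPPORTING)])

    def test_manual_overrides_automated_with_warning(self, configs):
        from acmgrules.combiner import combine
        from acmgrules.fixtures import make_evidence_scenario, scenario_spec

        bundle = make_evidence_scenario(scenario_spec("rare_truncating"))
        bundle = bundle.model_copy(update={
            "manual_criteria": [("PM2", Strength.MODERATE)],
        })
        cfg = config_for_gene(configs, "GENE1")
        result = combine(bundle, cfg)
        pm2 = next(c for c in result.calls if c.code == "PM2")
        assert pm2.source == "manual" and pm2.strength is Strength.MODERATE
        assert any("overrides" in w for w in result.warnings)
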