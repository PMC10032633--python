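"""PVS1 decision tree, PP3/BP4 thresholds, BP7 conservation, PM4/BP3."""
import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acmgrules.fixtures import FIXTURE_TRANSCRIPTS, make_evidence_scenario, scenario_spec
from acmgrules.hgvs import parse_cdna_description
from acmgrules.lof_insilico import (
    NMD_ESCAPE_WINDOW_NT,
    evaluate_bp7,
    evaluate_pm4_bp3,
    evaluate_pp3_bp4,
    evaluate_pvs1,
    predict_nmd,
)
from acmgrules.models import (
    BundleFlags,
    Consequence,
    EvidenceBundle,
    PredictionSet,
    State,
    Strength,
)

GENE1 = FIXTURE_TRANSCRIPTS["GENE1"]  # junction at 720
PTEN_TX = FIXTURE_TRANSCRIPTS["PTEN"]


def _nonsense(pos, transcript=GENE1, gene="GENE1", **kwargs):
    d = parse_cdna_description(f"c.{pos}C>T", gene_symbol=gene,
                               transcript_id=transcript.transcript_id)
    return EvidenceBundle(
        descriptor=d, transcript=transcript,
        flags=BundleFlags(protein_consequence=Consequence.NONSENSE),
        **kwargs,
    )


def _splice(cdna, preds, transcript=GENE1, gene="GENE1"):
    d = parse_cdna_description(cdna, gene_symbol=gene,
                               transcript_id=transcript.transcript_id)
    return EvidenceBundle(
        descriptor=d, transcript=transcript, predictions=preds,
        flags=BundleFlags(protein_consequence=Consequence.INTRONIC,
                          is_canonical_splice=True),
    )


class TestNmd:
    def test_deep_upstream_triggers(self):
        d = parse_cdna_description("c.100C>T")
        assert predict_nmd(d, GENE1) is True

    def test_boundary_sweep_around_junction_minus_50(self):
        junction = GENE1.last_junction_cdna
        for pos in range(junction - 55, junction - 45):
            d = parse_cdna_description(f"c.{pos}C>T")
            assert predict_nmd(d, GENE1) == (pos < junction - NMD_ESCAPE_WINDOW_NT)

    def test_single_exon_never_triggers(self):
        from acmgrules.fixtures import make_transcript_fixture

        t = make_transcript_fixture(1, 300, seed=0)
        d = parse_cdna_description("c.10C>T")
        assert predict_nmd(d, t) is False

    def test_pure_intronic_position_is_domain_error(self):
        d = parse_cdna_description("c.100+5G>A")
        with pytest.raises(ValueError):
            predict_nmd(d, GENE1)


class TestPvs1Tree:
    def test_nmd_positive_in_relevant_region_is_very_strong(self, general_cfg):
        call = evaluate_pvs1(_nonsense(292), general_cfg)
        assert call.state is State.ASSIGNED
        assert call.strength is Strength.VERY_STRONG

    def test_nmd_positive_outside_relevant_region_reduced(self, configs):
        from acmgrules.evidence_io import config_for_gene

        cfg = config_for_gene(configs, "GENE3")
        bundle = _nonsense(500, transcript=FIXTURE_TRANSCRIPTS["GENE3"], gene="GENE3")
        call = evaluate_pvs1(bundle, cfg)
        assert call.strength is Strength.STRONG

    def test_nmd_escape_large_loss_strong_small_loss_moderate(self, general_cfg):
        assert evaluate_pvs1(_nonsense(680), general_cfg).strength is Strength.STRONG
        # late truncation on PTEN-like geometry loses <10% of the protein
        cfg = dataclasses.replace(general_cfg, pvs1_mode="general_tree")
        bundle = _nonsense(1180, transcript=PTEN_TX, gene="PTEN")
        assert evaluate_pvs1(bundle, cfg).strength is Strength.MODERATE

    def test_pten_override_boundary(self, configs):
        """Truncations 5' of c.1121 are forced to very strong; the general
        tree takes over at and beyond the boundary."""
        pten = configs["PTEN"]
        general = dataclasses.replace(pten, pvs1_mode="general_tree")
        for pos in (100, 500, 1003, 1120):
            bundle = _nonsense(pos, transcript=PTEN_TX, gene="PTEN")
            assert evaluate_pvs1(bundle, pten).strength is Strength.VERY_STRONG
        for pos in (1121, 1150, 1180):
            bundle = _nonsense(pos, transcript=PTEN_TX, gene="PTEN")
            assert evaluate_pvs1(bundle, pten).strength is \
                evaluate_pvs1(bundle, general).strength
            assert evaluate_pvs1(bundle, pten).strength is not Strength.VERY_STRONG

    def test_cdh1_site_specific_table(self, configs):
        bundle = _splice("c.1137+1delG", PredictionSet(spliceai_dl=0.95),
                         transcript=FIXTURE_TRANSCRIPTS["CDH1"], gene="CDH1")
        call = evaluate_pvs1(bundle, configs["CDH1"])
        assert call.state is State.ASSIGNED
        assert call.strength is Strength.STRONG

    def test_splice_gain_is_supporting_with_rna_warning(self, general_cfg):
        bundle = _splice("c.359+1G>A", PredictionSet(spliceai_dg=0.8))
        call = evaluate_pvs1(bundle, general_cfg)
        assert call.strength is Strength.SUPPORTING
        assert any("RNA" in w for w in call.warnings)

    @pytest.mark.parametrize("cdna", ["c.180+1G>T", "c.721-2A>G"])
    def test_terminal_exon_skip_warning_no_strength(self, general_cfg, cdna):
        bundle = _splice(cdna, PredictionSet(spliceai_dl=0.9))
        call = evaluate_pvs1(bundle, general_cfg)
        assert call.state is State.WARNING
        assert call.strength is Strength.NONE
        assert call.warnings

    def test_internal_exon_skip_frame_logic(self, general_cfg):
        # exon 2 (179 nt) disrupts the frame -> truncating branch, NMD yes
        fs = evaluate_pvs1(_splice("c.359+2T>C", PredictionSet(spliceai_dl=0.9)),
                           general_cfg)
        assert fs.strength is Strength.VERY_STRONG
        # exon 3 (180 nt) preserves the frame and removes >10% of the protein
        inframe = evaluate_pvs1(_splice("c.539+1G>A", PredictionSet(spliceai_dl=0.9)),
                                general_cfg)
        assert inframe.strength is Strength.STRONG

    def test_missing_spliceai_not_automated(self, general_cfg):
        bundle = _splice("c.359+1G>A", PredictionSet())
        call = evaluate_pvs1(bundle, general_cfg)
        assert call.state is State.NOT_AUTOMATED

    def test_startloss_moderate(self, general_cfg):
        d = parse_cdna_description("c.2T>C", gene_symbol="GENE1",
                                   transcript_id=GENE1.transcript_id)
        bundle = EvidenceBundle(
            descriptor=d, transcript=GENE1,
            flags=BundleFlags(protein_consequence=Consequence.STARTLOSS),
        )
        assert evaluate_pvs1(bundle, general_cfg).strength is Strength.MODERATE

    def test_missense_not_applicable(self, general_cfg):
        d = parse_cdna_description("c.100A>G")
        bundle = EvidenceBundle(
            descriptor=d, transcript=GENE1,
            flags=BundleFlags(protein_consequence=Consequence.MISSENSE),
        )
        assert evaluate_pvs1(bundle, general_cfg).state is State.NOT_APPLICABLE


def _pred_bundle(cons=Consequence.SYNONYMOUS, **preds):
    d = parse_cdna_description("c.450G>A")
    return EvidenceBundle(
        descriptor=d, transcript=GENE1,
        predictions=PredictionSet(**preds),
        flags=BundleFlags(protein_consequence=cons,
                          is_missense=cons is Consequence.MISSENSE,
                          is_synonymous=cons is Consequence.SYNONYMOUS),
    )


class TestPp3Bp4:
    def _states(self, bundle, cfg):
        return {c.code: c for c in evaluate_pp3_bp4(bundle, cfg)}

    @pytest.mark.parametrize("s, expected", [
        (0.50, "PP3"), (0.15, "BP4"), (0.30, None), (0.9, "PP3"), (0.0, "BP4"),
    ])
    def test_splice_cutoffs_inclusive(self, general_cfg, s, expected):
        calls = self._states(_pred_bundle(spliceai_dl=s), general_cfg)
        assigned = [c for c in ("PP3", "BP4") if calls[c].state is State.ASSIGNED]
        assert assigned == ([expected] if expected else [])

    def test_step_function_has_exactly_two_change_points(self, general_cfg):
        """BP4 -> none -> PP3 as the splice score sweeps 0 to 1."""
        seq = []
        grid = [round(0.01 * i, 2) for i in range(101)]
        for s in grid:
            calls = self._states(_pred_bundle(spliceai_ag=s), general_cfg)
            if calls["PP3"].state is State.ASSIGNED:
                seq.append("PP3")
            elif calls["BP4"].state is State.ASSIGNED:
                seq.append("BP4")
            else:
                seq.append("none")
        changes = [(a, b, grid[i + 1]) for i, (a, b) in enumerate(zip(seq, seq[1:]))
                   if a != b]
        assert [c[:2] for c in changes] == [("BP4", "none"), ("none", "PP3")]
        assert changes[0][2] == pytest.approx(general_cfg.bp4_splice_max + 0.01)
        assert changes[1][2] == pytest.approx(general_cfg.pp3_splice_min)

    def test_protein_arm_missense_only(self, general_cfg):
        calls = self._states(_pred_bundle(Consequence.MISSENSE, revel=0.9,
                                          spliceai_dl=0.05), general_cfg)
        assert calls["PP3"].state is State.ASSIGNED
        # same scores on a synonymous variant: no protein arm, BP4 fires
        calls = self._states(_pred_bundle(Consequence.SYNONYMOUS, revel=0.9,
                                          spliceai_dl=0.05), general_cfg)
        assert calls["BP4"].state is State.ASSIGNED

    def test_bp4_requires_every_arm_benign(self, general_cfg):
        calls = self._states(_pred_bundle(Consequence.MISSENSE, revel=0.10,
                                          spliceai_dl=0.30), general_cfg)
        assert calls["PP3"].state is State.DENIED
        assert calls["BP4"].state is State.DENIED

    def test_no_predictors_not_automated(self, general_cfg):
        calls = self._states(_pred_bundle(), general_cfg)
        assert calls["PP3"].state is State.NOT_AUTOMATED
        assert calls["BP4"].state is State.NOT_AUTOMATED

    @settings(max_examples=200, derandomize=True)
    @given(s=st.one_of(st.none(), st.floats(0, 1)),
           r=st.one_of(st.none(), st.floats(0, 1)))
    def test_never_coassigned(self, s, r):
        from acmgrules.models import GeneConfig

        bundle = _pred_bundle(Consequence.MISSENSE, revel=r, spliceai_al=s)
        calls = self._states(bundle, GeneConfig())
        assert not (calls["PP3"].state is State.ASSIGNED
                    and calls["BP4"].state is State.ASSIGNED)

    def test_mmr_conjunctive_combination(self, configs):
        mlh1 = configs["MLH1"]
        agree = self._states(_pred_bundle(spliceai_dl=0.62, mmr_prior=0.81), mlh1)
        assert agree["PP3"].state is State.ASSIGNED
        disagree = self._states(_pred_bundle(spliceai_dl=0.62, mmr_prior=0.10), mlh1)
        assert disagree["PP3"].state is State.DENIED
        assert disagree["BP4"].state is State.DENIED
        assert "disagree" in disagree["PP3"].explanation
        missing = self._states(_pred_bundle(spliceai_dl=0.62), mlh1)
        assert missing["PP3"].state is State.DENIED


class TestBp7:
    def _call(self, cfg, cons=Consequence.SYNONYMOUS, bp4=True, **preds):
        return evaluate_bp7(_pred_bundle(cons, **preds), cfg, bp4_splice_assigned=bp4)

    def test_conserved_nucleotide_denied(self, general_cfg):
        call = self._call(general_cfg, phastcons=1.0)
        assert call.state is State.DENIED
        assert "conserved" in call.explanation

    def test_nonconserved_assigned(self, general_cfg):
        assert self._call(general_cfg, phastcons=0.1).state is State.ASSIGNED

    def test_cdh1_conservation_condition_dropped(self, configs):
        call = self._call(configs["CDH1"], phastcons=1.0)
        assert call.state is State.ASSIGNED

    def test_missing_phastcons_not_automated(self, general_cfg):
        assert self._call(general_cfg).state is State.NOT_AUTOMATED

    def test_requires_bp4(self, general_cfg):
        assert self._call(general_cfg, bp4=False, phastcons=0.1).state is State.DENIED

    def test_missense_not_applicable(self, general_cfg):
        call = self._call(general_cfg, cons=Consequence.MISSENSE, phastcons=0.1)
        assert call.state is State.NOT_APPLICABLE

    def test_canonical_splice_not_applicable(self, general_cfg):
        bundle = _splice("c.359+1G>A", PredictionSet(phastcons=0.1))
        call = evaluate_bp7(bundle, general_cfg, bp4_splice_assigned=True)
        assert call.state is State.NOT_APPLICABLE


class TestPm4Bp3:
    def _states(self, cons, repeat, cfg):
        d = parse_cdna_description("c.301_303del")
        bundle = EvidenceBundle(
            descriptor=d, transcript=GENE1,
            flags=BundleFlags(protein_consequence=cons, in_repeat_region=repeat),
        )
        return {c.code: c for c in evaluate_pm4_bp3(bundle, cfg)}

    def test_inframe_outside_repeat_is_pm4(self, general_cfg):
        calls = self._states(Consequence.INFRAME_INDEL, False, general_cfg)
        assert calls["PM4"].state is State.ASSIGNED
        assert calls["BP3"].state is State.DENIED

    def test_inframe_in_repeat_is_bp3(self, general_cfg):
        calls = self._states(Consequence.INFRAME_INDEL, True, general_cfg)
        assert calls["BP3"].state is State.ASSIGNED
        assert calls["PM4"].state is State.DENIED

    def test_stoploss_is_pm4(self, general_cfg):
        calls = self._states(Consequence.STOPLOSS, False, general_cfg)
        assert calls["PM4"].state is State.ASSIGNED

    def test_nonsense_not_applicable(self, general_cfg):
        calls = self._states(Consequence.NONSENSE, False, general_cfg)
        assert calls["PM4"].state is State.NOT_APPLICABLE
        assert calls["BP3"].state is State.NOT_APPLICABLE
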