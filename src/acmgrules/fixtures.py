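"""Deterministic synthetic fixtures: transcripts, gene configs, evidence
scenarios and brute-force oracles.

Every scenario template declares the automated criteria it is constructed
to trigger (``intended_criteria``); a dedicated test runs each scenario
through the engine and checks the assignment set matches the intent, so
generator drift is self-detecting. Scenario generation is a pure function
of ``(ScenarioSpec, seed)``.

The numeric thresholds baked into the fixture gene configurations are the
shipped defaults (allele-frequency cut-offs ba1 0.005 / bs1 0.001 /
pm2 2e-5); they are explicit synthetic values, so no test depends on
unpublished guideline numbers.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from .evidence_io import default_gene_configs, dump_evidence_bundle
from .hgvs import parse_cdna_description
from .models import (
    BundleFlags,
    Classification,
    ClinVarContext,
    ClinVarEntry,
    Consequence,
    EvidenceBundle,
    GeneConfig,
    PopulationRecord,
    PredictionSet,
    Strength,
    TranscriptModel,
)

# --------------------------------------------------------------------------
# transcripts
# --------------------------------------------------------------------------

def _transcript(tid: str, exon_ends: list[int],
                relevant_region_end: Optional[int] = None) -> TranscriptModel:
    bounds = []
    prev = 0
    for i, end in enumerate(exon_ends, start=1):
        bounds.append((i, prev + 1, end))
        prev = end
    cds = exon_ends[-1]
    return TranscriptModel(
        transcript_id=tid,
        exon_cdna_bounds=bounds,
        cds_length=cds,
        protein_length=cds // 3 - 1,
        last_junction_cdna=exon_ends[-2] if len(exon_ends) > 1 else 0,
        relevant_region_end=relevant_region_end,
        single_exon=len(exon_ends) == 1,
    )


#: Synthetic transcript geometries used by the scenario templates. Exon
#: bounds are cDNA coordinates; they are fixture inventions, not real
#: RefSeq annotations, even where the identifiers echo familiar ones.
FIXTURE_TRANSCRIPTS: dict[str, TranscriptModel] = {
    "GENE1": _transcript("NM_000001.1", [180, 359, 539, 720, 900]),
    "GENE2": _transcript("NM_000002.1", [180, 240, 420, 720, 900]),
    "GENE3": _transcript("NM_000003.1", [180, 359, 539, 720, 900],
                         relevant_region_end=400),
    "TP53": _transcript("NM_000546.6",
                        [100, 200, 400, 600, 700, 800, 900, 1000, 1100, 1182]),
    "PTEN": _transcript("NM_000314.8",
                        [80, 165, 210, 255, 394, 600, 767, 1026, 1212]),
    "CDH1": _transcript("NM_004360.5",
                        [300, 600, 900, 1137, 1500, 1900, 2300, 2649]),
    "ATM": _transcript("NM_000051.4", [800, 1600, 2400, 3000]),
    "CHEK2": _transcript("NM_007194.4", [400, 800, 1200, 1632]),
    "MLH1": _transcript("NM_000249.4", [400, 800, 1200, 1600, 2000, 2271]),
}


def make_transcript_fixture(n_exons: int, cds_length: int, seed: int) -> TranscriptModel:
    """A reproducible synthetic transcript with ``n_exons`` exons.

    Exon lengths are a seeded random partition of ``cds_length`` with a
    3-nt minimum per exon.
    """
    if n_exons < 1:
        raise ValueError("n_exons must be >= 1")
    if cds_length < max(6, 3 * n_exons):
        raise ValueError("infeasible geometry: cds_length too short for exon count")
    rng = np.random.default_rng(seed)
    extra = rng.multinomial(cds_length - 3 * n_exons, [1.0 / n_exons] * n_exons)
    lengths = extra + 3
    ends = np.cumsum(lengths).tolist()
    return _transcript(f"NM_SYN{n_exons:02d}{seed % 1000:03d}.1", ends)


def fixture_gene_configs() -> dict[str, GeneConfig]:
    """Gene configurations used by all scenario fixtures (shipped defaults)."""
    return default_gene_configs()


# --------------------------------------------------------------------------
# population helpers
# --------------------------------------------------------------------------

_POP_AN = {
    "NFE": 113_000, "AFR": 24_000, "EAS": 18_000,
    "ASJ": 10_000, "FIN": 21_000,
}
_FOUNDERS = {"ASJ", "FIN"}


def _pops(nfe_ac: int = 0, an_jitter: int = 0, **extra_ac: int) -> list[PopulationRecord]:
    records = []
    for label, an in _POP_AN.items():
        ac = nfe_ac if label == "NFE" else extra_ac.get(label, 0)
        records.append(PopulationRecord(
            population_label=label,
            allele_count=ac,
            allele_number=an + an_jitter,
            founder=label in _FOUNDERS,
        ))
    return records


# --------------------------------------------------------------------------
# scenario registry
# --------------------------------------------------------------------------

@dataclass
class ScenarioSpec:
    """Declared intent of one synthetic evidence scenario."""

    name: str
    gene: str = ""
    intended_criteria: set[tuple[str, Strength]] = dc_field(default_factory=set)
    seed: int = 0
    perturbations: dict = dc_field(default_factory=dict)


class UnknownScenarioError(KeyError):
    pass


def _bundle(
    gene: str,
    cdna: str,
    consequence: Consequence,
    transcript_key: Optional[str] = None,
    population: Optional[list[PopulationRecord]] = None,
    predictions: Optional[PredictionSet] = None,
    **kwargs,
) -> EvidenceBundle:
    transcript = FIXTURE_TRANSCRIPTS[transcript_key or gene]
    descriptor = parse_cdna_description(
        cdna, gene_symbol=gene, transcript_id=transcript.transcript_id
    )
    flags = BundleFlags(
        protein_consequence=consequence,
        is_missense=consequence is Consequence.MISSENSE,
        is_synonymous=consequence is Consequence.SYNONYMOUS,
        is_canonical_splice=descriptor.is_canonical_splice_position,
        in_pm1_region=kwargs.pop("in_pm1_region", False),
        in_repeat_region=kwargs.pop("in_repeat_region", False),
    )
    return EvidenceBundle(
        descriptor=descriptor,
        transcript=transcript,
        population=population if population is not None else [],
        predictions=predictions or PredictionSet(),
        flags=flags,
        **kwargs,
    )


def _intent(*pairs: tuple[str, Strength]) -> set[tuple[str, Strength]]:
    return set(pairs)


# Each template: (gene, builder(jitter) -> bundle, intended_criteria)
_TEMPLATES: dict[str, tuple[str, Callable[[int], EvidenceBundle],
                            set[tuple[str, Strength]]]] = {}


def _register(name, gene, intended, builder):
    _TEMPLATES[name] = (gene, builder, intended)


_register(
    "benign_common", "GENE1",
    _intent(("BA1", Strength.STANDALONE)),
    lambda j: _bundle("GENE1", "c.300A>G", Consequence.SYNONYMOUS,
                      population=_pops(nfe_ac=1200, an_jitter=j)),
)
_register(
    "common_intermediate", "GENE1",
    _intent(("BS1", Strength.STRONG)),
    lambda j: _bundle("GENE1", "c.300A>G", Consequence.SYNONYMOUS,
                      population=_pops(nfe_ac=250, an_jitter=j)),
)
_register(
    "rare_truncating", "GENE1",
    _intent(("PVS1", Strength.VERY_STRONG), ("PM2", Strength.SUPPORTING),
            ("PP3", Strength.SUPPORTING)),
    lambda j: _bundle("GENE1", "c.292C>T", Consequence.NONSENSE,
                      population=_pops(an_jitter=j),
                      predictions=PredictionSet(spliceai_dl=0.60)),
)
_register(
    "splice_region_gain", "GENE1",
    _intent(("PVS1", Strength.SUPPORTING), ("PP3", Strength.SUPPORTING),
            ("PM2", Strength.SUPPORTING)),
    lambda j: _bundle("GENE1", "c.359+1G>A", Consequence.INTRONIC,
                      population=_pops(an_jitter=j),
                      predictions=PredictionSet(spliceai_dg=0.80)),
)
_register(
    "synonymous_conserved", "PTEN",
    _intent(("BP4", Strength.SUPPORTING)),
    lambda j: _bundle("PTEN", "c.513C>T", Consequence.SYNONYMOUS,
                      population=_pops(nfe_ac=30, an_jitter=j),
                      predictions=PredictionSet(spliceai_al=0.05, phastcons=1.0)),
)
_register(
    "synonymous_nonconserved", "GENE1",
    _intent(("BP4", Strength.SUPPORTING), ("BP7", Strength.SUPPORTING)),
    lambda j: _bundle("GENE1", "c.450G>A", Consequence.SYNONYMOUS,
                      population=_pops(nfe_ac=30, an_jitter=j),
                      predictions=PredictionSet(spliceai_al=0.02, phastcons=0.12)),
)
_register(
    "cdh1_synonymous", "CDH1",
    _intent(("BP4", Strength.SUPPORTING), ("BP7", Strength.SUPPORTING)),
    lambda j: _bundle("CDH1", "c.2100C>T", Consequence.SYNONYMOUS,
                      population=_pops(nfe_ac=30, an_jitter=j),
                      predictions=PredictionSet(spliceai_dl=0.05, phastcons=1.0)),
)
_register(
    "missense_hotspot", "TP53",
    _intent(("PM1", Strength.MODERATE), ("PP3", Strength.SUPPORTING),
            ("PM2", Strength.MODERATE), ("PS3", Strength.STRONG)),
    lambda j: _bundle("TP53", "c.743G>A", Consequence.MISSENSE,
                      population=_pops(an_jitter=j), in_pm1_region=True,
                      predictions=PredictionSet(revel=0.93, spliceai_al=0.03),
                      protein_change=("R", 248, "Q")),
)
_register(
    "missense_benign", "GENE1",
    _intent(("BS1", Strength.STRONG), ("BP4", Strength.SUPPORTING),
            ("BS2", Strength.STRONG)),
    lambda j: _bundle("GENE1", "c.520A>G", Consequence.MISSENSE,
                      population=_pops(nfe_ac=250, an_jitter=j),
                      predictions=PredictionSet(revel=0.10, spliceai_ag=0.04),
                      flossies_count=5, homozygote_count_noncancer=0),
)
_register(
    "pten_truncating_early", "PTEN",
    _intent(("PVS1", Strength.VERY_STRONG), ("PM2", Strength.MODERATE)),
    lambda j: _bundle("PTEN", "c.1003C>T", Consequence.NONSENSE,
                      population=_pops(an_jitter=j),
                      protein_change=("R", 335, "*")),
)
_register(
    "pten_truncating_late", "PTEN",
    _intent(("PVS1", Strength.MODERATE), ("PM2", Strength.MODERATE)),
    lambda j: _bundle("PTEN", "c.1180C>T", Consequence.NONSENSE,
                      population=_pops(an_jitter=j)),
)
_register(
    "cdh1_truncating_pm5", "CDH1",
    _intent(("PVS1", Strength.VERY_STRONG), ("PM5", Strength.MODERATE),
            ("PM2", Strength.SUPPORTING)),
    lambda j: _bundle("CDH1", "c.1003C>T", Consequence.NONSENSE,
                      population=_pops(an_jitter=j)),
)
_register(
    "cdh1_splice_site", "CDH1",
    _intent(("PVS1", Strength.STRONG), ("PP3", Strength.SUPPORTING),
            ("PM2", Strength.SUPPORTING)),
    lambda j: _bundle("CDH1", "c.1137+1delG", Consequence.INTRONIC,
                      population=_pops(an_jitter=j),
                      predictions=PredictionSet(spliceai_dl=0.95)),
)
_register(
    "splice_first_exon", "GENE1",
    _intent(("PP3", Strength.SUPPORTING), ("PM2", Strength.SUPPORTING)),
    lambda j: _bundle("GENE1", "c.180+1G>T", Consequence.INTRONIC,
                      population=_pops(an_jitter=j),
                      predictions=PredictionSet(spliceai_dl=0.90)),
)
_register(
    "splice_last_exon", "GENE1",
    _intent(("PP3", Strength.SUPPORTING), ("PM2", Strength.SUPPORTING)),
    lambda j: _bundle("GENE1", "c.721-2A>G", Consequence.INTRONIC,
                      population=_pops(an_jitter=j),
                      predictions=PredictionSet(spliceai_al=0.80)),
)
_register(
    "splice_skip_frameshift", "GENE1",
    _intent(("PVS1", Strength.VERY_STRONG), ("PP3", Strength.SUPPORTING),
            ("PM2", Strength.SUPPORTING)),
    lambda j: _bundle("GENE1", "c.359+2T>C", Consequence.INTRONIC,
                      population=_pops(an_jitter=j),
                      predictions=PredictionSet(spliceai_dl=0.90)),
)
_register(
    "splice_skip_inframe_large", "GENE1",
    _intent(("PVS1", Strength.STRONG), ("PP3", Strength.SUPPORTING),
            ("PM2", Strength.SUPPORTING)),
    lambda j: _bundle("GENE1", "c.539+1G>A", Consequence.INTRONIC,
                      population=_pops(an_jitter=j),
                      predictions=PredictionSet(spliceai_dl=0.85)),
)
_register(
    "splice_skip_inframe_small", "GENE2",
    _intent(("PVS1", Strength.MODERATE), ("PP3", Strength.SUPPORTING),
            ("PM2", Strength.SUPPORTING)),
    lambda j: _bundle("GENE2", "c.240+1G>A", Consequence.INTRONIC,
                      transcript_key="GENE2",
                      population=_pops(an_jitter=j),
                      predictions=PredictionSet(spliceai_dl=0.85)),
)
_register(
    "truncating_outside_relevant_region", "GENE3",
    _intent(("PVS1", Strength.STRONG), ("PM2", Strength.SUPPORTING)),
    lambda j: _bundle("GENE3", "c.500C>T", Consequence.NONSENSE,
                      transcript_key="GENE3",
                      population=_pops(an_jitter=j)),
)
_register(
    "truncating_nmd_escape_large_loss", "GENE1",
    _intent(("PVS1", Strength.STRONG), ("PM2", Strength.SUPPORTING)),
    lambda j: _bundle("GENE1", "c.680C>T", Consequence.NONSENSE,
                      population=_pops(an_jitter=j)),
)
_register(
    "inframe_del", "GENE1",
    _intent(("PM4", Strength.MODERATE), ("PM2", Strength.SUPPORTING),
            ("BP4", Strength.SUPPORTING)),
    lambda j: _bundle("GENE1", "c.301_303del", Consequence.INFRAME_INDEL,
                      population=_pops(an_jitter=j),
                      predictions=PredictionSet(spliceai_dl=0.05)),
)
_register(
    "inframe_repeat", "GENE1",
    _intent(("BP3", Strength.SUPPORTING)),
    lambda j: _bundle("GENE1", "c.400_402del", Consequence.INFRAME_INDEL,
                      population=_pops(nfe_ac=30, an_jitter=j),
                      in_repeat_region=True),
)
_register(
    "functional_normal", "ATM",
    _intent(("BS3", Strength.STRONG), ("BP4", Strength.SUPPORTING)),
    lambda j: _bundle("ATM", "c.1010G>A", Consequence.MISSENSE,
                      population=_pops(nfe_ac=30, an_jitter=j),
                      predictions=PredictionSet(revel=0.20, spliceai_ag=0.05)),
)
_register(
    "ps1_codon", "TP53",
    _intent(("PS1", Strength.STRONG), ("PP3", Strength.SUPPORTING),
            ("PM2", Strength.MODERATE)),
    lambda j: _bundle(
        "TP53", "c.817C>T", Consequence.MISSENSE,
        population=_pops(an_jitter=j),
        predictions=PredictionSet(revel=0.85, spliceai_dl=0.02),
        protein_change=("R", 273, "C"),
        codon_context=ClinVarContext(entries=[
            ClinVarEntry(cdna="c.817C>A", protein_change=("R", 273, "C"),
                         classification="P", expert_panel_reviewed=True),
        ]),
    ),
)
_register(
    "pm5_codon", "TP53",
    _intent(("PM5", Strength.MODERATE), ("PP3", Strength.SUPPORTING),
            ("PM2", Strength.MODERATE)),
    lambda j: _bundle(
        "TP53", "c.818G>A", Consequence.MISSENSE,
        population=_pops(an_jitter=j),
        predictions=PredictionSet(revel=0.88, spliceai_dl=0.02),
        protein_change=("R", 273, "H"),
        codon_context=ClinVarContext(entries=[
            ClinVarEntry(cdna="c.817C>T", protein_change=("R", 273, "C"),
                         classification="P", expert_panel_reviewed=True),
        ]),
    ),
)
_register(
    "bp2_homozygous", "CDH1",
    _intent(("BP2", Strength.SUPPORTING), ("BP4", Strength.SUPPORTING)),
    lambda j: _bundle("CDH1", "c.2200G>A", Consequence.MISSENSE,
                      population=_pops(nfe_ac=30, an_jitter=j),
                      predictions=PredictionSet(revel=0.15, spliceai_ag=0.05),
                      homozygote_count_noncancer=2),
)
_register(
    "mmr_splice_agree", "MLH1",
    _intent(("PP3", Strength.SUPPORTING), ("PM2", Strength.MODERATE)),
    lambda j: _bundle("MLH1", "c.1731+5G>A", Consequence.INTRONIC,
                      population=_pops(nfe_ac=1, an_jitter=j),
                      predictions=PredictionSet(spliceai_dl=0.62, mmr_prior=0.81)),
)
_register(
    "mmr_splice_disagree", "MLH1",
    _intent(("PM2", Strength.MODERATE)),
    lambda j: _bundle("MLH1", "c.1731+5G>A", Consequence.INTRONIC,
                      population=_pops(nfe_ac=1, an_jitter=j),
                      predictions=PredictionSet(spliceai_dl=0.62, mmr_prior=0.10)),
)
_register(
    "manual_heavy", "GENE1",
    _intent(("PVS1", Strength.VERY_STRONG), ("PM2", Strength.SUPPORTING)),
    lambda j: _bundle("GENE1", "c.292C>T", Consequence.NONSENSE,
                      population=_pops(an_jitter=j),
                      manual_criteria=[("PP1", Strength.STRONG),
                                       ("PS4", Strength.MODERATE)]),
)
_register(
    "startloss", "GENE1",
    _intent(("PVS1", Strength.MODERATE), ("PM2", Strength.SUPPORTING)),
    lambda j: _bundle("GENE1", "c.2T>C", Consequence.STARTLOSS,
                      population=_pops(an_jitter=j)),
)
_register(
    "no_population", "GENE1",
    _intent(),
    lambda j: _bundle("GENE1", "c.520A>G", Consequence.MISSENSE,
                      population=[],
                      predictions=PredictionSet(revel=0.50, spliceai_ag=0.30),
                      flossies_count=0, homozygote_count_noncancer=0),
)
_register(
    "splice_no_predictions", "GENE1",
    _intent(("PM2", Strength.SUPPORTING)),
    lambda j: _bundle("GENE1", "c.359+1G>A", Consequence.INTRONIC,
                      population=_pops(an_jitter=j)),
)
_register(
    "pten_missense_pp2", "PTEN",
    _intent(("PP2", Strength.SUPPORTING), ("PS3", Strength.STRONG)),
    lambda j: _bundle("PTEN", "c.388C>T", Consequence.MISSENSE,
                      population=_pops(nfe_ac=30, an_jitter=j),
                      predictions=PredictionSet(revel=0.50, spliceai_dl=0.30)),
)
_register(
    "chek2_missense_bs1", "CHEK2",
    _intent(("BS1", Strength.STRONG)),
    lambda j: _bundle("CHEK2", "c.470T>C", Consequence.MISSENSE,
                      population=_pops(nfe_ac=250, an_jitter=j),
                      predictions=PredictionSet(revel=0.40, spliceai_ag=0.20)),
)


def scenario_names() -> list[str]:
    return sorted(_TEMPLATES)


def make_evidence_scenario(spec: ScenarioSpec) -> EvidenceBundle:
    """Build the evidence bundle for a registered scenario template.

    ``perturbations['an_jitter']`` shifts every allele number by a small
    constant without changing the intended criteria, so batches of
    distinct-but-equivalent variants can be generated from one template.
    """
    if spec.name not in _TEMPLATES:
        raise UnknownScenarioError(
            f"unknown scenario template {spec.name!r}; known: {scenario_names()}"
        )
    _, builder, _ = _TEMPLATES[spec.name]
    jitter = int(spec.perturbations.get("an_jitter", 0)) + (spec.seed % 7)
    return builder(jitter)


def scenario_spec(name: str, seed: int = 0, **perturbations) -> ScenarioSpec:
    """The declared :class:`ScenarioSpec` for a registered template."""
    if name not in _TEMPLATES:
        raise UnknownScenarioError(f"unknown scenario template {name!r}")
    gene, _, intended = _TEMPLATES[name]
    return ScenarioSpec(name=name, gene=gene,
                        intended_criteria=set(intended), seed=seed,
                        perturbations=dict(perturbations))


# --------------------------------------------------------------------------
# brute-force combination oracle
# --------------------------------------------------------------------------

def combination_oracle(
    universe: list[tuple[str, Strength, int]],
) -> dict[frozenset, tuple[int, Classification]]:
    """Exhaustively enumerate every subset of a criterion universe.

    ``universe`` holds (code, strength, sign) with sign +1/-1. Points and
    classes are recomputed here from first principles (independent of the
    combiner) so the two routes can be compared: supporting/moderate/
    strong/very-strong map to 1/2/4/8 and the signed sum is banded at
    >=10 / 6 / 0 / -5.
    """
    if len(universe) > 14:
        raise ValueError("universe too large for exhaustive enumeration")
    weight = {"supporting": 1, "moderate": 2, "strong": 4, "very_strong": 8}

    def band(total: int) -> Classification:
        if total >= 10:
            return Classification.PATHOGENIC
        if 6 <= total <= 9:
            return Classification.LIKELY_PATHOGENIC
        if 0 <= total <= 5:
            return Classification.VUS
        if -5 <= total <= -1:
            return Classification.LIKELY_BENIGN
        return Classification.BENIGN

    table: dict[frozenset, tuple[int, Classification]] = {}
    for r in range(len(universe) + 1):
        for subset in itertools.combinations(universe, r):
            total = sum(sign * weight[Strength(st).value]
                        for _, st, sign in subset)
            key = frozenset(code for code, _, _ in subset)
            table[key] = (total, band(total))
    return table


# --------------------------------------------------------------------------
# fixture dataset on disk
# --------------------------------------------------------------------------

def write_fixture_dataset(out_dir, n_variants: int = 50, seed: int = 0) -> Path:
    """Write a complete synthetic test dataset: evidence bundles, a gene
    configuration file and a batch table. Returns the batch-table path.

    Variants are drawn by cycling the scenario registry with small
    allele-number perturbations; generation is byte-reproducible for a
    given seed.
    """
    out = Path(out_dir)
    bundles = out / "bundles"
    bundles.mkdir(parents=True, exist_ok=True)
    names = scenario_names()
    rows = ["gene\ttranscript\tcdna\tevidence_path"]
    for i in range(n_variants):
        name = names[i % len(names)]
        spec = scenario_spec(name, seed=seed, an_jitter=i)
        bundle = make_evidence_scenario(spec)
        path = bundles / f"{i:03d}_{name}.json"
        path.write_text(dump_evidence_bundle(bundle), encoding="utf-8")
        d = bundle.descriptor
        rows.append(f"{d.gene_symbol}\t{d.transcript_id}\t{d.cdna}\t{path}")
    batch = out / "batch.tsv"
    batch.write_text("\n".join(rows) + "\n", encoding="utf-8")
    (out / "gene_config.tsv").write_text(
        "# fixture gene configuration (shipped defaults)\n", encoding="utf-8"
    )
    return batch
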