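"""Core domain types shared by every stage of the classification engine.

The engine consumes a per-variant *evidence bundle* (population allele
counts, in-silico predictor scores, expert-panel codon context, functional
assay records and boolean flags) plus a per-gene configuration of cut-offs,
and emits one :class:`CriterionCall` per ACMG/AMP criterion followed by a
point-based five-tier classification.

Evidence values that were never looked up are represented as ``None``
("explicitly missing"), never as zero: downstream criteria must distinguish
"the evidence says no" (``denied``) from "there is no evidence"
(``not_automated``).
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field as dc_field
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator


# --------------------------------------------------------------------------
# enums
# --------------------------------------------------------------------------

class VariantType(str, enum.Enum):
    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    INSERTION = "insertion"
    DUPLICATION = "duplication"
    DELINS = "delins"
    INVERSION = "inversion"


class Consequence(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SYNONYMOUS = "synonymous"
    INFRAME_INDEL = "inframe_indel"
    STOPLOSS = "stoploss"
    STARTLOSS = "startloss"
    INTRONIC = "intronic"
    UTR = "utr"


class State(str, enum.Enum):
    """Outcome of evaluating one criterion.

    ``denied`` means the evidence was examined and argues against the
    criterion; ``not_automated`` means the required evidence was absent or
    the criterion is out of reach of automation for this gene;
    ``not_applicable`` means the gene-specific guideline forbids the
    criterion; ``warning`` flags an outcome that needs curator review
    (e.g. predicted exon skipping on a terminal exon).
    """

    ASSIGNED = "assigned"
    DENIED = "denied"
    NOT_AUTOMATED = "not_automated"
    NOT_APPLICABLE = "not_applicable"
    WARNING = "warning"


class Strength(str, enum.Enum):
    STANDALONE = "standalone"
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"
    NONE = "none"


class Classification(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "VUS"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"


#: Unsigned magnitude of the naturally scaled point system.
STRENGTH_POINTS = {
    Strength.SUPPORTING: 1,
    Strength.MODERATE: 2,
    Strength.STRONG: 4,
    Strength.VERY_STRONG: 8,
    Strength.STANDALONE: 0,   # BA1 short-circuits instead of scoring
    Strength.NONE: 0,
}

#: Codes whose evidence argues for benignity (points are subtracted).
BENIGN_PREFIXES = ("BA", "BS", "BP")

#: Canonical strength-class rank of a criterion code, used for
#: deterministic tie-breaks when an exclusion pair has equal points.
_CLASS_RANK = {"PVS": 0, "BA": 0, "PS": 1, "BS": 1, "PM": 2, "PP": 3, "BP": 3}


def criterion_sign(code: str) -> int:
    """+1 for pathogenic codes, -1 for benign codes."""
    return -1 if code.upper().startswith(BENIGN_PREFIXES) else 1


def code_class_rank(code: str) -> int:
    for prefix in ("PVS", "PS", "PM", "PP", "BA", "BS", "BP"):
        if code.upper().startswith(prefix):
            return _CLASS_RANK[prefix]
    return 99


# --------------------------------------------------------------------------
# variant identity
# --------------------------------------------------------------------------

class VariantDescriptor(BaseModel):
    """A parsed HGVS coding-DNA variant description.

    Coding positions are 1-based and inclusive; intron offsets are signed
    (0 when exonic); 5'UTR positions are negative; 3'UTR positions are
    stored as positive integers with the matching ``utr3_*`` flag set.
    """

    model_config = ConfigDict(extra="forbid")

    gene_symbol: str
    transcript_id: str
    cdna: str
    variant_type: VariantType
    cdna_start: int
    cdna_end: int
    intron_offset_start: int = 0
    intron_offset_end: int = 0
    ref_allele: str = ""
    alt_allele: str = ""
    indel_length: int = Field(0, ge=0)
    utr3_start: bool = False
    utr3_end: bool = False

    @model_validator(mode="after")
    def _check(self) -> "VariantDescriptor":
        if self.utr3_start == self.utr3_end and self.cdna_start > self.cdna_end:
            raise ValueError("cdna_start must not exceed cdna_end")
        if self.variant_type is VariantType.SUBSTITUTION:
            if self.indel_length != 0 or len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("substitution requires single-nt ref/alt and indel_length 0")
        return self

    @property
    def is_intronic(self) -> bool:
        return self.intron_offset_start != 0 or self.intron_offset_end != 0

    @property
    def is_canonical_splice_position(self) -> bool:
        """±1/±2 intronic dinucleotides flanking an exon."""
        offs = [o for o in (self.intron_offset_start, self.intron_offset_end) if o != 0]
        return any(abs(o) in (1, 2) for o in offs)

    def variant_key(self) -> str:
        return f"{self.gene_symbol}:{self.transcript_id}:{self.cdna}"


class TranscriptModel(BaseModel):
    """Transcript geometry in cDNA space (genome builds are out of scope).

    ``exon_cdna_bounds`` lists ``(exon_index, cdna_first, cdna_last)`` over
    the coding sequence; ``last_junction_cdna`` is the cDNA coordinate of
    the 3'-most exon-exon junction (last nt of the penultimate exon), the
    anchor of the 50-nt NMD rule. ``relevant_region_end`` optionally bounds
    the biologically relevant region used by the loss-of-function decision
    tree.
    """

    model_config = ConfigDict(extra="forbid")

    transcript_id: str
    strand: str = "+"
    exon_cdna_bounds: list[tuple[int, int, int]]
    cds_length: int = Field(gt=0)
    protein_length: int = Field(gt=0)
    last_junction_cdna: int = 0
    relevant_region_end: Optional[int] = None
    single_exon: bool = False

    @model_validator(mode="after")
    def _check(self) -> "TranscriptModel":
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        bounds = self.exon_cdna_bounds
        if not bounds:
            raise ValueError("at least one exon required")
        prev_last = 0
        for idx, first, last in bounds:
            if first != prev_last + 1:
                raise ValueError("exons must be contiguous in cDNA space")
            if last < first:
                raise ValueError("exon bounds reversed")
            prev_last = last
        if prev_last != self.cds_length:
            raise ValueError("exon spans must cover cds_length exactly")
        if self.single_exon != (len(bounds) == 1):
            raise ValueError("single_exon flag inconsistent with exon count")
        if not self.single_exon and not (0 < self.last_junction_cdna < self.cds_length):
            raise ValueError("last_junction_cdna must fall inside the CDS")
        return self

    def exon_of_position(self, cdna_pos: int) -> Optional[tuple[int, int, int]]:
        for exon in self.exon_cdna_bounds:
            if exon[1] <= cdna_pos <= exon[2]:
                return exon
        return None

    @property
    def n_exons(self) -> int:
        return len(self.exon_cdna_bounds)


# --------------------------------------------------------------------------
# evidence
# --------------------------------------------------------------------------

class PopulationRecord(BaseModel):
    """Allele counts for one (sub)population of a control dataset.

    ``coverage_ok`` records whether site mean coverage reached 20x;
    populations failing it never argue for presence or absence.
    ``founder`` marks bottleneck populations (e.g. Ashkenazi Jewish,
    Finnish) whose inflated frequencies may mask negative selection.
    """

    model_config = ConfigDict(extra="forbid")

    population_label: str
    allele_count: int = Field(ge=0)
    allele_number: int = Field(gt=0)
    homozygote_count: int = Field(0, ge=0)
    founder: bool = False
    coverage_ok: bool = True

    @model_validator(mode="after")
    def _check(self) -> "PopulationRecord":
        if self.allele_count > self.allele_number:
            raise ValueError("allele_count exceeds allele_number")
        if self.homozygote_count > self.allele_count // 2:
            raise ValueError("homozygote_count exceeds allele_count // 2")
        return self

    @property
    def af(self) -> float:
        return self.allele_count / self.allele_number


@dataclass
class FrequencySummary:
    """Result of the filtered population-maximum frequency computation."""

    popmax_label: str
    af_point: float
    af_ci_lower: float
    used_ci: bool
    excluded_populations: list[str] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.af_ci_lower <= self.af_point <= 1.0):
            raise ValueError("expected 0 <= af_ci_lower <= af_point <= 1")

    @property
    def statistic(self) -> float:
        """The value compared against the gene's frequency cut-offs."""
        return self.af_ci_lower if self.used_ci else self.af_point


class PredictionSet(BaseModel):
    """In-silico predictor scores; ``None`` means the score was not obtained.

    SpliceAI contributes four delta scores (acceptor/donor gain/loss);
    ``spliceai_gain_flag`` marks that the maximum delta is a gain type,
    which the loss-of-function tree treats conservatively (new splice
    sites have uncertain transcript outcomes). ``mmr_prior`` is the
    mismatch-repair-gene splice prior combined with SpliceAI for those
    genes only.
    """

    model_config = ConfigDict(extra="forbid")

    revel: Optional[float] = Field(None, ge=0.0, le=1.0)
    spliceai_ag: Optional[float] = Field(None, ge=0.0, le=1.0)
    spliceai_al: Optional[float] = Field(None, ge=0.0, le=1.0)
    spliceai_dg: Optional[float] = Field(None, ge=0.0, le=1.0)
    spliceai_dl: Optional[float] = Field(None, ge=0.0, le=1.0)
    spliceai_gain_flag: Optional[bool] = None
    provean: Optional[float] = None
    phastcons: Optional[float] = Field(None, ge=0.0, le=1.0)
    phylop: Optional[float] = None
    mmr_prior: Optional[float] = Field(None, ge=0.0, le=1.0)

    def spliceai_deltas(self) -> Optional[list[float]]:
        vals = [self.spliceai_ag, self.spliceai_al, self.spliceai_dg, self.spliceai_dl]
        present = [v for v in vals if v is not None]
        return present or None

    def spliceai_max(self) -> Optional[float]:
        present = self.spliceai_deltas()
        return max(present) if present else None

    def spliceai_max_is_gain(self) -> Optional[bool]:
        """True when the top delta score is a gain type (AG/DG)."""
        if self.spliceai_gain_flag is not None:
            return self.spliceai_gain_flag
        scores = {
            "ag": self.spliceai_ag, "al": self.spliceai_al,
            "dg": self.spliceai_dg, "dl": self.spliceai_dl,
        }
        present = {k: v for k, v in scores.items() if v is not None}
        if not present:
            return None
        top = max(present, key=lambda k: present[k])
        return top in ("ag", "dg")


class ClinVarEntry(BaseModel):
    """One codon-context record from an expert-curated archive."""

    model_config = ConfigDict(extra="forbid")

    cdna: str
    protein_change: Optional[tuple[str, int, str]] = None
    classification: str  # P, LP, VUS, LB, B
    expert_panel_reviewed: bool = False
    nmd_predicted: Optional[bool] = None

    @model_validator(mode="after")
    def _check(self) -> "ClinVarEntry":
        if self.classification not in ("P", "LP", "VUS", "LB", "B"):
            raise ValueError("classification must be one of P/LP/VUS/LB/B")
        if self.protein_change is not None and self.protein_change[1] < 1:
            raise ValueError("codon_index must be >= 1")
        return self


class ClinVarContext(BaseModel):
    model_config = ConfigDict(extra="forbid")
    entries: list[ClinVarEntry] = Field(default_factory=list)


class FunctionalAssayRecord(BaseModel):
    """One curated clinically calibrated functional-assay result."""

    model_config = ConfigDict(extra="forbid")

    gene: str
    variant_key: str
    source_id: str
    result: str  # abnormal | normal | intermediate
    criterion: Optional[str] = None  # PS3 | BS3 | None
    strength: Strength = Strength.NONE
    guideline_listed: bool = False

    @model_validator(mode="after")
    def _check(self) -> "FunctionalAssayRecord":
        if self.result not in ("abnormal", "normal", "intermediate"):
            raise ValueError("result must be abnormal/normal/intermediate")
        expected = {"abnormal": "PS3", "normal": "BS3", "intermediate": None}[self.result]
        if self.criterion != expected:
            raise ValueError(f"result {self.result} requires criterion {expected}")
        return self


class BundleFlags(BaseModel):
    model_config = ConfigDict(extra="forbid")

    protein_consequence: Consequence
    in_pm1_region: bool = False
    in_repeat_region: bool = False
    is_missense: bool = False
    is_synonymous: bool = False
    is_canonical_splice: bool = False


class EvidenceBundle(BaseModel):
    """Everything the engine consumes for one variant.

    Optional evidence absent from the serialized form stays ``None``;
    criteria that need it return ``not_automated`` rather than a denial.
    """

    model_config = ConfigDict(extra="forbid")

    descriptor: VariantDescriptor
    transcript: TranscriptModel
    population: list[PopulationRecord] = Field(default_factory=list)
    predictions: PredictionSet = Field(default_factory=PredictionSet)
    codon_context: Optional[ClinVarContext] = None
    functional: list[FunctionalAssayRecord] = Field(default_factory=list)
    flags: BundleFlags
    protein_change: Optional[tuple[str, int, str]] = None
    flossies_count: Optional[int] = Field(None, ge=0)
    homozygote_count_noncancer: Optional[int] = Field(None, ge=0)
    nmd_proven: Optional[bool] = None
    cdh1_pm5_splice_eligible: bool = False
    manual_criteria: list[tuple[str, Strength]] = Field(default_factory=list)

    @property
    def consequence(self) -> Consequence:
        return self.flags.protein_consequence


# --------------------------------------------------------------------------
# gene configuration
# --------------------------------------------------------------------------

GENERAL = "GENERAL"

#: Hereditary-cancer genes with dedicated gene-specific rules.
SPECIFIC_GENES = (
    "ATM", "CDH1", "CHEK2", "MLH1", "MSH2", "MSH6", "PMS2", "PTEN", "TP53",
)

MMR_GENES = ("MLH1", "MSH2", "MSH6", "PMS2")


@dataclass
class GeneConfig:
    """Per-gene cut-offs, rule variants and criterion applicability.

    Frequency thresholds are allele frequencies; predictor thresholds are
    on their native [0, 1] scales (REVEL for protein impact, SpliceAI
    delta for splicing). The shipped numeric thresholds are explicit
    defaults for curator review, overridable via the tab-delimited
    configuration file.
    """

    gene_symbol: str = GENERAL
    ba1_af: float = 0.005
    bs1_af: float = 0.001
    pm2_af: float = 0.00002
    pm2_strength: Strength = Strength.MODERATE
    use_ci_lower: bool = True
    ci_confidence: float = 0.95
    exclude_founder: bool = True
    pp3_protein_min: float = 0.70
    bp4_protein_max: float = 0.25
    pp3_splice_min: float = 0.50
    bp4_splice_max: float = 0.15
    bp7_requires_nonconserved: bool = True
    conservation_max_phastcons: float = 1.0
    pvs1_mode: str = "general_tree"  # general_tree | pten_override | cdh1_site_specific
    pvs1_override_boundary: Optional[int] = None
    ps1_enabled: bool = True
    pm5_mode: str = "classic_codon"  # classic_codon | cdh1_truncating | off
    bs2_mode: str = "flossies_or_homozygote"  # off | flossies_or_homozygote | not_automated
    bs2_flossies_min: int = 2
    bs2_homozygote_min: int = 1
    bp2_mode: str = "off"  # off | homozygote_supporting | not_applicable
    mmr_splice_combination: bool = False
    mmr_prior_min: float = 0.50
    pm1_applicable: bool = True
    pp2_enabled: bool = False
    ps3_bs3_covered: bool = True
    bs3_covered: bool = True
    applicability: dict[str, str] = dc_field(default_factory=dict)

    def validate(self) -> None:
        if not (self.ba1_af > self.bs1_af > self.pm2_af >= 0.0):
            raise ValueError(
                f"{self.gene_symbol}: frequency thresholds must satisfy "
                f"ba1_af > bs1_af > pm2_af >= 0 "
                f"(got {self.ba1_af}, {self.bs1_af}, {self.pm2_af})"
            )
        if not self.pp3_splice_min > self.bp4_splice_max:
            raise ValueError(
                f"{self.gene_symbol}: pp3_splice_min must exceed bp4_splice_max "
                f"(got {self.pp3_splice_min} <= {self.bp4_splice_max})"
            )
        if not self.pp3_protein_min > self.bp4_protein_max:
            raise ValueError(
                f"{self.gene_symbol}: pp3_protein_min must exceed bp4_protein_max "
                f"(got {self.pp3_protein_min} <= {self.bp4_protein_max})"
            )
        if self.pvs1_mode not in ("general_tree", "pten_override", "cdh1_site_specific"):
            raise ValueError(f"{self.gene_symbol}: unknown pvs1_mode {self.pvs1_mode!r}")
        if self.pm5_mode not in ("classic_codon", "cdh1_truncating", "off"):
            raise ValueError(f"{self.gene_symbol}: unknown pm5_mode {self.pm5_mode!r}")
        if self.bs2_mode not in ("off", "flossies_or_homozygote", "not_automated"):
            raise ValueError(f"{self.gene_symbol}: unknown bs2_mode {self.bs2_mode!r}")
        if self.bp2_mode not in ("off", "homozygote_supporting", "not_applicable"):
            raise ValueError(f"{self.gene_symbol}: unknown bp2_mode {self.bp2_mode!r}")


# --------------------------------------------------------------------------
# criterion calls and classification
# --------------------------------------------------------------------------

@dataclass
class CriterionCall:
    """One criterion's evaluated state, strength, points and explanation."""

    code: str
    state: State
    strength: Strength = Strength.NONE
    explanation: str = ""
    source: str = "automated"  # automated | manual
    warnings: list[str] = dc_field(default_factory=list)

    @property
    def points(self) -> int:
        if self.state is not State.ASSIGNED:
            return 0
        return criterion_sign(self.code) * STRENGTH_POINTS[self.strength]

    def __post_init__(self) -> None:
        if self.strength is Strength.STANDALONE and self.code != "BA1":
            raise ValueError("standalone strength is only valid for BA1")


@dataclass
class ExclusionRule:
    """An unordered pair of criteria that must not be combined."""

    code_a: str
    code_b: str
    rationale: str = ""

    @property
    def pair(self) -> frozenset:
        return frozenset((self.code_a, self.code_b))


@dataclass
class Pvs1Outcome:
    strength: Strength
    path: list[str] = dc_field(default_factory=list)
    warnings: list[str] = dc_field(default_factory=list)


@dataclass
class ClassificationResult:
    """Post-exclusion criterion set, total points and five-tier class."""

    calls: list[CriterionCall]
    active: list[CriterionCall]
    dropped: list[tuple[str, str, str]]  # (dropped_code, kept_code, rationale)
    total_points: int
    classification: Classification
    ba1_standalone: bool
    warnings: list[str] = dc_field(default_factory=list)
    variant_key: str = ""
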