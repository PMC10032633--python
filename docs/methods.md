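# Methods

## Scope and design

`acmgrules` is a deterministic rules engine: given a variant description
(gene symbol, transcript identifier, HGVS coding-DNA name), an *evidence
bundle* (JSON) and a per-gene configuration of cut-offs, it evaluates
each ACMG/AMP criterion, applies overlap exclusions and produces a
point-based five-tier classification. Nothing is fetched at run time;
reproducibility and explainability are the design goals. Every criterion
call carries one of five states — `assigned`, `denied`, `not_automated`,
`not_applicable`, `warning` — so that "the evidence argues no" is never
conflated with "there is no evidence". Missing evidence is serialized as
absent and deserialized as `None`; it yields `not_automated`, never a
denial.

Supported variants are single-nucleotide substitutions, deletions,
duplications, insertions and single-anchor deletion–insertions up to
25 nt, including intronic (signed offsets) and UTR positions. Inversions,
two-sided delins and longer indels are rejected with machine-readable
reasons. The HGVS subset is parsed by a purpose-built grammar
(`acmgrules.hgvs`); nomenclature correction, transcript discovery and
genome-coordinate (VCF) input are out of scope, which is why all
coordinates are kept in cDNA space and transcripts are described by their
exon bounds in that space.

## Point system and bands

Assigned criteria score +1/+2/+4/+8 at supporting/moderate/strong/very
strong strength (negated for benign criteria). The signed total is banded
as: ≥ 10 pathogenic; 6–9 likely pathogenic; 0–5 VUS; −5–−1 likely benign;
≤ −6 benign. BA1 is standalone: when it fires, the classification is
benign regardless of other evidence; the engine still evaluates and
reports every other criterion for the curator, but only BA1 remains in
the point-contributing set (with 0 points, since no sum is needed).

Overlap exclusions are data (a packaged tab-delimited table), not code.
The shipped pairs are PVS1×PP3, PVS1×PM1, PM1×PP3 and PVS1×PM4 —
combinations that would double-count prediction, domain-location or
protein-length evidence. Within a triggered pair the lower-point call is
dropped; ties keep the code in the earlier canonical strength class
(PVS < PS < PM < PP), which makes the outcome deterministic and
independent of input order. Every drop is recorded with its rationale.

## Population criteria

BA1/BS1 compare a *filtered population maximum* against per-gene
cut-offs. Populations failing site coverage (mean < 20×) never count;
founder populations (bottlenecked — the shipped fixtures mark Ashkenazi
Jewish and Finnish) are excluded from the maximum because drift can mask
negative selection. The comparison statistic is either the point allele
frequency or the one-sided 95% exact-binomial (Clopper–Pearson) lower
confidence bound, per configuration. Clopper–Pearson was chosen because
it is conservative, closed-form (a beta quantile: the 1−c quantile of
Beta(k, n−k+1)) and reproducible; the level is configurable
(`ci_confidence`, default 0.95). Threshold comparisons are inclusive
(statistic ≥ cut-off assigns), covered by boundary tests.

PM2 requires absence from **all** coverage-passing populations (with at
least one such population — absence with no coverage is `not_automated`)
or a pooled global statistic at or below the PM2 cut-off. BA1, BS1 and
PM2 are mutually exclusive by construction. BS2 evaluates FLOSSIES
observations and non-cancer homozygote counts where the gene mode allows
(inapplicable for ATM/CHEK2, beyond automation for CDH1 and the
mismatch-repair genes); the count thresholds (2 FLOSSIES observations,
1 homozygote) are explicit configuration defaults flagged for curator
review, as no published values exist for them.

### Shipped thresholds

The numeric frequency cut-offs shipped per gene (BA1 0.005, BS1 0.001,
PM2 2×10⁻⁵) are explicit engine defaults intended to be overridden from
the applicable guideline via the configuration file; gene-specific
guideline *structure* (rule variants, applicability, strengths — e.g.
CDH1's PM2 at supporting strength) is encoded in the shipped per-gene
configurations. The general ruleset also keeps PM2 at supporting
strength, in line with current practice of demoting
absence-from-controls evidence. All tests use these same explicit
values, so no result depends on unpublished numbers.

## Loss-of-function tree (PVS1)

Nonsense/frameshift variants: nonsense-mediated decay is predicted by
the 50-nt junction rule — the premature stop must lie more than 50 nt
upstream of the last exon–exon junction of a multi-exon transcript
(single-exon transcripts never trigger NMD). NMD-positive truncations in
the biologically relevant region (bounded by
`TranscriptModel.relevant_region_end`; unbounded means the whole CDS is
relevant) are very strong, otherwise strong. NMD-escaping truncations
are strong when more than 10% of the protein is lost, else moderate. The
10% cut and the 50-nt window are module constants documented here; the
region boundary is data.

Canonical ±1/±2 splice variants: a predicted splice-site *gain*
(maximum SpliceAI delta of acceptor/donor-gain type) has an uncertain
transcript outcome, so the engine conservatively assigns supporting
strength and warns that an RNA assay is needed before any upgrade.
Predicted loss maps the site to its exon: skipping the first or last
exon yields a warning with no strength (curator review); internal-exon
skips preserve or disrupt the reading frame according to exon length
modulo 3 — frame-disrupting skips re-enter the truncation branch with
the exon start as the stop proxy, in-frame skips use the >10% rule on
the removed fraction. Missing SpliceAI scores make the call
`not_automated`.

Gene modes: the PTEN-style override forces very strong for truncations
5′ of a configured boundary (c.1121) regardless of NMD; the CDH1-style
mode consults a packaged per-site strength table for canonical splice
positions (c.1137+1 → strong) before any prediction logic. Start-loss
variants take the moderate branch. Every call records its root-to-leaf
path, and a coverage test asserts each leaf is reachable from the
fixture scenarios.

## Prediction criteria (PP3/BP4/BP7)

The splice arm thresholds the maximum of the four SpliceAI delta scores:
≥ 0.50 assigns PP3, ≤ 0.15 assigns BP4, the gap assigns neither (a
two-change-point step function, asserted on a 0.01 grid). The protein
arm applies to missense variants only and uses REVEL with shipped
defaults 0.70/0.25 (plain configuration values). PP3 fires when any
evaluable arm predicts impact; BP4 only when *every* evaluable arm
supports benignity. Strength is conservatively fixed at supporting. For
mismatch-repair genes the splice call is conjunctive: SpliceAI and the
dedicated splice prior must agree (threshold 0.5 on the prior);
disagreement produces no call with an explanation. The conjunction was a
design choice where only "combination" was specified — it is the
conservative operator.

BP7 (synonymous or deep-intronic variants) requires the BP4 splice arm
and, unless the gene's guideline dropped the condition (CDH1), a
non-conserved nucleotide: phastCons at or above the configured maximum
(default 1.0, i.e. a score of 1 blocks BP7) denies the call; a missing
score with the condition active is `not_automated`. PhyloP is carried in
the bundle but unused by default, as no threshold is established.

## Codon context, functional assays, applicability

PS1/PM5 use only expert-panel-reviewed pathogenic entries: PS1 for an
identical protein change through a different nucleotide change, PM5 for
a different substitution at the same residue (missense only, and never
together with PS1). The CDH1-style mode retires PS1 and grants PM5 to
nonsense/frameshift variants predicted (50-nt rule) or proven (explicit
RNA-evidence flag in the bundle) to undergo NMD, and to canonical splice
variants explicitly marked eligible — eligibility is a bundle flag, not
a guess.

PS3/BS3 are exact-key lookups in the packaged calibrated-assay table
(synthetic stand-in rows; real deployments extend or replace the file).
Genes without usable assay literature (CDH1, PMS2 entirely; PTEN for
BS3) stay `not_automated`, as does any variant without a record —
absence of an assay is not evidence. When records conflict,
guideline-listed sources outrank others; unresolved conflicts suppress
both calls with a warning.

PM1 applies only to missense and small in-frame indels inside a hotspot
flag, and not at all for ATM, CDH1 or the mismatch-repair genes; PP2
only for PTEN missense. BP2 is inapplicable for mismatch-repair genes
and otherwise grants at most supporting strength from observed
homozygosity, because control-population homozygotes cannot be assumed
healthy for adult-onset disease. PP5/BP6 are retired and rejected at
manual intake; segregation, de-novo, allelic and phenotype criteria
(PP1, BS4, PS2, PM6, PM3, PS4, PP4, BP5) enter as curator-supplied
(code, strength) pairs and merge like automated calls, a manual code
overriding an automated assignment with a logged warning.

## Synthetic data

The fixtures module generates everything the tests consume: transcript
geometries (hand-laid exon bounds for the nine genes plus three generic
models, and a seeded random partition generator for property tests),
subpopulation allele-count profiles (five labelled populations, two
founder-flagged, total AN ≈ 186 000, echoing large exome aggregates) and
34 scenario templates, each declaring the exact criteria it is built to
trigger. A test runs every scenario through the engine and asserts the
assignment set equals the declaration, so generator drift is
self-detecting. Scenarios cover every criterion code in assigned state
and at least one negative state, and every leaf of the loss-of-function
tree. The batch generator cycles templates with small allele-number
perturbations that leave intent unchanged.

What the generator does **not** emulate: real gnomAD subpopulation
structure beyond labelled AC/AN/founder records, genuine transcript
annotations (the exon bounds are inventions even where identifiers look
familiar), linkage between predictor scores and sequence context, and
real calibrated-assay literature (the shipped table is synthetic).
Passing tests therefore demonstrate the correctness of the *rules*, not
the clinical validity of any particular threshold on real data.

## Numerical and procedural choices

* Clopper–Pearson via the beta quantile; verified in tests against an
  independent bisection of the binomial survival function (1e-9) and
  against a second library implementation.
* All threshold comparisons inclusive; documented boundary tests at
  BA1, PP3/BP4 and the 25-nt scope limit.
* Exclusion tie-break by canonical strength class; permutation
  invariance is property-tested.
* Problem sizes: the exhaustive combiner check enumerates all 4096
  subsets of a 12-criterion universe; the exclusion/monotonicity
  property runs 1000 seeded random criterion sets; the batch test runs
  50 fixture variants. These sizes exercise every code path while
  keeping the suite fast.
* Determinism: no step uses unseeded randomness; bundle serialization
  is canonical (sorted keys), making generation byte-reproducible.

## Limitations

The engine classifies from the evidence it is handed: bundle quality
bounds output quality, and the non-automatable criteria still require a
curator. The shipped frequency/predictor thresholds are defaults to be
reviewed against the applicable guideline version. The HGVS subset
excludes complex rearrangements, and transcripts are trusted as given —
no consistency check against a reference genome is possible in cDNA
space.
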