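# acmgrules

Deterministic ACMG/AMP variant classification for hereditary-cancer genes,
driven by locally supplied evidence bundles.

Clinical laboratories classify germline variants by combining coded
evidence criteria (PVS1, PS1–PS4, PM1–PM6, PP1–PP5 for pathogenicity;
BA1, BS1–BS4, BP1–BP7 for benignity). Generic rules leave room for
interpretation, so expert panels publish gene-specific refinements —
different frequency cut-offs, demoted or retired criteria, dedicated
loss-of-function rules. `acmgrules` implements this per-criterion
evaluation as a pure rules engine for nine hereditary-cancer genes
(*ATM*, *CDH1*, *CHEK2*, *MLH1*, *MSH2*, *MSH6*, *PMS2*, *PTEN*, *TP53*)
plus a general ruleset, for curators and pipeline developers who want
reproducible, explainable criterion calls without any live database
access: every piece of evidence arrives in a JSON *evidence bundle*.

## The model

Each assigned criterion carries a strength and contributes points on the
naturally scaled scheme

&nbsp;&nbsp;supporting = 1, moderate = 2, strong = 4, very strong = 8,

positive for pathogenic criteria and negative for benign ones. The signed
total *S* maps onto five tiers:

| *S* ≥ 10 | 6 ≤ *S* ≤ 9 | 0 ≤ *S* ≤ 5 | −5 ≤ *S* ≤ −1 | *S* ≤ −6 |
|---|---|---|---|---|
| pathogenic | likely pathogenic | VUS | likely benign | benign |

BA1 is standalone: a common variant is benign outright. Before summing,
overlap-exclusion rules drop the weaker member of any pair of criteria
that would count the same evidence twice (e.g. PVS1 with PP3, PM1 with
PP3). Highlights of the per-criterion logic:

* **PVS1** walks a loss-of-function decision tree: nonsense-mediated
  decay prediction (50-nt junction rule), biologically relevant region,
  fraction of protein lost, splice-site gain conservatism (supporting
  strength plus an RNA-assay warning), terminal-exon skip warnings, a
  PTEN-style very-strong override for truncations 5′ of c.1121, and a
  CDH1-style per-site splicing table (c.1137+1 → strong).
* **BA1/BS1/PM2** compare a filtered population maximum — founder
  populations excluded, one-sided 95% Clopper–Pearson lower bound
  optional — against per-gene frequency cut-offs.
* **PP3/BP4** threshold the maximum SpliceAI delta (≥ 0.5 / ≤ 0.15) and
  REVEL for missense; mismatch-repair genes additionally require the
  dedicated splice prior to agree. **BP7** adds a phastCons conservation
  check where the gene's guideline demands one.
* **PS1/PM5** compare against expert-panel-classified variants at the
  same codon; CDH1 instead grants PM5 to truncations undergoing NMD.
* **PS3/BS3** are looked up in a curator-extensible calibrated-assay
  table; PP5/BP6 are retired and rejected; segregation/de-novo criteria
  enter through manual intake.

Missing evidence is never treated as a denial: criteria return
`not_automated` and the report says why.

## Worked example

```
$ acmgrules make-fixtures --out fx --n 34 --seed 0
$ acmgrules classify GENE1 NM_000001.1 "c.292C>T" fx/bundles/021_rare_truncating.json --out report.tsv
GENE1:NM_000001.1:c.292C>T	likely_pathogenic	9 points
```

The report explains every call. The nonsense variant at c.292 triggers
NMD (the stop lies well upstream of the last exon–exon junction), so
PVS1 is very strong (8); absence from all five control populations adds
PM2 at supporting strength (1); the high SpliceAI score fires PP3, but
the overlap rule drops it in favour of PVS1, leaving a total of 9 —
likely pathogenic:

```
PVS1	assigned	very_strong	8	automated	path: nonsense > nmd:yes > region:relevant
PM2	assigned	supporting	1	automated	variant absent from all 5 coverage-passing populations (AN 186105)
PP3	assigned	supporting	1	automated	SpliceAI max delta 0.60 >= 0.50
## total_points	9
## classification	likely_pathogenic
## dropped	PP3->PVS1: splice/protein prediction is already counted inside the loss-of-function tree
```

Gene-specific cut-offs live in a three-column tab-delimited file
(`gene<TAB>parameter<TAB>value`) that overrides the shipped defaults, and
`acmgrules batch` classifies a variant table sequentially with a fresh
per-run log. See `docs/methods.md` for the full model description and
parameter reference.

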