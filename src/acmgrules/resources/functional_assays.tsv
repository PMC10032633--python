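# SYNTHETIC curated functional-assay table. Real deployments replace this
# with records extracted from clinically calibrated mid-to-high-throughput
# assays listed in gene-specific guidelines; the rows below are synthetic
# stand-ins used by the shipped fixtures and tests.
gene	variant_key	source_id	result	criterion	strength	guideline_listed
TP53	TP53:NM_000546.6:c.892G>T	synthetic:assay01	abnormal	PS3	strong	true
TP53	TP53:NM_000546.6:c.743G>A	synthetic:assay01	abnormal	PS3	strong	true
ATM	ATM:NM_000051.4:c.1010G>A	synthetic:assay02	normal	BS3	strong	true
CHEK2	CHEK2:NM_007194.4:c.470T>C	synthetic:assay03	intermediate		none	false
PTEN	PTEN:NM_000314.8:c.388C>T	synthetic:assay04	abnormal	PS3	strong	true
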