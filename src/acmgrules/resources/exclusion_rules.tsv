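# Pairs of criteria that must not be combined because they count the same
# underlying evidence twice (CanVIG-UK-style overlap exclusions).
code_a	code_b	rationale
PVS1	PP3	splice/protein prediction is already counted inside the loss-of-function tree
PVS1	PM1	a truncating call subsumes functional-domain location evidence
PM1	PP3	PM1 (functional domain) and computational prediction use the same information
PVS1	PM4	protein-length change is already counted by the loss-of-function call
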