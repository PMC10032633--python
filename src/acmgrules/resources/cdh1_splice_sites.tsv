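# Site-specific PVS1 strengths for canonical splice positions (CDH1-style
# splicing table). Key is the coding anchor plus signed intron offset.
site	strength
1137+1	strong
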