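# Shipped benchmark family: a glycoside-hydrolase-family-65 analog.
# 22 subgroups x 50 sequences over 600 columns, 24 planted co-evolving
# columns (six strong at reference positions 64, 392, 394, 402, 416,
# 585 with hub 392; fifteen weak partners; a three-column loop cluster),
# per-site substitution noise 0.02, gap rate 0.01.  The per-column
# subgroup->residue maps are constructed by specmap.simulate.gh65_analog_spec.
family: gh65_analog
seed: 20210
epsilon: 0.02
seqs_per_subgroup: 50
n_columns: 600
gap_rate: 0.01
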