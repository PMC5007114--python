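# Demo configuration for the eight-lineage schematic Firmicutes fixture.
# The fixture tree offers five reattachment positions per diderm clade
# (the full reference phylogeny offers six).
seed = 0
n_markers = 47
marker_length = 118
missing_rate = 0.1
paralog_markers = 2
alpha = 0.7
n_gene_trees = 47
spr_moves = 1
gene_missing_frac = 0.0
max_absent_frac = 0.5
max_missing_markers = 11
support_threshold = 70
n_boot = 2000
n_positions = 5
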