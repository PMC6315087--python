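expression: toy_expression.tsv
meta: toy_meta.tsv
annotations: toy_annotations.gmt
ppi_edges: toy_ppi_edges.tsv
omega: toy_omega.tsv
seed: 1
n_boot: 100
k: 6
n_init: 10
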