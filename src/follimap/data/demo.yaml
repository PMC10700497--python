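# Bundled demonstration run: both modalities simulated at reduced scale so the
# full pipeline finishes in minutes on one CPU.
seed: 1
outdir: follimap_demo

scrna:
  simulate: true
st:
  simulate: true

simulate:
  n_cells_per_timepoint: 200
  n_genes: 600
  n_spots: 300

qc: {}

markers:
  test: ttest
  scrna_p: 1.0e-20
  st_p: 1.0e-3

mia:
  background: intersection

interactions:
  n_permutations: 200
  p_rule: add_one
  sig_threshold: 0.05
  senders: [Macrophage, Neutrophil, DC]
  receivers: [TFC-1, TFC-2]
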