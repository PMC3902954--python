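# Rare-population study: endothelial-like target at f = 0.02.
# Scaled to 1000 genes for a quick demonstration run.
seed: 7
simulation:
  n_genes: 1000
  target_fraction: 0.02
  n_markers: 60
  marker_effect: 8.0
  background: 0.05
  dispersion: 0.05
  depth: 400000
  replicates: 3
thresholds:
  fc_min: 2.0
  padj_max: 0.001
  rpkm_floor: 1.0
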