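# Fibroblast-like (VH10) scenario: low-expressing normal cells.  The 3C
# profile is pure distance decay with no loops, expression and ddPCR carry
# only the calibrator sample, and ChIP enrichment over IgG is flat (fold 1)
# at both assayed regions.
name: fibroblast
seed: 20190111
locus:
  length_bp: 210000
  tss_position: 85000
  gene_strand: "+"
  motif: AAGCTT
  anchor_fragment_bp: 1500
  bait_fragment_bp: 2000
  extra_cut_sites: 8
anchors_kb: [-79.7, -63.2, -30.7, -6.8, 48.4, 71.3, 119.3]
decay:
  a: 2.6076809621
  b: 0.5
loops: []
replicates: 3
normalizer_cq: 25.0
cq_noise_sd_3c: 0.15
cq_noise_sd_expression: 0.12
cq_noise_sd_chip: 0.15
digestion:
  efficiency: 0.92
  cq_noise_sd: 0.15
expression:
  calibrator: fibroblast
  samples: {}
chip:
  cell_line: VH10
  experiments: 2
  input_fraction: 0.01
  baseline_percent_input: 0.05
  folds: {minus63kb: 1.0, plus48kb: 1.0}
ddpcr:
  calibrator: fibroblast
  samples: {}
  reference_lambda: 0.5
  target_base_lambda: 0.2
  wells_per_sample: 2
  total_droplets: 15000
  droplet_volume_nl: 0.85
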