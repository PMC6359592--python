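# PC3M-like scenario: strongly expressing prostate-cancer cell line with
# both promoter-interacting elements present.
#
# Effect sizes (loop folds, expression folds, ChIP enrichments, ddPCR
# ratios) are the scenario's ground truth and are what the analysis
# modules are expected to recover.  Replicate noise levels are tuning
# choices: no replicate dispersion is published for assays of this kind
# at this scale, so the defaults are set to values typical of careful
# TaqMan/SYBR plate work (sd 0.12-0.15 cycles).
name: pc3m
seed: 20190109
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
  # a is chosen so the proximal (-6.8 kb) fragment sits at rel == 1;
  # b = 0.5 reproduces the observed ratio between fold-over-background
  # and fold-over-proximal at the two looping fragments.
  a: 2.6076809621
  b: 0.5
loops:
  - {anchor_kb: -63.2, fold: 9.0}
  - {anchor_kb: 48.4, fold: 6.0}
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
  samples:
    PC3M: {GAPDH: 4.5, PBGD: 3.0}
chip:
  cell_line: PC3M
  experiments: 2
  input_fraction: 0.01
  baseline_percent_input: 0.05
  folds: {minus63kb: 30.0, plus48kb: 60.0}
ddpcr:
  calibrator: fibroblast
  samples: {PC3M: 2.5}
  reference_lambda: 0.5
  target_base_lambda: 0.2
  wells_per_sample: 2
  total_droplets: 15000
  droplet_volume_nl: 0.85
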