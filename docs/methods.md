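# Methods

## Overview

`loop3c` quantifies promoter-anchored chromatin looping from 3C-qPCR data.
In a 3C experiment, chromatin is crosslinked, digested with a single
restriction enzyme (HindIII here), and re-ligated so that spatially
proximal fragments form chimeric junctions. The abundance of the junction
between a fixed bait fragment (the gene promoter) and each assayed distal
fragment, read out as a TaqMan quantification cycle (Cq), is the raw
interaction signal. The package also implements the three companion
quantifications such a study needs: ddCt relative expression, ChIP-qPCR
percent-input enrichment, and droplet digital PCR (ddPCR) Poisson
concentrations.

## Locus model

The locus is digested in silico at every occurrence of the enzyme
recognition motif (default `AAGCTT`). Coordinates are 0-based half-open;
the cut is placed at the motif start by default (the sticky-end offset is
configurable but irrelevant downstream, where only fragment identity
matters). Each fragment's position is summarized as the signed distance
in kb from its midpoint to the transcription start site (TSS), oriented so
that negative always means upstream of the gene. Midpoints are used
because a single per-fragment distance is needed and fragment widths (1-16
kb for HindIII) make any boundary convention equally arbitrary. `N` bases
never match the motif: digestion is treated conservatively in ambiguous
sequence.

## 3C quantification

Relative ligation frequency for a junction is

    rel = 2 ** (Cq_normalizer - Cq_junction)

against a control junction inside a conformationally invariant,
ubiquitously expressed locus (an ERCC3-style normalizer). This makes
profiles invariant to template amount and plate-wide Cq shifts; an
optional per-assay calibration factor (for a random-ligation control) is
supported and defaults to 1. Replicates are summarized as mean, sd, n per
fragment. Independent libraries are combined by geometric mean.

### Distance-decay background

Polymer contact frequency falls off with genomic distance approximately as
a power law, so the background is modelled as `rel = a * |d|**-b` and
fitted by least squares in log-log space. True loops would inflate their
own background, so the fit excludes candidates iteratively (at most 3
rounds): after each round, points lying more than 2 robust standard
deviations *above* the fit are excluded and the model refitted. Two
numerical choices matter here and were made deliberately:

* **Robust scale.** The residual scale is `1.4826 * MAD`, floored at the
  replicate-noise level (the median per-point log standard error). With
  only ~7 anchors, one or two strong loops dominate an ordinary residual
  variance and mask themselves; the MAD ignores them. The floor prevents
  the opposite failure, where a lucky tight null fit makes the MAD
  collapse and ordinary noise gets excluded.
* **One-sided exclusion.** Loops are enrichments; points below the fit
  are never excluded. This halves the null exclusion rate and avoids
  discarding legitimate distal plateau points that sit below a
  loop-contaminated first-round fit.

If the fitted exponent is not positive, the model falls back to a flat
background at the median level and logs a warning.

### Loop calling

A fragment is called a loop when its signal exceeds the fitted background
by at least 3-fold *and* a promoter-proximal reference fragment by at
least 1.5-fold. The proximal reference is the fragment nearest the TSS
within a 4-kb window, falling back to the nearest assayed fragment (with a
log note) when no fragment is that close — the bundled scenarios' nearest
anchor sits at -6.8 kb, so the fallback is the common path. The two
thresholds sit between the null regime (both folds near 1) and the
reported looping regime (6-9x background, 2-3x proximal), and are exposed
in the run configuration.

### Digestion QC

Per restriction site, efficiency is computed from paired
digested/undigested templates with a site-spanning and a control
amplicon:

    ddCq = (Cq_site,dig - Cq_ctrl,dig) - (Cq_site,undig - Cq_ctrl,undig)
    efficiency% = 100 - 100 / 2**ddCq

A library passes QC when every assayed site exceeds 85%. By default a
failing library aborts the pipeline; a warn-only mode exists.

## Expression (ddCt)

Per sample, dCq = mean Cq_target - mean Cq_reference; the fold change vs
the calibrator sample is `2**-ddCq` at perfect efficiency, with the
general efficiency-corrected ratio `(1+E_t)**dCq_t / (1+E_r)**dCq_r` when
assay efficiencies are provided (default E = 1; no standard curves are
assumed). Inference uses per-replicate dCq values: a two-sided Welch
t-test between samples (a robust default at n = 3, where nothing supports
equal-variance assumptions) and a t-interval on ddCq back-transformed to
the fold scale. Reference genes are analyzed separately by default; a
geometric-mean combination mode exists. Stars: `*` p < 0.05, `**`
p < 0.01, `***` p < 0.001; a two-tier preset (0.05, 0.001) is provided
for ChIP-style panels.

## ChIP-qPCR

Percent input adjusts the input Cq by `log2(1/input_fraction)` (default
fraction 1%, i.e. 6.64 cycles) and computes
`100 * 2**(adjusted_input_Cq - IP_Cq)`. Specific enrichment is the ratio
of antibody to IgG percent input with the input well shared per
experiment, so the input fraction and input-well noise cancel exactly in
the fold. Experiments are combined as a geometric mean with a Welch
t-test on log2 percent input — enrichment ratios are approximately
log-normal, so the log scale is where averaging and testing are honest.

## ddPCR

With target molecules Poisson-distributed over ~0.85-nl droplets, the mean
copies per droplet is `lambda = -ln(1 - p)` for positive fraction p, and
concentration is lambda over droplet volume. The volume default is the
QX100-era convention and cancels in all ratios. The standard error of
lambda is `sqrt(p / ((1-p) * total))` by the delta method; confidence
intervals are normal by default with an exact Clopper-Pearson option for
low counts, and wells with fewer than 10 positive or 10 negative droplets
are flagged. Sample ratios are double-normalized —
`(target/reference)_test / (target/reference)_calibrator` — with
duplicates averaged on the concentration scale and the interval from
log-scale error propagation.

## Synthetic-data generator

The generator emulates the study conditions and is the ground truth for
every test:

* **Locus**: 210 kb, TSS at 85 kb, gene on the + strand, anchors at
  -79.7, -63.2, -30.7, -6.8, +48.4, +71.3 and +119.3 kb. One 1.5-kb
  fragment is centered on each anchor (two planted cuts), a 2-kb bait on
  the TSS, plus 8 extra cut sites placed away from planted fragments.
  Accidental motif occurrences in the random background are edited out,
  so the digest's ground truth is exactly the planted cut list.
* **Decay**: `a * |d|**-b` with b = 0.5 and a = 6.8**0.5, putting the
  proximal (-6.8 kb) anchor at rel = 1. The exponent is set by the
  internal consistency of the looping scenario: with loop enrichments of
  9x and 6x over background at -63.2 and +48.4 kb, b = 0.5 places those
  fragments at ~3x and ~2.3x the proximal fragment, the regime the loop
  caller's two thresholds are designed around. A steeper decay (b = 1)
  would put a 9x loop at 63 kb *below* the proximal signal and make the
  fold-over-proximal criterion unsatisfiable.
* **Loops** multiply the decay curve, making "x-fold over background" the
  direct generator parameter.
* **Cq noise** is additive Gaussian (sd 0.15 for 3C/ChIP/digestion wells,
  0.12 for expression), replicates 3, normalizer drawn once per plate.
  No replicate dispersion is published for data of this kind, so these
  are tuning choices at the level of careful plate work, fixed once in
  the preset files.
* **Presets**: `pc3m` (loops 9x/6x; expression folds 4.5/3.0; ChIP 30x/60x;
  ddPCR ratio 2.5), `pc3` (one loop 9x; folds 2.0; ChIP 5x/3x; ratio 1.4),
  `fibroblast` (no loops, flat ChIP), `null` (all effects at 1, with a
  test sample carried through every assay).

What the generator does **not** emulate: fragment-level GC or mappability
bias, PCR efficiency differences between assays, ligation-side asymmetry,
inter-library batch structure beyond a scalar loading shift, or droplet
rain. Passing tests therefore demonstrate that the estimators recover
their targets under idealized, well-calibrated noise — not that the
pipeline is robust to every artifact of real plates.

## Problem sizes

Monte-Carlo checks use 20 seeds for effect-size recovery (matching the
reporting convention of two to four independent experiments averaged over
triplicates), 100 seeds for pass-rate and significance-pattern checks,
and 200 seeds for loop-caller sensitivity/specificity; the Poisson
coverage check uses 1000 wells. These sizes give standard errors well
inside the asserted tolerances while keeping the whole suite fast.

## Known limitations

* The background model is symmetric in |distance|; with only 7 anchors a
  two-sided fit is underdetermined (a config flag exists but is off).
* With ~7 points the iterative exclusion is a small-sample heuristic:
  roughly 1 loopless profile in 10 loses a point to it (harmless for
  calling, since thresholds are far above the null), and its calibration
  degrades below ~6 anchors.
* ChIP significance with 2 experiments has very low power; a true 3-fold
  enrichment is non-significant in a fifth of runs. Bounds-style claims
  (fold estimates) are the reliable readout at that n.
* The ddCt confidence interval treats replicates as biological; with
  technical triplicates it understates biological uncertainty.
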