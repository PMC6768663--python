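# Methods

## The generative model of the screen

The simulator reproduces the statistical structure of the in utero pooled
screen, not its spatial biology. Per embryo:

1. **Transduction.** The number of transduced founders is
   Binomial(*N*, *r*) with *N* = 120,000 surface progenitors and
   *r* = 0.15. MOI is exactly 0 or 1: each founder carries a single hairpin
   drawn uniformly from the library (the low-titer injection is designed to
   make multiple integrations negligible).
2. **Fate.** Each transduced founder independently becomes a hair-follicle
   (HF) founder with probability 0.10, otherwise remains interfollicular
   epidermis (EPI). No placode clustering or spatial correlation is
   modeled.
3. **Clonal expansion.** A founder's clone size at E18.5 is negative
   binomial with mean 40 · *e*(gene, fraction) and shape *k* = 5, where
   *e* is the knockdown's multiplicative fitness effect in that fraction
   (1.0 = neutral, 0.25 = 4-fold depletion; scrambled hairpins are neutral
   by definition). The sum over *f* founders of one hairpin is drawn in one
   shot as NB(*f·k*, ·), which is exact for i.i.d. negative binomials with
   a shared success probability. Only the ~40-cell mean is an empirical
   quantity; the dispersion *k* = 5 (per-clone CV ≈ 0.47) encodes the
   well-known overdispersion of clone sizes in developing epithelia and is
   a configuration knob — the hit-calling statistics must be robust to it.
   EPI and HF founders expand with the same law; the data do not
   distinguish fraction-specific expansion for neutral hairpins.
4. **Pooling and sequencing.** Cell tallies from 60 embryos are pooled per
   biological replicate (3 replicates), multiplied by a per-hairpin gamma
   amplification factor with mean 1 and shape 50 (CV ≈ 14%, the scale of
   jackpotting expected from a validated ~28-cycle amplicon protocol), and
   sampled to a fixed depth by a multinomial draw. The default depth,
   2·10⁶ reads/sample (~2,000 reads per hairpin), matches deep pooled-screen
   practice. The t0 in vitro sample is sequenced the same way from a
   uniform library representation.

All randomness flows from a single integer seed through one
`numpy.random.Generator`, so simulated screens are bit-reproducible.

The screen's published description also quotes a "~4,000-fold" E18.5
representation; that figure is not derivable from the other stated
quantities (120,000 × 0.15 × 40 / 999 ≈ 720), so the simulator reports the
representation it actually achieved in its ground-truth record and asserts
nothing about it.

The two-color competition assay reuses steps 1–3 with two viruses mixed
1:1 (each founder GFP-scrambled or RFP-test with probability ½) and reports
per embryo and fraction (final RFP/GFP cells)/(initial RFP/GFP founders).
Embryo-fractions with zero reference (GFP) cells are excluded with a
warning rather than imputed.

### What the simulator does *not* capture

Spatial structure (placode fields, follicle waves), founder-fate
correlations between neighboring cells, dispase separation errors between
fractions, sequencing errors within reads (emitted FASTQ reads are exact),
and library-representation skew at t0 (uniform by default). Passing
recovery and FDR tests therefore demonstrate the statistics behave
correctly under the screen's sampling noise, not that any given biological
screen meets its assumptions.

## Fold change and hit calling

Counts are converted to counts-per-million before adding the pseudocount
(0.5), which makes every downstream number exactly invariant to per-sample
depth rescaling; the pseudocount keeps fold changes finite for E18.5
dropouts, which are retained as biological depletions (only hairpins with
zero reads across *all* samples are discarded). Fold changes are centred
on the median (not mean — robust to individual outlier controls) of the
scrambled hairpins per sample, making the scrambled median identically
zero.

Per-hairpin significance uses a row-wise two-tailed two-sample t-test of
the hairpin's replicate log₂FC values against the pooled scrambled
replicate values of the same fraction, then Benjamini–Hochberg step-up
adjustment within the fraction. A one-sample alternative (replicates vs 0,
df = n−1) is available behind `mode="one_sample"`, but it is not the
default for a concrete reason discovered during development: with
triplicates its t statistics have 2 degrees of freedom, whose heavy-tailed
null caps attainable p-values near 10⁻³; BH across ~10³ hairpins then
cannot certify even an unambiguous 4-fold depletion (measured q ≈ 0.23 for
p ≈ 10⁻³) unless dozens of genes move together. The two-group reading —
which is also what row-wise "multiple t-test" analyses in common
statistics packages perform, comparing each hairpin against the scrambled
reference it is normalized to — restores the degrees of freedom the
published screen's candidate yield implies.

A supporting hairpin must satisfy |mean log₂FC| ≥ log₂(2), raw p < 0.05
**and** q < 0.10 (the conjunction is the stricter reading of the two
published thresholds; both are parameters). A gene needs ≥2 supporters in
one direction and no ≥2-fold hairpin in the other. "HF-specific" genes are
HF calls whose gene-mean |log₂FC| in EPI is below 1.0 log₂ units (within
two-fold — "not dramatically selected" made operational; parameter
`epi_neutrality_threshold`).

Degenerate inputs: zero replicate variance with zero mean yields p = 1;
with nonzero mean, p is set to the smallest positive float with a warning.
A constant replicate vector makes Spearman correlation undefined (NaN,
warned) rather than silently 0 or 1.

## Coverage design

`min_embryos_for_coverage` is the ceiling of
library × coverage / (progenitors × HF-fraction × transduction). It is
deliberately deterministic arithmetic — the screen's own sizing logic —
not a stochastic power analysis; the simulator exists for the latter.

## Morphometrics

- **Angles** are degrees; the anterior–posterior axis is 0°,
  counterclockwise positive. Follicle orientations live in (−180, 180]
  with right-closed histogram bins (so −170° and +170° sit in the two bins
  adjacent across the wrap); polarity axes are non-directional and live in
  (−90, 90].
- **Polarity detection** operationalizes "two opposing cortical domains":
  peaks found on the circularly tiled profile with relative prominence
  ≥ 0.2 of the dynamic range, the two tallest required to be 180° ± 30°
  apart (both tolerances are parameters of `PolarityParams`). The polarity
  *angle* is the doubled-angle (orientation-tensor) mean of the
  above-median signal, which is exactly rotation-covariant and degrades
  gracefully under noise (±5° recovery at SNR ≈ 20 in the tests).
- **Perpendicular vs angled follicles:** within 15° of the skin normal
  (inclusive), threshold exposed; the published analysis states no cutoff.
- **Line profiles** are rescaled to [0, 1] per cell and averaged into 20
  equal-width bins; with balanced sampling the global mean is preserved
  exactly and a 20-sample profile is a fixed point.
- **Masks:** connected components use 8-connectivity; the focal-adhesion
  size filter is inclusive at 0.3 µm² (the published range is "0.3 ≤ ∞").
  Segmentation is an input; synthetic Voronoi fields, ellipse masks and
  von Mises cortical profiles generate all test inputs with known truth.

## BioID filter

Detection is count > 0; a protein passes with ≥2 of 3 bait replicates and
0 control detections (both thresholds parameters). Because "frequency" for
the interactome cloud is ambiguous between spectral counts and replicate
counts, both normalizations are reported. Output order (descending count,
then protein id) is fixed for determinism.

## Problem sizes in the validation suite

The unit suite runs scaled-down simulations (3,000–5,000 progenitors, 5–6
embryos/replicate) where only correctness of the plumbing is at stake, and
full study-scale simulations (999 hairpins, 120,000 progenitors, 60
embryos × 3 replicates) where operating characteristics are: 50 null
screens for FDR control, 20 seeds × 10 planted genes for recovery, 20
seeds for Venn-class recovery, 50 embryos for competition neutrality.
These sizes give Monte-Carlo error comfortably below the asserted margins
while keeping the whole suite under a minute.

## Known limitations

- The simulator's t0 is uniform; real plasmid pools are log-normal-ish
  skewed. Skew would widen per-hairpin count variance at fixed depth but
  is absorbed by the t0-ratio normalization in expectation.
- The vs-scrambled t-test treats the 3×20 scrambled replicate values as
  exchangeable draws of the null fold-change distribution; hairpin-level
  dependence within a replicate (shared embryo pool) is ignored, as it is
  in the published analysis.
- The competition ratio normalizes to realized founder counts, not the
  nominal 1:1 mix; with few founders the ratio of sums is slightly
  Jensen-biased upward (≪ its SEM at ≥50 embryos).
- Gene-call counts from any single simulated screen are not comparable to
  the published candidate tallies: the raw screen sequencing was never
  deposited, and the published effect-size spectrum is unknown.
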