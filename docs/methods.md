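# Methods

This note documents the models behind each analysis stage and each synthetic
generator, the parameters that matter (units, defaults, rationale), the
numerical choices, and what the synthetic experiments do and do not show
about real data.

## EV miRNA count analysis

### Model of the assay

Hybridization digital counters report, per sample (lane), one nonnegative
count per probe. Three probe classes are carried through the pipeline:
endogenous miRNA probes, positive-control probes (a ladder of synthetic
spike-in RNAs at fixed input, so their counts reflect only the lane's
technical efficiency), and negative-control probes (no-target probes
measuring non-specific background).

Counting noise is overdispersed; we model it as negative binomial with
variance m + φ·m² (dispersion φ, default 0.05, a typical value for
technical-plus-pipetting variability at moderate counts; φ = 0 degenerates
to exactly deterministic means, which the exactness tests exploit).

### Normalization

* **Spike-in scaling.** Each sample is multiplied by
  (geometric mean over samples of positive-control sums)/(its own
  positive-control sum). The geometric mean is the standard choice for
  multiplicative lane factors; an arithmetic-mean variant would be biased by
  high-factor lanes. After scaling, positive-control sums are equal across
  samples by construction. A sample with zero positive-control counts is a
  hard error naming the sample (it cannot be rescued).
* **Quantile normalization.** Endogenous probes only (controls are
  technical, not cargo, and would distort the reference distribution).
  Every sample's sorted endogenous values are replaced by the per-rank
  cross-sample means; ties within a sample receive the mean of the tied
  ranks' reference values — deterministic and order-independent.

### Fold change and enrichment

Fold change per miRNA is the ratio of per-condition means over replicate
samples against the designated baseline condition (means, not medians, are
the default; medians are available via `stat="median"`). A pseudocount of
0.5 is added to numerator and denominator only when the baseline mean is
exactly zero. Cargo is *enriched* at FC ≥ threshold with the boundary
included (threshold default 1.5). Enrichment calling is antitone in the
threshold by construction.

### What quantile normalization can and cannot preserve

Two intrinsic properties of quantile normalization shaped the synthetic
design and are worth knowing when interpreting real data:

* **Rank saturation.** A probe that is already rank-maximal in its sample
  keeps that rank when its abundance doubles, so quantile normalization maps
  it back onto the same reference value: enrichment of the single most
  abundant species is *invisible* after quantile normalization. The
  generator therefore draws enriched cargo from a mid-abundance band
  (baseline means 100–5000) inside a panel spanning 50–20000, leaving rank
  headroom.
* **Compression.** When only a minority of samples carry a shifted
  distribution, the per-rank reference mixes shifted and unshifted samples
  and compresses the realized fold change by a stable factor of ≈ 0.94
  (worst ≈ 0.90 in our conditions). A planted FC of 2.0 is observed as
  ≈ 1.8–1.9 after normalization. The enrichment threshold of 1.5 still
  separates planted from null cargo, but the margin is narrower than the
  raw fold change suggests.

### Replicate counts

The recovery experiments use 36 replicate samples per condition (three
12-lane cartridges). This follows from a power calculation: with φ = 0.05
the per-count CV is ≈ 0.224, so the SE of the log fold change of n-replicate
means is 0.224·√(2/n); requiring the worst-case compressed planted effect
(log 1.8 vs the log 1.5 cutoff) to sit ≥ 3.4 SE above threshold — so that
an exact 20-of-20 planted-set recovery succeeds in ≫ 95% of runs — gives
n = 36. The demonstration pipeline plants a typical enrichment magnitude of
FC 2.5 and runs with 24 replicates, where recovery is essentially
deterministic.

### Detection and clustering

A miRNA is *detected* when its normalized count exceeds the within-sample
negative-control mean + 2 SD in at least one sample; the multiplier and an
optional absolute floor are configurable and recorded in output metadata.
Heatmap clustering operates on log2(per-condition median of normalized
counts + 1), agglomerative with Euclidean distance and complete linkage
(both configurable); a single row yields a degenerate single-leaf tree
rather than an error.

### ΔΔCt

Relative expression is 2^−ΔΔCt with ΔCt = Ct(target) − Ct(housekeeping) per
sample, averaged within group, and ΔΔCt = ΔCt(treated) − ΔCt(calibrator).
The Ct generator encodes a planted fold change as a −log2(FC) cycle shift in
the treated group over a constant housekeeping target, so at zero noise the
closed form returns the planted value exactly.

## Seed-site scanning

Site taxonomy (mature miRNA given 5′→3′, UTR scanned on its sense strand
only, U ≡ T, ambiguity codes rejected):

| type | UTR content (5′→3′) |
|---|---|
| 6mer | revcomp(miRNA nt 2–7) |
| 7mer-m8 | revcomp(miRNA nt 2–8) |
| 7mer-A1 | revcomp(nt 2–7) + A |
| 8mer | revcomp(nt 2–8) + A |

The A of the A1 position is a literal adenosine regardless of miRNA
position 1 (the standard convention — A at target position 1 is recognized
by the silencing complex, not by pairing). Each seed-core hexamer match
yields exactly one site of the longest applicable type ("longest type
wins"). Coordinates are 0-based half-open.

`disrupt_site` models reporter-assay binding-site mutants: n (default 2)
transversions (A↔C, G↔T) at seed-core positions chosen center-outward
(seed-shufflable), verified when the miRNA is supplied by rescanning —
no site of any type may overlap the original footprint; alternative
position subsets are tried until that holds. Sequence length is always
preserved and exactly n characters change.

The UTR generator writes exact site strings into a random background and
then patches the background (transversions outside planted footprints)
until scanning reports exactly the planted sites — including guarding the
flanks of sub-8mer sites so they are not accidentally upgraded — and, for
miRNAs listed as screen-only, no site at all.

## MEA analysis

### Signal chain

* **Filter**: Butterworth, order 2, 200 Hz cutoff. High-pass is the
  appropriate direction for extracellular spike detection (a 200 Hz
  low-pass would discard spike energy); low-pass remains available in the
  config. Zero-phase forward–backward application is the default so spike
  peak timing is preserved; this squares the magnitude response (doubles
  attenuation in dB), which the tests account for. Single-pass causal
  filtering matches the analytic response (f/fc)²/√(1+(f/fc)⁴) to < 0.1%.
* **Noise**: robust estimator median(|x|)/0.6745 by default — the plain SD
  is inflated by the spikes themselves; both are available and the method
  is recorded.
* **Spikes**: absolute-value crossings of k·σ̂ (k = 5); event time is the
  first suprathreshold sample; a 1 ms dead time prevents one biphasic
  waveform from counting twice (negative-only thresholding is available).
  On pure Gaussian noise at 25 kHz this yields ≈ 0.9 false events/min,
  comfortably below 2/min.
* **Bursts**: maximal runs of ≥ 4 spikes with all consecutive ISIs
  ≤ 100 ms (boundary inclusive).
* **QC**: an electrode is analyzed only if baseline noise < 50 µV (as the
  SD-like noise estimate; a peak-to-peak variant would simply rescale the
  criterion) and the baseline epoch shows spontaneous activity
  (≥ 0.1 spikes/s).
* **Normalization**: per electrode, spike rate (spikes/s) and burst rate
  (bursts/min) per epoch; percent of baseline = 100·post/pre per measure,
  undefined (flagged, excluded from normalized statistics) when the pre
  rate is zero. Paired two-sided t-tests compare per-electrode pre vs post
  rates; degenerate difference vectors (all zero, or constant shift) are
  reported as such rather than raised.

### Trace generator

Traces are Gaussian noise (default σ = 5 µV) plus a biphasic
(negative-then-positive) 1 ms waveform — one full sine cycle — inserted at
each true spike time with absolute peak amplitude expressed in noise SDs
(default 10). Background spikes are homogeneous Poisson (default 2/s);
bursts are clusters of 4–8 spikes with intra-burst ISIs uniform in
[20, 50] ms, placed with ≥ 0.5 s of quiescence between burst windows so
that distinct bursts remain distinct under the 100 ms chaining rule.
Spikes closer than the detector dead time are dropped from the truth, and
burst windows are re-validated after merging. Treatment epochs are derived
from a baseline truth by count-deterministic scaling: thinning for
suppression, insertion of extra bursts/background spikes for potentiation.

Demonstration conditions: 8 electrodes, two 120 s epochs at 25 kHz; the
post epoch plants spike/burst rates at 54.85%/37.41% of baseline for the
cytokine-EV-like condition and 132.9%/140.9% for the control-like condition.

### What the synthetic traces do not model

No spike-waveform diversity or unit overlap (no sorting is attempted), no
electrode drift, no correlated or non-Gaussian noise, no network-level
synchrony across electrodes. Passing recovery tests therefore validate the
detection/clustering/normalization logic, not robustness to real recording
artifacts.

## Group statistics

One-way fixed-effects ANOVA is computed from the closed-form
sums-of-squares decomposition (SS_total = SS_between + SS_within is asserted
to 1e-10) with the p-value from the F distribution; all-constant input is
flagged degenerate rather than raised. Tukey's HSD uses the
studentized-range distribution with the Tukey–Kramer harmonic-mean standard
error, so groups of unequal size (e.g. 15–20 neurons per condition) are
handled; at k = 2 the adjusted p equals the pooled two-sample t-test p
(verified to ~1e-14). No normality pre-tests are run — the analysis mirrors
the ANOVA + Tukey design it supports.

## Reproducibility machinery

A single master seed fans out to per-stage seeds through a counter-based
`numpy.random.SeedSequence` derivation (all derived seeds < 2³¹), so each
stage is independently reproducible and the demo report is byte-identical
across runs with the same seed. Every simulator validates its truth
object's invariants before returning, and every demo run writes its fully
resolved configuration and JSON truth sidecars next to the data files.

## Known limitations

* The enrichment rule is the fold-change threshold itself — no count-model
  differential testing, no multiplicity control; that is the design being
  implemented, not a recommendation.
* Quantile normalization's rank-saturation and compression effects (above)
  mean recovered fold changes understate planted ones; conclusions should
  rest on the threshold rule, not the FC magnitudes.
* Seed scanning is purely pattern-based: no conservation filtering, no
  thermodynamic or context scoring, no 3′-supplementary pairing, and no
  quantitative repression prediction.
* The burst definition is the consecutive-ISI chaining rule; other
  definitions (e.g. rate-surprise methods) will disagree on edge cases.
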