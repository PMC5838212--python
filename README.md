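# evcargo

Analysis toolkit for a recurring experimental design in glia–neuron
communication studies: do inflammatory stimuli change the **miRNA cargo of
astrocyte-derived extracellular vesicles (ADEVs)**, and does that altered
cargo **dampen neuronal network activity**?

The package implements the complete computational chain of such a study, and
pairs every stage with a synthetic-data generator that plants known ground
truth, so the whole pipeline is testable end to end without any external
data:

1. **EV miRNA cargo profiling** (`evcargo.counts`) — hybridization-counter
   (NanoString nCounter–style) count matrices: positive-control spike-in
   normalization, quantile normalization, per-condition fold change against
   the constitutive-release baseline, enrichment calling at ≥ 1.5-fold
   (inclusive), detection above negative-control background, hierarchical
   clustering of log2 per-condition median counts, and 2^−ΔΔCt qRT-PCR
   validation.
2. **miRNA target-site scanning** (`evcargo.seedscan`) — canonical seed
   sites (6mer, 7mer-A1, 7mer-m8, 8mer; longest type wins) on 3′-UTRs, and
   the 2-nucleotide site-disruption mutants used in luciferase reporter
   assays.
3. **MEA electrophysiology** (`evcargo.mea`) — 2nd-order Butterworth
   high-pass filtering (200 Hz), spike detection at 5 × noise SD with a
   robust (median/0.6745) noise estimator, burst clustering (≥ 4 spikes with
   consecutive inter-spike intervals ≤ 100 ms), electrode QC (< 50 µV noise,
   spontaneous activity), 0.2 s raster binning, percent-of-baseline
   normalization of post- vs pre-treatment rates, and paired t-tests.
4. **Group statistics** (`evcargo.groupstats`) — one-way ANOVA with Tukey
   (Tukey–Kramer) post hoc comparisons for per-neuron morphometrics.
5. **Synthetic data** (`evcargo.simulate`) — negative-binomial count
   matrices with planted condition-specific fold changes and control probes;
   extracellular voltage traces (Gaussian noise + biphasic ~1 ms waveforms)
   with known spike times and burst windows; Ct tables with planted fold
   changes; screened UTRs with planted seed sites.

## The statistics at the core

*Enrichment rule.* After scaling each sample by
g(Σpos)/Σpos_s (g = geometric mean over samples of positive-control sums)
and quantile-normalizing endogenous probes, cargo miRNA *m* is enriched in
stimulus condition *c* when

&nbsp;&nbsp;&nbsp;&nbsp;FC(m, c) = x̄(m, c) / x̄(m, baseline) ≥ 1.5,

with means over replicate samples and a 0.5 pseudocount only when the
baseline mean is zero.

*Spike/burst rule.* On the filtered trace x(t), spikes are threshold
crossings |x| ≥ k·σ̂ (k = 5, σ̂ = median(|x|)/0.6745, 1 ms dead time); bursts
are maximal runs of ≥ 4 spikes whose consecutive ISIs are all ≤ 100 ms;
activity is summarized as 100 · rate_post / rate_pre per electrode.

*ΔΔCt.* Relative expression = 2^−ΔΔCt with
ΔCt = Ct(target) − Ct(housekeeping) averaged within group and
ΔΔCt = ΔCt(treated) − ΔCt(calibrator).

## Worked example

```bash
evcargo demo --seed 1 --out demo_out
```

generates every input modality with known truth, runs every stage, and
prints a recovery report. With seed 1:

```
"counts":  n_detected = 131; enriched_counts = {ADEV-ATP: 7, ADEV-IL-1b: 10,
           ADEV-TNFa: 15}; false_positives/negatives: none    -> PASS
"mea":     mean spike %-of-baseline = 54.86  (planted 54.85)
           mean burst %-of-baseline = 37.27  (planted 37.41)
           paired t(7) = -40.75, p = 1.4e-09                  -> PASS
"ddct":    recovered {let-7f: 3.0, miR-125a-5p: 2.5, miR-16: 2.0}
           = planted                                          -> PASS
"seed_scan": 3 planted sites found, all abolished by 2-nt mutants -> PASS
```

Reading the counts block: of a 131-miRNA panel, all 131 are detected above
negative-control background, and the ≥ 1.5-fold rule recovers exactly the
7 / 10 / 15 miRNAs planted as enriched in the ATP / IL-1β / TNFα conditions
versus the constitutive-release baseline — zero false calls. The MEA block
shows the planted post-treatment suppression of spiking (to ~55% of
baseline) and bursting (to ~37%) recovered from raw voltage traces by the
full filter → detect → QC → normalize chain.

Each stage is also exposed directly, e.g.:

```bash
evcargo cargo enrich --counts counts.tsv --conditions conditions.yaml \
    --baseline ADEV-CR --threshold 1.5 --out enriched.tsv
evcargo targets scan --utrs utrs.fasta --mirnas mirnas.fasta --out sites.tsv
evcargo mea analyze --pre pre.h5 --post post.h5 --k 5 --cutoff 200 --out mea/
evcargo stats anova --data morphometrics.csv --out tukey.csv
```

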