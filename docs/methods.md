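# Methods

This note documents the models, parameter choices and numerical decisions
behind each stage of the pipeline, what the synthetic-data generator does
and does not emulate, and the known limitations.

## Data model

All times are seconds. Intervals are half-open `[start, end)`; frame `i`
of a raster covers `[i/rate, (i+1)/rate)`. Hypnograms are read on a fixed
5-s epoch grid (the scoring resolution); misaligned bounds are rejected
rather than rounded, so scoring errors surface instead of shifting
silently. Text formats round-trip to 9 significant digits; spike times
that collide at that precision are deduplicated on read to preserve the
strictly-ascending invariant.

Extended state bouts are maximal runs of one state in which every
contiguous interruption by other states is < 30 s, kept when the merged
span is ≥ 5 min. An interruption is the full non-target time between two
target intervals regardless of how it is labeled, which makes bout
extraction invariant to splitting hypnogram intervals into same-label
pieces.

Band-pass filtering is a zero-phase forward-backward 4th-order Butterworth
(`sosfiltfilt`), chosen so that event *times* are not phase-shifted; the
effective magnitude response is the filter's squared.

## Anesthetic-depth staging

Burst suppression is treated as a two-regime process observed through
three per-500-ms-bin features: max |v|, SD, and the bin's score on the
first principal axis of the per-bin 1–100 Hz periodograms. The strictly
positive amplitude features are log-transformed (their two regimes are
lognormal); the spectral score can be negative and is standardized
instead. A single joint two-component full-covariance Gaussian mixture is
fit on the 3-vectors — the three features inform one binary decision, so a
joint fit is used rather than per-feature votes. Initialization is a
deterministic median split on log SD (means, covariances and weights of
the two halves seed EM), so classification involves no randomness; the
component with the larger mean log SD is *burst*. A zero-value guard
`log(x + ε)` uses ε = 1e-12 × the largest bin SD. If every feature vector
is identical no mixture exists: all bins are labeled burst and a warning
is raised.

Burst merging follows the printed order: runs of burst separated by < 2 s
of suppression are merged first, then merged bursts lasting ≤ 2 s are
relabeled suppression. The result always partitions the analyzed span and
is a fixed point of re-application.

BSR and relative delta power use coarse bins of 52.428 s (2¹⁹ samples at
10 kHz; configurable). PSDs are averaged periodograms with 1-s segments
and 50% overlap (the estimator is otherwise unconstrained); band powers
are trapezoid-integrated. Relative delta power is z-scored across the
recording's coarse bins and min-max mapped to [0, 1] — per recording, not
per cohort, so a session is stageable in isolation. A constant series maps
to 0.5.

Staging applies the strict per-bin rules (deep iff 0.3 < BSR < 0.8;
moderate iff BSR < 0.3 and relative delta > 0.5; BSR exactly at a boundary
is not deep), then per label merges epochs across gaps < 60 s and keeps
epochs > 60 s. Because a coarse bin is 52.428 s, single-bin epochs never
survive. If a merged deep epoch overlaps a merged moderate epoch the deep
label wins (the deeper state is the conservative call); remaining time is
*unclassified*.

## Epileptiform event detection

The trace is z-scored by its whole-recording mean and SD, making detection
exactly invariant to positive rescaling. Candidates are samples with
|z| > 10; a candidate becomes an event when max − min of z within a 30-ms
window *centered* on the crossing (alignment is a package choice) exceeds
10. The event time is the sample of largest |z| in the window, and a 50-ms
dead time anchored at that extremum suppresses later candidates. Manual
post-approval of events is replaced by reporting per-event peak-to-peak
amplitudes and an optional minimum peak-to-peak override. Event rates per
minute can be computed against any labeled epoch set (e.g. deep-anesthesia
epochs).

## Single-unit and MEA statistics

Unit QC requires, jointly: ISI-violation fraction < 0.005, isolation
distance > 10 (consumed as sorter metadata, not recomputed), active-wake
MFR > 0.05 Hz, and rate stability. The stability rule is a package
decision (the criterion is cited without a formula upstream): the
recording span `[0, max(last spike, last bout end))` is split into three
equal spans and a unit is excluded when any span's MFR deviates more than
30% from its overall MFR — the same 30% bound used for MEA baselines; the
threshold is configurable. Exclusion reasons enumerate *all* failed
criteria.

The gain factor is computed exactly as printed, `(a − b)/max(|a|,|b|) × 100`
with a the NREM and b the wake MFR; it is antisymmetric and bounded by
±100, and undefined only at a = b = 0. The median split on wake MFR
assigns ties to `below_median` (the subgroups are defined as below/above
the median; equality is otherwise unassigned). Subgroup medians carry
bootstrap percentile 95% CIs (B = 10,000, seeded; the CI method upstream
is unnamed).

MEA normalization excludes a channel when any baseline point deviates
> 30% from that channel's baseline mean, then rescales included channels
so the baseline mean is exactly 100%. Threshold spike detection finds
negative-going crossings of mean − k·SD (k = 5.5, within the conventional
5–6 SD band) with a 1-ms dead time, and expects a ≥ 200 Hz high-passed
trace.

## Calcium raster analytics

mCaR is a cell's summed inferred event amplitudes divided by recording
time. "Active" cells are those with rate strictly above a threshold
(default 0 — any inferred event counts; configurable). Total activity is
Nₐ × *median* mCaR; the mean is offered as an option. Relative
synchronization is (cells with ≥ 1 event)/(total cells) per 100-ms bin;
the bin must be an integer multiple of the frame interval.

Network bursts are contiguous supra-threshold runs of the sync vector:
one burst per run, its peak the earliest maximal bin. The threshold is the
session's own 90th sync percentile (exploration) or the absolute value
0.05 (anesthesia), applied strictly. Defining the burst as the whole run
(rather than one burst per interior local maximum) keeps burst extents
disjoint with each containing its peak, which the per-burst cell and event
counts require. Per burst we report distinct active cells and the summed
event amplitudes over the extent (a binarized count is an option — whether
"spikes per burst" counts events or sums amplitudes is underdetermined),
inter-peak intervals, and a seeded subsample of min(20, n) bursts for
pooled analyses.

## Microstate clustering

Frames with ≥ 2 co-active cells enter the analysis. PCA denoising keeps
components whose explained-variance share (the discrete derivative of the
cumulative explained variance) reaches the 30th percentile of all shares —
with ≥ rather than > so that exactly tied shares are retained rather than
discarded wholesale. t-SNE runs 1000 iterations with PCA initialization
and a fixed seed; the perplexity rule is ⌊√N⌋, the standard heuristic
(the exact upstream rule is unrecoverable), configurable and recorded.

The density map is a 256×256 histogram over the bounding box plus a 5%
margin, smoothed with a Gaussian kernel of σ = (largest map coordinate)/60.
The map lives in positive (shifted) coordinates — a density image requires
a positive frame — so this is 1/60 of the bounding-box extent. Watershed
basins of the inverted density, seeded at its regional maxima, tile the
grid with no ridge lines, so every frame receives exactly one label;
`n_microstates` counts regions containing at least one frame. If all
embedded coordinates coincide the result is a single microstate with a
warning.

The randomization null reassigns each frame's positive amplitudes (in
cell order) to a uniformly drawn cell subset of the same size, preserving
per-frame co-activation counts exactly; a frame with all cells active is
unchanged. Note the direction this control produces: recurring patterns
compress many frames into a few dense embedding islands, whereas permuted
frames — all distinct — scatter, and a fixed-bandwidth kernel density of
scattered points carries many sample-fluctuation modes. Structured data
therefore yields *far fewer* microstates than its permutation (roughly an
order of magnitude under the default generator conditions), and the
meaningful null statistic is that gap. Relatedly, an isolated frame in a
sparse region of the embedding forms its own region: a diffuse cloud does
not collapse to one microstate at this kernel scale.

Cluster quality reports mean pairwise Pearson correlation of post-PCA
frame vectors within clusters (intra) and across clusters (inter)
separately — the aggregation into a single score is underdetermined, so
both raw values are returned. Validation clusterings: affinity propagation
on the frame-correlation similarity with convergence window 10 and
preference = median off-diagonal similarity (non-convergence raises,
reporting the iteration count), and agglomerative weighted (WPGMA) linkage
on correlation distance 1 − r cut at 0.75.

## Synthetic-data generator

One global seed expands into per-generator substreams by CRC-hashing the
generator name, so adding a generator never perturbs another's draws.
Defaults define the study conditions used throughout the tests:

- **LFP** (1 kHz): wake = 1/f background (SD 0.05 mV) + 6–9 Hz theta
  (0.04 mV) with high EMG RMS; NREM/moderate = 1/f background + 1–4 Hz
  delta (0.15 mV) with low EMG; deep = 1–50 Hz band-limited noise whose SD
  envelope alternates burst (0.2 mV) and suppression (0.02 mV) — a 10:1
  ratio, comfortably above the ~8:1 needed for the classifier's features
  to separate. Segment durations are shifted exponentials (minimum 2.5 s,
  mean 5 s each), so ground truth cannot be re-written by the classifier's
  own 2-s merge rule and the long-run suppression fraction is 0.5.
  Amplitude scales per state are free parameters (no quantitative scales
  are published); only their ordering matters to the analyses.
  Epileptiform transients are biphasic (positive then negative lobe,
  20 ms), amplitude expressed in SDs of the generated background, placed
  uniformly with a minimum spacing (default 100 ms) and recorded at the
  positive-lobe peak.
- **Spike trains**: base rates lognormal (default median 1.4 Hz, σ = 1);
  units fire as inhomogeneous Poisson processes at base rate in wake and
  base × multiplier in NREM. Presets draw multipliers with lognormal
  jitter (σ = 0.10) around 0.79 for above-median units (WT-like, implied
  median gain −21%) or around 1/0.88 for below-median units (APP-like,
  +12%), the other subgroup around 1.0. The drawn multipliers and implied
  gains are the ground truth.
- **Rasters** (10 Hz): background Bernoulli activation per cell-frame
  (default 0.003 under the motif conditions), motif frames activate a
  fixed cell subset (default 8 motifs × 12 of 100 cells, motif rate 0.2
  per frame over 3000 frames), scheduled bursts activate a drawn fraction
  of all cells in their 100-ms bin; amplitudes are lognormal.
- **MEA**: hourly channel MFRs = lognormal baseline × profile ×
  multiplicative noise (σ = 0.02); a perturbation drops the profile to its
  immediate fraction at onset with optional exponential recovery;
  designated unstable channels swing ±40% during the baseline.

The generator reproduces the *statistical structure the analyses assume* —
spectral signatures, burst-suppression alternation, lognormal rates with
multiplicative state gains, motif recurrence, scheduled synchrony — and
deliberately not biophysics: no conductance models, no raw fluorescence
(rasters are generated at the inferred-event level, downstream of source
extraction), no electrode artifacts, no non-stationary drift in rates, no
behavioral covariates. Passing tests therefore certify the analysis chain
against data satisfying its assumptions, not robustness to the artifacts
of real recordings.

## Problem sizes and determinism

The test suite runs on desk-scale problems chosen to keep the full suite
in minutes while leaving comfortable statistical margins: 10-min LFP
sessions (1.2k classified bins), 200-unit / 30-min-per-state spike
simulations, 3000-frame rasters (~700 active frames), 20-seed coverage
runs for the bootstrap CI and 10-seed runs for the permutation null.
Every stochastic step (generators, bootstrap, t-SNE, burst subsampling)
is seeded and reproducible bit-for-bit under a fixed seed.

## Known limitations

- The mixture classifier assumes both regimes are present in the record;
  a recording that is entirely burst or entirely suppression will still be
  split into two clusters unless the features are exactly degenerate.
  Staging mitigates this downstream (BSR near 0 or 1 is not "deep").
- Bins straddling a burst/suppression boundary are intrinsically
  ambiguous; they bound attainable bin accuracy a little below 100%.
- The epileptiform detector's whole-recording z-score assumes transients
  are rare; a trace dominated by events would inflate the SD and raise the
  effective threshold.
- The microstate count depends on the kernel-to-structure scale ratio as
  discussed above; comparing counts across sessions is only meaningful at
  matched numbers of active frames.
- Isolation distance is trusted from the sorter; no spike-sorting QC is
  recomputed here.
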