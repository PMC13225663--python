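# Methods

## Generative model

Each simulated neuron is a Gaussian tuning curve over equally sized spatial
bins, plus a constant baseline and additive per-bin Gaussian noise:

```
F(x)   = A·exp(−(x−μ)²/(2σ²))            field term (Hz)
G(x)   = F(x) + B₀ + N(x),  N ~ 𝒩(0,σₙ²)  per-trial rate (Hz)
```

In 2D the field is an isotropic Gaussian on a grid (10×10 by default) with
one σ shared across both dimensions; the grid is stored flattened
row-major, which is lossless for both statistics because they treat bins as
unordered categories. Trial-level variability enters two ways: the field
centre is jittered per trial by an offset drawn from U[0, jitter_max]
(offsets as printed, one direction; a symmetric U[−j, j] mode is also
provided and recorded in each matrix's provenance), and a presence ratio
p ∈ [0, 1] silences the field on a Bernoulli(1−p) subset of trials, leaving
baseline plus noise only. Noise is drawn on every trial regardless of
presence.

**Clipping.** Gaussian noise can drive rates negative; rates are physical,
so matrices are clipped at 0 before any metric. Clipping inflates the mean
of low-rate bins by at most σₙ·φ(B₀/σₙ) (≈0.08 Hz at B₀ = σₙ = 1), which
matters only for exact-convergence oracles; `simulate_trials(clip=False)`
exists for those tests. Jittered/broad fields are evaluated on the fixed
bin grid and therefore truncate at the track edges (linear tracks have
walls; no wrap-around).

**Parameters and defaults.** Sweeps vary one parameter and hold the rest at
A = 10 Hz, μ = centre bin, σ = 5 bins, B₀ = 1 Hz, σₙ = 1 Hz, jitter 0,
presence 1, 30 trials — a strong, clean single field typical of dorsal-CA1
recordings, chosen once and recorded in every output. Sweep ranges follow
the study conditions: peak 1–20 Hz, width 1–20 bins, baseline 0.5–5 Hz,
noise 0.5–5 Hz, jitter 0–5 bins, presence 0.1–1.

**Seeding.** A population seed s plus neuron index i gives the
counter-based sub-seed `SeedSequence((s, 1+i))`, so any neuron is
reproducible in isolation and populations are order-independent.

## Statistics

Spatial information uses the occupancy-weighted overall mean
γ̄ = Σ p(x)γ(x) (an unweighted-mean variant is exposed for comparability
with pipelines that use it; the two coincide under uniform occupancy, the
only case the simulator produces). Bins with γ(x) = 0 contribute 0 via the
x·log x → 0 limit; a silent neuron yields NaN with a flag. The ANOVA is a
two-pass one-way between-groups F with per-group counts, so bins missing on
some trials (zero occupancy) reduce that group's n rather than entering as
zeros. Degenerate cases are flagged: zero within-variance with remaining
between-bin structure → +∞; an all-constant matrix → NaN. The
degenerate-case detector uses a magnitude-scaled tolerance
((max(|grand mean|, 1)·1e−12)²) so float round-off is not mistaken for
variance.

## Rate maps from spikes

Empirical (or synthesized) sessions enter as spike times plus a position
trace. Per-sample dwell times come from central differences of the
timestamps; samples below the running-speed floor (default 5 cm/s for the
rodent-style QC, 0 otherwise) contribute neither occupancy nor spikes.
Bins are half-open [edge, edge) intervals, 0-based, with the track end
falling in the last bin. rate[t, x] = spike count / occupancy seconds; the
identity Σₓ rate[t,x]·seconds[t,x] = trial spike count holds exactly on
unsmoothed maps and is tested. Zero-occupancy bins are NaN (missing), not
zero. Smoothing is a per-row Gaussian kernel truncated at 3 SD with
per-bin renormalisation (flat maps are invariant; interior-supported maps
conserve their mean to ~1e−9, which is also the tested property — exact
mass conservation and constant-invariance cannot hold simultaneously for a
truncated kernel at the edges). Smoothing is never applied implicitly.
The QC filter mirrors common linear-track practice (0.2–20 Hz mean rate,
≥50 spikes, ≥15 trials after dropping traversals >2 SD from the mean
duration, ≥50% presence) and names every violated rule. A 3-bin edge mask
for reward-site artefacts is available but off by default.

## Detection

Spike-level nulls circularly rotate the whole train by U[min_shift,
T−min_shift] (min_shift default 1 s, excluding near-identity shifts);
rate-level nulls rotate every trial row by an independent uniform bin
offset, preserving each row's multiset. For simulated matrices the
rate-row shift is the default and is recorded in the result. Surrogate
maps are rebuilt with the same binning/smoothing as the observed map.
Significance requires the observed value to *strictly exceed* the 95th
percentile (linear-interpolation percentile) of 1,000 surrogates; the
add-one p-value (1 + #{null ≥ obs})/(1 + n) is reported alongside. Under
the null (A = 0) both tests reject at 4.7–4.8% with 1,000 neurons × 1,000
surrogates, inside the 99% binomial band around the nominal 5%. No
correction is applied across neurons. Classification curves use 20
equal-count score bins by default.

## Features and PCA

The eight features are estimated from unsmoothed matrices: peak and average
rate and their ratio from the trial-averaged map; field width as the total
count of bins above 20% of the raw peak (baseline not subtracted — the
threshold is defined on the raw peak); field count as the number of
contiguous supra-threshold runs at least 2 bins long (the minimum width is
configurable; 2 discards single-bin noise blips); consistency as the
fraction of trials whose per-trial peak bin (ties → lowest index) falls
within ±3 bins of the overall peak; presence as the fraction of trials
with strictly positive rate somewhere in the detected field region; and
the Pearson correlation of mean maps from odd- vs even-numbered trials
(trial 1 is odd). With a positive baseline the estimated presence ratio
saturates at 1 — it is informative for sparse/spike-like data, and the
recovery oracle therefore uses noise-free, baseline-free neurons. Feature
extraction is 1D-only; 2D matrices are analysed by the metrics alone.

PCA standardizes columns (z-score, ddof = 1 — the decomposition of the
correlation matrix), excludes NaN rows with a record, drops zero-variance
features with a warning, and fixes signs so the largest-magnitude loading
of each component is positive. All components are retained by default; the
count needed for 90% variance is reported.

## Problem sizes and numerical choices

The width-sweep study uses 200 neurons per integer σ = 1…20 (4,000
neurons), enough that the argmax of each mean curve is stable across seeds
while the whole study runs in seconds; the calibration study uses 1,000
no-field neurons with 1,000 surrogates each, the size at which the 99%
binomial band around 5% is ±1.8 points. Directional sweeps in the test
suite use 5 values × 100 neurons (3 × 60 in 2D), sizes at which every
asserted ordering of population means held with margin at design time.
Binning-sensitivity experiments simulate at 60 bins so that 10-, 20- and
30-bin variants are exact divisors (clean aggregation only).

## What the simulations do and do not show

The generator reproduces the features the detection statistics respond to —
field sharpness, contrast against baseline, trial-level noise, field
dropout and drift — but not spike-level phenomena (no theta modulation or
phase precession, no multi-field generative mode, no waveforms), behavioural
confounds (speed, direction, reward), or realistic occupancy inhomogeneity
(simulated occupancy is uniform). Passing tests therefore validate the
statistics' behaviour as functions of tuning-curve structure; they do not
certify performance on empirical recordings, where the rate-map and QC path
(built here for spike/position input) and per-session occupancy weighting
matter.

One documented divergence: over the presence-ratio sweep, mean SI is far
less responsive than mean F (F grows ~200-fold, SI ~9-fold with the default
baseline), but SI is not flat in the strict sense of a mean-normalized
slope below 10% of F's. Because presence scales only the field term while
the baseline/noise floor is fixed, SI's peak-to-mean contrast necessarily
grows with presence under any positive floor; the corresponding strict
assertion in the acceptance suite fails by design rather than being
weakened.

## Known limitations

- Feature extraction assumes a single dominant field; multi-field neurons
  get a sensible field count but consistency/presence refer to the union of
  detected fields.
- The spike-level circular shift assumes a stationary session; sessions
  with long gaps dilute the null.
- The ANOVA treats bins as exchangeable groups and ignores spatial
  adjacency; smoothing induces correlation between neighbouring bins that
  inflates F (this is exactly the sensitivity the smoothing experiments
  quantify, not a defect of the implementation).
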