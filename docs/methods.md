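# Methods

This note documents the models, parameter choices and numerical decisions
behind `zfseizure`, and what the synthetic validation does and does not show
about real recordings.

## Recording model and the synthetic generator

A recording is 10 min of baseline followed by 60 min of PTZ treatment,
sampled at 1 kHz by default (the acquisition hardware digitizes at 10 kHz;
1 kHz keeps a full 70 min trace at ~4.2 M samples and resolves every
frequency the pipeline quantifies — the delta band and spike timescales down
to 10 ms; 10 kHz is supported through `SimulationConfig`). Times are seconds
from recording start; intervals are half-open `[start, end)`.

The generator's defaults are the study conditions. Each
`GenotypeProfile` carries the published cohort summaries — e.g. TL:
49.86 SLE/h, 12.9 min latency, 5.5 s mean duration, 167.3 IED/h, 7/7
incidence, 1.25% 24 h survival; *panx1a*⁻/⁻: 0.38 SLE/h, 1/8 incidence, 30%
survival — plus amplitude factors (SLE peak 6×, IED 2.5× the noise SD) that
are not printed anywhere and were chosen so that events sit comfortably
above the detection thresholds (3× / 1.5×), as the published example traces
show.

* **Noise** is white Gaussian by default (σ = 0.05 mV), making the
  baseline-SD thresholds analytically checkable; 1/f ("pink") noise is
  available.
* **SLE waveform**: a Tukey-windowed (α = 0.1) polyspike train (12 Hz spike
  rate, 10 ms Gaussian spikes, mostly-positive polarity) plus a 2.5 Hz
  sinusoid at 55% relative weight, normalized to unit peak and scaled to the
  profile's amplitude factor × noise SD. The spike train satisfies the
  polyspike criterion; the sinusoid produces the delta-band power increase
  during events.
* **IED waveform**: a short Tukey-windowed 8 Hz oscillatory burst.
* **Arrivals** are homogeneous Poisson after a deterministic latency offset.
  The profile rate is interpreted as the arrival rate over the effective
  window `[latency, end − mean duration]`; a per-recording count over the
  full hour is therefore slightly below rate × 1 h whenever the latency is
  large. Cohort incidence is honored by drawing per-larva seizer status and
  giving seizers rate `sle_rate / incidence`, so the cohort-mean rate
  matches the profile.
* **Collisions**: SLE intervals closer than 0.8 s are merged; IED arrivals
  colliding (same margin) with anything already placed are discarded. The
  margin exceeds the detector's 0.5 s merge gap plus envelope smoothing, so
  ground-truth events are resolvable in principle. `GroundTruth` keeps both
  the merged event list (what a detector can be scored against) and the raw
  Poisson arrival count (what rate calibration is scored against — merging
  would bias it by a few percent at the TL rate).
* **SLE durations** are normal (profile mean/SD) truncated below at 3.3 s —
  not 3.0 — because envelope thresholding loses ~0.1–0.2 s per edge and a
  true SLE must not be detectable as sub-3 s. IED durations are uniform on
  [1.3, 2.7] s for the same reason. Events are placed to end inside the
  treatment window.
* Baseline segments contain noise only: the study's example traces show
  quiet baselines, and no baseline event statistics are reported to emulate.

Behavior: each larva gets 8 tracker outputs over 30 baseline + 60 treatment
1 min bins. Mean Δpixel activity follows a per-genotype gamma-shaped
template `b₀ + A (t/t_p)^a e^{a(1−t/t_p)}` (TL: b₀ = 20, A = 130,
t_p = 22 min, a = 2.5; *panx1b*⁻/⁻ has a sharper, earlier, larger bump and a
higher baseline; *panx1a*⁻/⁻ a halved bump) with additive Gaussian noise
(SD 12 Δpixel). The other 7 outputs are monotone saturating transforms of
activity with Poisson count noise, respecting per-bin duration budgets
(≤ 60 s). Stage II/III counts are Poisson around Gaussian intensity bumps
(stage III peak at 26 min for TL, 34 min for *panx1b*⁻/⁻). Survival times
are exponential with the hazard implied by the profile's 24 h survival,
censored at the horizon.

What the generator does *not* emulate: electrode drift and movement
artifacts, non-stationary noise, the within-event waveform diversity of real
ictal discharges, the full cross-output covariance of the video tracker, or
correlations between electrographic and behavioral severity within a larva.
Passing tests therefore demonstrate the correctness and calibration of the
quantification machinery under the stated model, not detector performance on
noisy real-world recordings.

## Event detection

Rectified deviation from the baseline mean → 50 ms moving-RMS envelope →
supra-threshold runs at 1.5 × baseline SD → runs closer than 0.5 s merged →
classification: SLE requires duration ≥ 3 s, raw peak ≥ 3 × SD and ≥ 5 local
maxima above the 1.5× threshold (≥ 20 ms apart); IED requires duration in
[1, 3) s and peak ≥ 1.5 × SD; everything else is discarded. Only the
treatment phase is scanned and events are truncated at the window edge.
Choices the amplitude/duration rules leave open, and how they were fixed:

* the envelope (moving RMS, 50 ms) and merge gap (0.5 s) are standard
  practice and exposed as parameters;
* "polyspikes" is operationalized as ≥ 5 counted maxima — conservative and
  configurable;
* amplitude is the peak absolute deviation from the baseline mean (example
  traces show bipolar deflections);
* the baseline SD is computed after removing a linear trend so DC offset and
  slow drift do not inflate it; detection is invariant under DC offset and
  under joint rescaling of trace and baseline;
* IEDs have no amplitude ceiling: classification is duration-first, then the
  SLE criteria;
* latency and mean duration are reported as missing (NaN), not zero, when a
  recording has no SLE.

On synthetic cohorts at the TL conditions the detector attains event-level
F1 ≈ 1.0 (match = overlapping ≥ 50% of the shorter interval, kinds equal)
and recovers the injected SLE rate within sampling error; boundary accuracy
is ~0.1–0.3 s, set by the envelope ramp at the event edges.

## Spectral quantification

Welch PSD with 4 s Hann windows and 50% overlap (defaults): 1–4 Hz must be
resolvable, which needs windows of at least ~1 s; 4 s gives 0.25 Hz
resolution while still averaging ≥ 150 segments over 10 min. Delta AUC uses
trapezoidal integration with the PSD linearly interpolated at the band
edges, so a constant PSD c integrates to exactly 3c. The spectrogram is a
tiling of non-overlapping windowed periodograms (display-oriented; its
column mean equals a zero-overlap Welch estimate for stationary signals).
Group PSDs are means across recordings with an s.e.m. band.

## Behavior and stage scoring

Activity curves are group mean ± s.e.m. per 1 min bin. AUC is trapezoidal
over bin centers (Δpixel·min); baseline subtraction removes each larva's
mean over the final 15 min of baseline (the stabilized period) before
integrating. Peak stage latency is the center of the bin with the highest
group-mean count, ties resolved to the earliest bin; the 50% criterion
counts larvae with ≥ 1 event in a bin. Stage I is not quantified — it lacks
an unambiguous scoring criterion.

## SOM phenotyping

One SOM is trained on 8-dimensional standardized samples (one per larva ×
treatment minute; 4 × 36 × 60 = 8640 samples for the 4-genotype design);
per-output classification maps are derived afterwards by masking the BMU
distance to a single feature. This reconciles per-output reporting with a
single 4×4 map. Weight initialization is linear along the first two
principal axes (sign-fixed), so training is deterministic and seed-free; the
seed only drives the permutation test. The neighborhood is a step function
of hex-lattice link distance with radius shrinking linearly 3 → 1 across the
200 batch iterations.

Numerical choice: the plain step-neighborhood batch update can flip-flop
between assignment configurations, which makes the quantization error (mean
sample-to-BMU distance) oscillate by ~0.1–1%. The update is therefore
damped by backtracking — the step is halved until the quantization error
does not increase, keeping the previous weights as a last resort — which
makes the recorded QE trajectory non-increasing by construction while
accepting the full batch step in the common case.

Similarity between two groups is the mean over the 16 nodes of the absolute
difference in classified-larvae counts. The group-distribution test is a
chi-square-ordered permutation test on the 2 × 16 count table (exhaustive
enumeration when feasible, otherwise Monte-Carlo with the add-one
estimator); a per-node 2 × 2 variant can be obtained by masking. Note that
modal-BMU classification weights the whole hour equally: genotypes whose
curves differ mainly in a short transient can classify similarly if most of
their hour is alike, so the synthetic similarity matrix reproduces the
same-template-vs-different-template ordering rather than any particular
published heatmap.

## Statistics

* **Barnard exact**: p = sup over the nuisance success probability π of the
  probability of tables at least as extreme as observed. Default ordering is
  the pooled-score statistic (the standardized difference of proportions
  with pooled variance), which reproduces the published incidence p-values;
  the unpooled Wald ordering is available. Tables with equal proportions get
  statistic 0 (their standardization is 0/0). The maximization evaluates a
  2001-point grid *including the endpoints* (the supremum can sit at the
  degenerate π → 0/1 corners, e.g. for two all-success groups) followed by
  two local refinement rounds; agreement with an independent dense-grid
  enumeration oracle is ≤ 10⁻⁶ over every design with n₁ + n₂ ≤ 12.
  One-sided tests are used where the direction was pre-specified; the
  one-sided value for the fully separated 7 vs 7 design equals 0.5¹⁴
  analytically. (Published legends report both 6.1 × 10⁻⁵ and 6.1 × 10⁻⁶
  for identical 7/7-vs-0/7 designs; only the former is consistent with the
  closed form, and it is the value this package reproduces.)
* **Rank tests** use exact null distributions for small untied samples and
  tie-corrected normal approximations otherwise (scipy). Kaplan–Meier and
  the log-rank test come from lifelines; without censoring the KM estimate
  equals the empirical survivor function.
* **Estimation statistics**: percentile bootstrap of the difference of
  means (default 10 000 resamples, seed-controlled). With n = 60 per group
  the 95% CI covers a true shift in ~95% of simulations; percentile
  intervals undercover slightly for much smaller samples.
* **Repeated-measures ANOVA**: two-way mixed design (group between, time
  within) via pingouin with Greenhouse–Geisser correction; the same ε is
  applied to the interaction term (both share the repeated-measures error).
  With two repeated levels ε = 1 exactly. Post-hoc per-bin comparisons are
  Bonferroni-corrected (p × number of bins, capped at 1).

## Assays

ATP: luminescence inverted through a least-squares linear standard curve
(0–1 µM; non-positive slopes rejected), divided by protein content, scaled
to the reference group. qPCR: Pfaffl-form efficiency-corrected ratio with
per-gene efficiency defaulting to 2.0 (perfect doubling — fold changes are
reported without efficiencies, so doubling is the neutral choice). The
fixed-reallocation randomization test permutes control/treated labels
jointly across the paired target/reference wells, two-sided on |log R|,
2000 reallocations by default (exhaustive when fewer exist — with 3 + 3
replicates the attainable two-sided floor is 2/20 = 0.1). R is invariant to
a constant Ct shift across all wells and to group relabeling (two-sided).

## Problem sizes used in validation

The simulation-based acceptance checks use: 50 TL-profile recordings at
1 kHz for detector calibration; 100 seeds of 3 × 36-larva cohorts for the
SOM similarity ordering; 1000 simulations × 1000 bootstrap resamples for CI
coverage; exhaustive oracles over all 2×2 designs with total n ≤ 12. The
numbered analysis scripts use 6-larva cohorts per genotype — large enough to
show every metric while keeping each script in the tens of seconds.

## Known limitations

* The detector thresholds the smoothed envelope; the original analysis code
  is not public, and whether it thresholded the raw trace, a filtered band
  or an envelope is unknown. The choice is exposed as parameters.
* Synthetic waveforms are stylized; F1 ≈ 1 on them is a correctness check,
  not a field performance estimate.
* Stage scoring is emulated (real stage counts are manual video scores).
* No artifact rejection beyond baseline normalization; no streaming
  detection; no multitaper/wavelet spectra; no mixed-effects models.
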