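# Methods

This note documents the models behind `calquench`, the defaults and why,
the numerical choices, and what the synthetic cohorts do and do not
emulate.

## 1. Signal model and ΔF/F

Input recordings are neuron × frame fluorescence matrices with a frame
rate (default study condition: 1.1 Hz, 500 frames ≈ 7.6 min). Baselines
drift slowly, so F0 is a per-neuron **rolling 20th percentile** over a
60 s window (window clipped at the recording edges; percentiles use
linear interpolation). ΔF/F = (F − F0)/F0 is invariant to rescaling a raw
trace by any positive constant. Neurons whose trace is identically zero,
or whose baseline is non-positive anywhere, cannot be normalised; they
are dropped with a logged warning rather than propagated as NaNs.

**Transient raster.** Per neuron the noise scale σ is the median absolute
deviation scaled to Gaussian σ (×1.4826), and frames strictly above
`median + k·σ` in runs of at least `min_frames` consecutive frames are
marked active. Defaults: k = 3, min_frames = 2 (≈1.8 s at 1.1 Hz).
The threshold is referenced to the trace **median**, not zero: a
20th-percentile baseline leaves ΔF/F with a systematic positive offset of
roughly 0.85 noise-SD, which would silently soften an absolute k·σ
criterion; the MAD is computed about the median, so the median is its
natural centre (`center_median=False` restores the absolute rule). When
σ = 0 (noise-free synthetic input) the threshold falls back to an
absolute ΔF/F floor (default 0.1), with a log notice. Ties never activate
(strict `>`), frames are 0-based, and all intervals are half-open
`[onset, offset)`.

## 2. Network events

The co-active fraction f(t) = active neurons / N is scanned for maximal
runs with f ≥ θ; runs separated by ≤ `merge_gap` frames (default 1) are
merged and merged runs shorter than `min_frames` (default 2) are dropped.
Event participants are the neurons active during at least one frame of
the event window (no fractional-overlap weighting).

**Threshold θ.** The synchrony criterion is a data-driven null: each
neuron's active-run train is circularly shifted by an independent uniform
offset — per-neuron activity statistics and run structure preserved,
inter-neuron synchrony destroyed — and θ is the 99th percentile of the
pooled shuffled co-active fractions (1,000 shuffles, seeded), floored at
an absolute 0.1. The null is explicit and its parameters are recorded in
run metadata.

**Metrics per recording.** Event frequency = n_events / minutes; mean
event duration in seconds; Network Activation = mean over events of
|participants|/N. With zero events the frequency is 0 and the other two
are reported as missing (NaN), never as 0. Per neuron, Neuronal Network
Participation is the fraction of the recording's events the neuron is
active in; with zero events it is missing and excluded from models at
that timepoint.

## 3. Quench calling and survival

A neuron is dead from the first observed day its soma intensity sits at
or below `k_bg ×` background (default k_bg = 1.5) **and stays there** on
every later observed day in the persistence window (default: all
remaining days — the strict reading of "no signal remained"). A dip that
recovers is censored noise, and dim-but-above-threshold signal never
triggers a call. A day-0 observation above threshold is required (the
neuron's baseline identity); fewer than two observation days is an error.

Kaplan–Meier curves use lifelines' product-limit estimator (S(0) = 1,
right-continuous, non-increasing). The group effect is a Cox
proportional-hazards model with one binary covariate, fitted in-package:

* **Efron tie handling** — death and censoring resolve on integer days,
  so ties are guaranteed; Efron's correction is exact enough at these tie
  sizes and is the convention matched by R's `coxph`.
* **Newton iterations** on the scalar partial likelihood, started at
  β = 0; divergence (|log HR| > 20) and single-group event sets raise a
  monotone-likelihood error with a diagnostic instead of a runaway
  estimate.
* **Cluster-robust variance** — neurons are nested in animals, so the
  variance is the Lin–Wei sandwich built from Efron score residuals
  summed within clusters, with a G/(G−1) small-cluster factor (G =
  animals). Without the factor the estimator reproduces R's
  `coxph(... + cluster(id))` standard error to printed precision; with
  it, simulated 95% CI coverage at G = 12–16 sits at 93–94% instead of
  below 90%. Wald z and p are reported; CI = exp(log HR ± 1.96·SE).

## 4. Mixed-effects participation analysis

Participation is analysed by neuron with a random intercept per animal
(neurons nested within pups/slices). The model y = Xβ + Zb + ε has a
single variance ratio λ = σ²_animal/σ²_resid, so REML is **profiled to a
1-D problem** and maximised by bounded scalar search with an explicit
λ = 0 boundary check — this avoids the boundary misconvergence we
observed with a general-purpose mixed-model optimiser, and reproduces
lme4/lmerTest variance components exactly on cross-check fixtures.

Fixed effects (group, fate, timepoint, interactions) are sum-coded, so
the per-term Wald F-tests are Type III. Denominator degrees of freedom
use the **Satterthwaite** approximation: for a contrast ℓ,
df = 2f²/(g'Ag) with f = ℓ'(X'V⁻¹X)⁻¹ℓ, g its gradient in the
log-variances (central differences) and A the inverse negative REML
Hessian (numeric, 2×2). Multi-df terms follow the lmerTest recipe
(eigendecompose the contrast covariance, combine per-eigencontrast dfs).
A "containment" rule is available instead: effects constant within
animals are tested against between-animal df, within-animal effects
against residual df. Participation is analysed untransformed on [0, 1],
matching how the quantity is reported; a logit transform is a caller-side
option. Singular fits (λ → 0 or a numerically perfect fit) downgrade to
the fixed-effects-only OLS solution with residual df and a logged notice;
with the random-intercept variance at zero this reproduces the
unclustered linear model exactly.

The fate analysis is run per group (does participation differ between
neurons that later die and neurons that survive?); a second model
regresses death day on baseline participation among observed deaths
(refused below three deaths).

## 5. The synthetic cohorts

The generator produces the study conditions the analyses assume, with
full ground truth for recovery testing.

**Calcium recordings.** Network events arrive as a renewal stream: gamma
durations (mean 4.3 s, shape 7.2 so the event-level SD ≈ 1.6 s) and
exponential gaps with a 3-frame (~2.7 s) refractory minimum, the
exponential rate dead-time-corrected to λ/(1 − λ·d) so the realized rate
equals the configured 3.9 events/min. (A plain Poisson process cannot
deliver both non-overlapping events and the configured rate; the renewal
form is the standard fix.) Each neuron owns a participation probability
drawn once from a beta distribution (mean 0.52, concentration 10) and
joins each event independently. The configured duration is the
**fluorescence footprint** — the quantity an imaging pipeline reports —
so participants' spikes (Poisson, 1.5 Hz scaled by the full duration, at
least one per joined event) occupy the interval shortened by one decay
half-life (kernel_decay·ln 2 ≈ 1 frame): GCaMP6s keeps a burst visible
for about that long after firing stops. Background transients arrive at
1/min/neuron. Spikes are convolved with a double-exponential kernel
(rise 0.18 s, decay 1.5 s — literature-typical GCaMP6s; the kernel is
sampled at its peak plus integer frames since the rise is sub-frame),
scaled to 0.25 ΔF/F per unitary transient (~1 AP), plus Gaussian noise
(SD 0.05, SNR 5). Raw fluorescence is re-expanded around a per-neuron
resting brightness so the ΔF/F stage is exercised.

**Injury schedule.** Multipliers on rate/duration/participation per
timepoint apply to the injured group only; the default schedule
suppresses all three at 1 h (0.4/0.7/0.7 — placeholders: the acute
magnitudes are not published numbers) and is identically 1 from 24 h
onward ("full recovery"). A `DEVELOPMENTAL_SCHEDULE` constant with
participation declining at d4/d11 (both groups) emulates developmental
desynchronization for callers who want it; it is not the default.

**Survival.** Death days are drawn per neuron from a piecewise-constant
daily hazard (days 1–6: 0.004/day; days 7–11: 0.03/day — late-rising,
giving ~16% cumulative death in controls and ~43% under HR 3.232),
multiplied by the group hazard ratio and a per-animal lognormal frailty
(median 1, SD 0.3 on the log-hazard scale — sized so the cluster-robust
CI is meaningfully wider than the model-based one, as in real
pup-clustered data), with administrative censoring at day 11 (in vivo)
or day 10 (in vitro). Cohort presets: in vivo 8 pups/group with 18–85
neurons/pup and HR 3.232 (a companion figure legend prints 3.242 for the
same analysis; both are documented, the text value is the default);
in vitro 6 slices/group with 26–56 neurons/slice and HR 2.88. Intensity
tracks put alive neurons at a bright level with lognormal day-to-day
noise and occasional dim days, floored at 2.5× background (any remaining
signal means alive, by construction), and dead neurons at background.

**What the simulator does not emulate.** No optical PSF, motion
artifacts, z-drift, neuropil contamination, vasculature, or ROI
segmentation — inputs are already neuron-resolved traces. Participation
is independent of fate by default (injectable via
`participation_offset`), frailty affects death hazard but not activity,
and day-to-day identity tracking is assumed perfect. Passing recovery
tests therefore validates the **analysis chain** under the stated
statistical structure, not robustness to imaging artifacts upstream of
trace extraction.

## 6. Problem sizes and numerical conventions

Recovery harnesses use 20 replicate 13-animal cohorts for the imaging
metrics and 100 replicate cohorts per survival configuration — sizes at
which the Monte-Carlo SE of each recovered mean is well under the
tolerance being checked. Detection on the package's own defaults has
known small biases (cohort means ≈ −5% frequency, +6% duration, −0.03
activation): short events below the 2-frame minimum are undetectable,
decay tails survive the half-life margin stochastically, and occasional
adjacent events merge. They are properties of thresholded event detection
at 1.1 Hz, left visible rather than calibrated away.

Everything random flows from a single integer seed through
`numpy.random.SeedSequence` spawning, so identical (spec, seed) pairs are
bit-identical. Frames 0-based; intervals half-open; days integer; ties at
event thresholds never activate; zero-event recordings report missing
(not zero) duration/activation; CSV round-trips are value-exact
(`%.17g` + round-trip float parsing).

## 7. Known limitations

* The Cox stage handles a single binary covariate (the study design);
  additional covariates would need the vectorised Newton step.
* Satterthwaite df relies on numeric second derivatives of the REML
  surface; extremely small animal counts (< 4) can make it unstable, in
  which case the containment rule is the safer option.
* The shuffle null preserves run lengths but not burst-rate
  autocorrelation beyond runs; θ is mildly anticonservative for neurons
  with strongly periodic activity.
* Event-duration recovery is resolution-limited at 1.1 Hz: one frame is
  ~21% of a 4.3 s event.
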