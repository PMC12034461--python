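# calquench

Calcium network-event metrics and quench-based neuronal survival analysis
for longitudinal two-photon cohorts.

## The problem

Mild neonatal hypoxic-ischaemic injury kills neurons *late*: cortical and
hippocampal neurons keep functioning for days after the insult and then
quench — permanently lose their constitutively expressed fluorophore
(mRuby) — mostly in the second week. Quantifying this requires two coupled
analyses of longitudinal two-photon imaging:

1. **Population calcium activity.** GCaMP6s recordings (neuron × frame
   matrices at ~1.1 Hz, 500 frames ≈ 7.6 min) are normalised to
   ΔF/F = (F − F0)/F0 with a rolling-percentile baseline F0, thresholded
   per neuron at k·σ (σ from the median absolute deviation) into binary
   activity rasters, and scanned for **network events**: maximal runs of
   frames in which the co-active fraction f(t) = (active neurons)/N stays
   at or above a threshold θ drawn from a circular-shuffle null. Per
   recording this yields the event frequency (events/min), mean event
   duration (s), **Network Activation** (mean over events of
   |participants|/N) and each neuron's **Neuronal Network Participation**
   (fraction of events it is active in).

2. **Single-neuron survival.** Each tracked neuron's daily soma intensity
   is reduced to a quench day — the first day its signal sits at
   background and never returns ("dim but present" is alive). The
   resulting (time, event) table feeds the Kaplan–Meier product-limit
   estimator and a Cox proportional-hazards model
   h_i(t) = h0(t)·exp(β·group) whose variance is the cluster-robust
   (Lin–Wei) sandwich over animals — neurons within a pup or slice are
   not independent. Participation-by-fate comparisons use a linear
   mixed-effects model with a random intercept per animal and Type III
   F-tests with Satterthwaite denominator degrees of freedom.

No raw recordings ship with the package; a forward simulator
(`calquench.synthdata`) generates two-photon-like cohorts — spikes through
a double-exponential GCaMP6s kernel with noise, injury-dependent acute
suppression with full recovery by 24 h, and pup-clustered late neuronal
death over an 11-day follow-up — with complete ground truth, so every
stage is validated by parameter recovery.

## Worked example

```python
import numpy as np
from calquench import (
    sham_baseline_spec, simulate_recording, compute_dff, detect_transients,
    coactive_fraction, shuffle_threshold, detect_network_events,
    network_metrics,
)

spec = sham_baseline_spec()          # 3.9 events/min, 4.3 s, participation 0.52
rec, truth = simulate_recording(spec, "baseline", seed=1, group="sham")

dff = compute_dff(rec)                       # rolling 20th-percentile baseline
raster = detect_transients(dff)              # k = 3, runs >= 2 frames
theta = shuffle_threshold(raster, seed=2)    # 1000 shuffles, 99th percentile
events = detect_network_events(
    coactive_fraction(raster), rec.frame_rate, theta, raster=raster
)
m = network_metrics(events, raster)
print(f"theta={theta:.3f} n_events={m.n_events} "
      f"freq={m.event_frequency:.2f}/min dur={m.mean_event_duration:.2f}s "
      f"activation={m.network_activation:.3f}")
```

Output:

```
theta=0.240 n_events=24 freq=3.17/min dur=5.04s activation=0.509
```

One 7.6-minute recording of this simulated animal contains 24 network
events (3.17/min) lasting 5.04 s on average, and an average 51% of its
neurons join each event — single-animal noise around the configured
3.9/min, 4.3 s and 0.52 (cohort means recover these closely; see below).

The survival arm:

```python
from calquench import (
    in_vivo_survival_spec, simulate_survival_cohort,
    simulate_intensity_tracks, call_quench_table, cox_clustered,
)

spec = in_vivo_survival_spec()       # 8 pups/group, HR 3.232, censor day 11
table, truth = simulate_survival_cohort(spec, seed=1)
tracks = simulate_intensity_tracks(table, spec, seed=2)
called = call_quench_table(tracks)   # quench = signal at background, for good
fit = cox_clustered(called)
print(f"HR {fit.hr:.2f} (95% CI {fit.ci95[0]:.2f}-{fit.ci95[1]:.2f}), "
      f"z={fit.z:.2f}, {fit.n_clusters} pups, {fit.n_events} deaths")
```

Output:

```
HR 2.93 (95% CI 2.07-4.16), z=6.03, 16 pups, 284 deaths
```

The quench caller recovered every simulated death day exactly, and the
clustered Cox stage estimates a hazard ratio of 2.93 for this one cohort
(the configured value is 3.232; across 100 replicate cohorts the mean
estimate sits within a few percent of it).

A staged CLI wraps the same functions: `calquench simulate cohort`,
`dff`, `events`, `participation`, `quench`, `survival`, `lme`, and
`calquench all --config cfg.json --seed 1 --out run/` for the whole
pipeline. See `docs/methods.md` for the model details and design choices.

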