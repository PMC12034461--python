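"""Forward simulation of longitudinal two-photon cohorts.

The generator emulates the two data streams the analysis pipeline consumes:

* **Population calcium recordings** — neuron × frame GCaMP6s-like ΔF/F at
  1.1 Hz for 500 frames (7.6 min).  Synchronous network events arrive as a
  non-overlapping renewal stream at a configured rate; each event's duration
  is gamma-distributed; each neuron joins a given event independently with a
  neuron-specific participation probability drawn once from a beta
  distribution.  Participants fire Poisson spike trains inside events,
  every neuron fires sparse background transients, and spikes are convolved
  with a double-exponential indicator kernel before additive Gaussian noise.
  Raw fluorescence is produced by re-expanding ΔF/F around a per-neuron
  resting brightness so the full ΔF/F → raster → event pipeline can be
  exercised end to end.

* **Longitudinal survival cohorts** — per-neuron death days drawn from a
  piecewise-constant daily baseline hazard, multiplied by a group hazard
  ratio and a per-animal lognormal frailty (within-animal correlation of
  fates), with administrative censoring; plus daily soma-intensity tracks in
  which death manifests as permanent quenching to the background level.

Every draw flows from a single integer seed through
:class:`numpy.random.SeedSequence`, so identical (spec, seed) pairs
reproduce outputs bit-identically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .signal import ActivityRaster, PopulationRecording

__all__ = [
    "CohortSpec",
    "GroundTruthLog",
    "DEVELOPMENTAL_SCHEDULE",
    "sham_baseline_spec",
    "in_vivo_survival_spec",
    "in_vitro_survival_spec",
    "simulate_recording",
    "simulate_survival_cohort",
    "simulate_intensity_tracks",
    "truth_raster",
]

#: Timepoint labels in acquisition order.
TIMEPOINTS = ("baseline", "1h", "24h", "d2", "d4", "d11")

#: Injured-group multipliers (event_rate, duration, participation) per
#: timepoint.  The default schedule suppresses network activity acutely at
#: 1 h and recovers fully from 24 h onward; the acute magnitudes are
#: configurable placeholders, not measured values.
DEFAULT_SCHEDULE: dict[str, tuple[float, float, float]] = {
    "baseline": (1.0, 1.0, 1.0),
    "1h": (0.4, 0.7, 0.7),
    "24h": (1.0, 1.0, 1.0),
    "d2": (1.0, 1.0, 1.0),
    "d4": (1.0, 1.0, 1.0),
    "d11": (1.0, 1.0, 1.0),
}

#: Alternative both-group schedule emulating developmental
#: desynchronization: participation declines by day 4 and day 11 as cortical
#: networks decorrelate.  Applied multiplicatively on top of the injury
#: schedule when passed as ``developmental_schedule``.
DEVELOPMENTAL_SCHEDULE: dict[str, tuple[float, float, float]] = {
    "baseline": (1.0, 1.0, 1.0),
    "1h": (1.0, 1.0, 1.0),
    "24h": (1.0, 1.0, 1.0),
    "d2": (1.0, 1.0, 0.9),
    "d4": (1.0, 1.0, 0.8),
    "d11": (1.0, 1.0, 0.6),
}

_INJURED_GROUPS = frozenset({"HI", "OGD"})


class InvalidSpecError(ValueError):
    """Raised when a cohort specification is internally inconsistent."""


@dataclass
class CohortSpec:
    """Generator parameters for one simulated cohort.

    Defaults are the sham-baseline in-vivo conditions: 1.1 Hz, 500-frame
    recordings with 3.9 network events/min of mean duration 4.3 s and mean
    per-neuron participation 0.52, and an 11-day follow-up with a
    late-rising daily hazard (higher in days 7–11 than days 0–6).
    """

    n_animals_per_group: int = 13
    neurons_min: int = 18
    neurons_max: int = 85
    frame_rate: float = 1.1           # Hz
    n_frames: int = 500
    event_rate: float = 3.9           # events / min
    event_duration_mean: float = 4.3  # s
    event_duration_shape: float = 7.2  # gamma shape; SD = mean / sqrt(shape)
    participation_mean: float = 0.52  # beta mean, in (0, 1]
    participation_dispersion: float = 10.0  # beta concentration; 0 = degenerate
    background_transient_rate: float = 1.0  # transients / min / neuron
    noise_sd: float = 0.05            # ΔF/F units
    kernel_rise: float = 0.18         # s
    kernel_decay: float = 1.5         # s
    spike_amplitude: float = 0.25     # ΔF/F per unitary transient
    event_spike_rate: float = 1.5     # Hz within events, per participant
    min_event_gap_frames: int = 3     # refractory gap between network events (~2.7 s)
    resting_brightness: float = 100.0  # a.u., raw-F re-expansion level
    timepoint_schedule: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SCHEDULE)
    )
    developmental_schedule: dict[str, tuple[float, float, float]] | None = None
    hazard_schedule: tuple[float, ...] = (0.004,) * 6 + (0.03,) * 5  # /day, days 1..11
    hazard_ratio: float = 3.232
    frailty_sd: float = 0.3           # SD of per-animal log-hazard offset
    censor_day: int = 11
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames <= 0 or self.frame_rate <= 0:
            raise InvalidSpecError("n_frames and frame_rate must be positive")
        if self.n_animals_per_group <= 0:
            raise InvalidSpecError("n_animals_per_group must be positive")
        if not 0 < self.neurons_min <= self.neurons_max:
            raise InvalidSpecError("neuron range must satisfy 0 < min <= max")
        if self.event_rate < 0 or self.background_transient_rate < 0:
            raise InvalidSpecError("rates must be non-negative")
        if self.event_duration_mean <= 0 or self.event_duration_shape <= 0:
            raise InvalidSpecError("event duration parameters must be positive")
        if not 0 < self.participation_mean <= 1:
            raise InvalidSpecError("participation_mean must lie in (0, 1]")
        if self.noise_sd < 0 or self.kernel_rise <= 0 or self.kernel_decay <= 0:
            raise InvalidSpecError("noise/kernel parameters out of range")
        if self.hazard_ratio <= 0:
            raise InvalidSpecError("hazard_ratio must be positive")
        if self.frailty_sd < 0:
            raise InvalidSpecError("frailty_sd must be non-negative")
        if len(self.hazard_schedule) < self.censor_day:
            raise InvalidSpecError("hazard schedule must span [0, censor_day]")
        if any(h < 0 for h in self.hazard_schedule):
            raise InvalidSpecError("hazards must be non-negative")
        # renewal feasibility: one event + refractory gap must fit, on average,
        # inside the mean inter-event interval at the configured rate
        dead_s = self.event_duration_mean + self.min_event_gap_frames / self.frame_rate
        if self.event_rate > 0 and self.event_rate / 60.0 * dead_s >= 1.0:
            raise InvalidSpecError(
                "event_rate infeasible for the configured duration and gap"
            )

    def multipliers(self, timepoint: str, group: str) -> tuple[float, float, float]:
        """(rate, duration, participation) multipliers for a session."""
        if timepoint not in self.timepoint_schedule:
            raise InvalidSpecError(f"unknown timepoint {timepoint!r}")
        rate, dur, part = (
            self.timepoint_schedule[timepoint]
            if group in _INJURED_GROUPS
            else (1.0, 1.0, 1.0)
        )
        if self.developmental_schedule is not None:
            dr, dd, dp = self.developmental_schedule.get(timepoint, (1.0, 1.0, 1.0))
            rate, dur, part = rate * dr, dur * dd, part * dp
        return rate, dur, part


@dataclass
class GroundTruthLog:
    """Oracle record of what the generator actually drew.

    ``true_event_intervals`` are sorted, non-overlapping half-open frame
    intervals; ``true_participants`` holds one neuron-id set per event;
    ``true_spike_frames`` maps neuron id to its full (event + background)
    spike-frame list; ``true_death_day`` maps neuron id to its drawn death
    day (``inf`` if never); ``cluster_id`` maps neuron id to its animal.
    """

    true_event_intervals: list[tuple[int, int]] = field(default_factory=list)
    true_participants: list[set[str]] = field(default_factory=list)
    true_spike_frames: dict[str, list[int]] = field(default_factory=dict)
    true_death_day: dict[str, float] = field(default_factory=dict)
    cluster_id: dict[str, str] = field(default_factory=dict)

    def validate(self, neuron_ids: list[str] | None = None) -> None:
        prev_end = -1
        for onset, offset in self.true_event_intervals:
            if onset < prev_end or offset <= onset:
                raise ValueError("event intervals must be sorted and disjoint")
            prev_end = offset
        if neuron_ids is not None:
            known = set(neuron_ids)
            for members in self.true_participants:
                if not members <= known:
                    raise ValueError("participant id missing from recording")

    def to_json(self) -> str:
        payload = asdict(self)
        payload["true_participants"] = [sorted(s) for s in self.true_participants]
        payload["true_death_day"] = {
            k: ("inf" if math.isinf(v) else v) for k, v in self.true_death_day.items()
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthLog":
        payload = json.loads(text)
        return cls(
            true_event_intervals=[tuple(iv) for iv in payload["true_event_intervals"]],
            true_participants=[set(s) for s in payload["true_participants"]],
            true_spike_frames={k: list(v) for k, v in payload["true_spike_frames"].items()},
            true_death_day={
                k: (math.inf if v == "inf" else float(v))
                for k, v in payload["true_death_day"].items()
            },
            cluster_id=dict(payload["cluster_id"]),
        )


# ---------------------------------------------------------------------------
# preset cohort configurations
# ---------------------------------------------------------------------------

def sham_baseline_spec(**overrides) -> CohortSpec:
    """The 13-animal/group in-vivo imaging configuration."""
    return CohortSpec(**({"n_animals_per_group": 13} | overrides))


def in_vivo_survival_spec(**overrides) -> CohortSpec:
    """8 pups/group, 18–85 neurons/pup, HR 3.232, censoring at day 11."""
    base = dict(
        n_animals_per_group=8,
        neurons_min=18,
        neurons_max=85,
        hazard_ratio=3.232,
        censor_day=11,
        hazard_schedule=(0.004,) * 6 + (0.03,) * 5,
    )
    return CohortSpec(**(base | overrides))


def in_vitro_survival_spec(**overrides) -> CohortSpec:
    """6 slices/group, 26–56 neurons/slice, HR 2.88, censoring at day 10."""
    base = dict(
        n_animals_per_group=6,
        neurons_min=26,
        neurons_max=56,
        hazard_ratio=2.88,
        censor_day=10,
        hazard_schedule=(0.004,) * 6 + (0.03,) * 4,
    )
    return CohortSpec(**(base | overrides))


# ---------------------------------------------------------------------------
# calcium recordings
# ---------------------------------------------------------------------------

def _indicator_kernel(spec: CohortSpec) -> np.ndarray:
    """Frame-sampled double-exponential kernel, unit peak amplitude.

    The kernel is evaluated at the peak time plus integer frame offsets so a
    spike's own frame carries the peak of the transient (the rise time is
    short relative to one 0.91 s frame).
    """
    dt = 1.0 / spec.frame_rate
    t_peak = spec.kernel_rise * math.log1p(spec.kernel_decay / spec.kernel_rise)

    def shape(t: np.ndarray) -> np.ndarray:
        return (1.0 - np.exp(-t / spec.kernel_rise)) * np.exp(-t / spec.kernel_decay)

    peak = shape(np.array([t_peak]))[0]
    ks = np.arange(0, 64)
    vals = shape(t_peak + ks * dt) / peak
    keep = vals >= 0.01
    return vals[: int(np.flatnonzero(keep).max() + 1)] if keep.any() else vals[:1]


def _draw_participation(rng: np.random.Generator, n: int, mean: float, phi: float) -> np.ndarray:
    if mean >= 1.0:
        return np.ones(n)
    if phi <= 0:
        return np.full(n, mean)
    return rng.beta(mean * phi, (1.0 - mean) * phi, size=n)


def _draw_event_intervals(
    rng: np.random.Generator, spec: CohortSpec, rate_mult: float, dur_mult: float
) -> list[tuple[int, int]]:
    """Non-overlapping event intervals at the configured realized rate.

    Events form a renewal stream: gamma durations plus exponential gaps with
    a refractory minimum of ``min_event_gap_frames``.  The exponential rate
    is dead-time corrected so the long-run realized event rate equals the
    configured one.
    """
    rate_s = spec.event_rate * rate_mult / 60.0
    if rate_s <= 0:
        return []
    fr = spec.frame_rate
    mean_dur = spec.event_duration_mean * dur_mult
    dead_s = mean_dur + spec.min_event_gap_frames / fr
    inv_gap = 1.0 / rate_s - dead_s
    if inv_gap <= 0:
        raise InvalidSpecError("event rate infeasible at this timepoint")

    intervals: list[tuple[int, int]] = []
    # no dead time before the first event: its onset is exponential at the
    # realized rate from the recording start
    onset = int(round(rng.exponential(1.0 / rate_s) * fr))
    while True:
        dur_s = rng.gamma(spec.event_duration_shape, mean_dur / spec.event_duration_shape)
        dur_f = max(1, int(round(dur_s * fr)))
        offset = onset + dur_f
        if offset > spec.n_frames:
            break
        intervals.append((onset, offset))
        gap_f = spec.min_event_gap_frames + int(round(rng.exponential(inv_gap) * fr))
        onset = offset + gap_f
        if onset >= spec.n_frames:
            break
    return intervals


def simulate_recording(
    spec: CohortSpec,
    timepoint: str = "baseline",
    seed: int | np.random.Generator = 0,
    group: str = "sham",
    animal_id: str = "a00",
    n_neurons: int | None = None,
    participation_offset: np.ndarray | None = None,
) -> tuple[PopulationRecording, GroundTruthLog]:
    """Simulate one population calcium recording plus its ground truth.

    Returns a raw-fluorescence :class:`PopulationRecording` (ΔF/F
    re-expanded around ``resting_brightness``) and the
    :class:`GroundTruthLog` of drawn events, participants and spikes.

    ``n_neurons`` overrides the per-animal neuron-count draw (used when the
    recording must align with an already-simulated survival cohort);
    ``participation_offset`` shifts individual neurons' participation
    probabilities, e.g. to inject a known fate effect.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rate_mult, dur_mult, part_mult = spec.multipliers(timepoint, group)

    n = (
        int(rng.integers(spec.neurons_min, spec.neurons_max + 1))
        if n_neurons is None
        else int(n_neurons)
    )
    if n <= 0:
        raise InvalidSpecError("n_neurons must be positive")
    ids = [f"{animal_id}_n{i:03d}" for i in range(n)]
    intervals = _draw_event_intervals(rng, spec, rate_mult, dur_mult)

    p_mean = min(1.0, spec.participation_mean * part_mult)
    p_i = _draw_participation(rng, n, p_mean, spec.participation_dispersion)
    if participation_offset is not None:
        p_i = np.clip(p_i + np.asarray(participation_offset, dtype=float), 0.01, 1.0)

    fr = spec.frame_rate
    spikes = np.zeros((n, spec.n_frames))
    truth = GroundTruthLog(true_event_intervals=list(intervals))
    spike_frames: dict[str, set[int]] = {nid: set() for nid in ids}

    # The configured event duration is the *fluorescence* footprint — the
    # quantity the imaging pipeline reports.  A transient stays visible for
    # about one decay half-life after firing stops (burst amplitudes sit
    # roughly twice above detection level), so the underlying spiking window
    # is the event interval shortened by kernel_decay·ln2, floored at one
    # frame.  The burst's spike mass scales with the full event duration and
    # is compressed into the firing window.
    margin = int(round(spec.kernel_decay * math.log(2.0) * fr))
    for onset, offset in intervals:
        joined = np.flatnonzero(rng.random(n) < p_i)
        truth.true_participants.append({ids[i] for i in joined})
        spike_hi = max(onset + 1, offset - margin)
        dur_s = (offset - onset) / fr
        for i in joined:
            k = rng.poisson(spec.event_spike_rate * dur_s)
            times = rng.uniform(onset, spike_hi, size=max(1, k))  # join ⇒ ≥1 spike
            frames = np.floor(times).astype(int)
            np.add.at(spikes[i], frames, 1.0)
            spike_frames[ids[i]].update(int(t) for t in frames)

    bg_per_frame = spec.background_transient_rate / 60.0 / fr
    if bg_per_frame > 0:
        bg = rng.random((n, spec.n_frames)) < bg_per_frame
        spikes += bg
        for i in range(n):
            spike_frames[ids[i]].update(np.flatnonzero(bg[i]).tolist())

    truth.true_spike_frames = {nid: sorted(fs) for nid, fs in spike_frames.items()}
    truth.validate(ids)

    kernel = spec.spike_amplitude * _indicator_kernel(spec)
    dff = np.apply_along_axis(
        lambda row: np.convolve(row, kernel)[: spec.n_frames], 1, spikes
    )
    if spec.noise_sd > 0:
        dff = dff + rng.normal(0.0, spec.noise_sd, size=dff.shape)

    f0 = spec.resting_brightness * rng.uniform(0.8, 1.2, size=(n, 1))
    raw = f0 * (1.0 + dff)

    rec = PopulationRecording(
        matrix=raw,
        frame_rate=fr,
        neuron_ids=ids,
        session={"animal_id": animal_id, "group": group, "timepoint": timepoint},
        is_dff=False,
    )
    return rec, truth


def membership_raster(truth: GroundTruthLog, neuron_ids: list[str], n_frames: int,
                      frame_rate: float = 1.1) -> ActivityRaster:
    """Noise-free raster marking participants active across their events.

    Bypasses spiking and fluorescence entirely: a neuron is active on every
    frame of every event it joined.  Event detection on this raster at any
    threshold below the smallest per-event participant fraction reproduces
    the logged intervals exactly.
    """
    mat = np.zeros((len(neuron_ids), n_frames), dtype=np.uint8)
    index = {nid: i for i, nid in enumerate(neuron_ids)}
    for (onset, offset), members in zip(
        truth.true_event_intervals, truth.true_participants
    ):
        for nid in members:
            mat[index[nid], onset:offset] = 1
    return ActivityRaster(
        matrix=mat,
        frame_rate=frame_rate,
        neuron_ids=list(neuron_ids),
        k=math.nan,
        min_frames=1,
        baseline_sigma=np.zeros(len(neuron_ids)),
        session={"source": "ground-truth-membership"},
    )


def truth_raster(truth: GroundTruthLog, neuron_ids: list[str], n_frames: int,
                 frame_rate: float = 1.1) -> ActivityRaster:
    """Binary raster of true spike frames — the detector-bypass oracle."""
    mat = np.zeros((len(neuron_ids), n_frames), dtype=np.uint8)
    index = {nid: i for i, nid in enumerate(neuron_ids)}
    for nid, frames in truth.true_spike_frames.items():
        mat[index[nid], frames] = 1
    return ActivityRaster(
        matrix=mat,
        frame_rate=frame_rate,
        neuron_ids=list(neuron_ids),
        k=math.nan,
        min_frames=1,
        baseline_sigma=np.zeros(len(neuron_ids)),
        session={"source": "ground-truth"},
    )


# ---------------------------------------------------------------------------
# survival cohorts
# ---------------------------------------------------------------------------

def simulate_survival_cohort(
    spec: CohortSpec,
    seed: int | np.random.Generator = 0,
    group_labels: tuple[str, str] = ("sham", "HI"),
) -> tuple[pd.DataFrame, GroundTruthLog]:
    """Draw per-neuron death days for a two-group clustered cohort.

    Each animal receives a lognormal frailty (median 1) that multiplies its
    neurons' hazards; the treated group's hazard is additionally multiplied
    by ``spec.hazard_ratio``.  Death and censoring resolve on integer days
    (ties expected).  Returns the tidy survival table with columns
    ``neuron_id, cluster_id, group, group_label, time, event`` and the
    ground-truth log of death days and cluster assignments.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    truth = GroundTruthLog()
    hazards = np.asarray(spec.hazard_schedule[: spec.censor_day], dtype=float)

    for g, label in enumerate(group_labels):
        for a in range(spec.n_animals_per_group):
            cluster = f"{label}{a:02d}"
            frailty = math.exp(rng.normal(0.0, spec.frailty_sd)) if spec.frailty_sd else 1.0
            n = int(rng.integers(spec.neurons_min, spec.neurons_max + 1))
            rate = hazards * (spec.hazard_ratio if g == 1 else 1.0) * frailty
            p_die = 1.0 - np.exp(-rate)  # per-day conditional death probability
            for j in range(n):
                nid = f"{cluster}_n{j:03d}"
                death: float = math.inf
                for d in range(spec.censor_day):
                    if rng.random() < p_die[d]:
                        death = d + 1  # hazard for day d+1 lives in slot d
                        break
                if math.isinf(death):
                    time, event = spec.censor_day, 0
                else:
                    time, event = int(death), 1
                rows.append(
                    {
                        "neuron_id": nid,
                        "cluster_id": cluster,
                        "group": g,
                        "group_label": label,
                        "time": time,
                        "event": event,
                    }
                )
                truth.true_death_day[nid] = death
                truth.cluster_id[nid] = cluster

    return pd.DataFrame(rows), truth


def simulate_intensity_tracks(
    survival: pd.DataFrame,
    spec: CohortSpec,
    seed: int | np.random.Generator = 0,
    bright_level: float = 100.0,
    background_level: float = 10.0,
    day_noise_sd: float = 0.25,     # lognormal sigma of day-to-day brightness
    dim_day_prob: float = 0.06,     # occasional dim-but-alive days
    dim_factor: float = 0.3,
    alive_floor: float = 2.5,       # alive intensity never below this × background
) -> pd.DataFrame:
    """Daily soma-intensity tracks consistent with a survival table.

    Alive neurons emit intensity near ``bright_level`` with multiplicative
    day-to-day noise and occasional dim-but-clearly-nonzero days — by
    construction never below ``alive_floor × background_level``, mirroring
    the assay rule that any remaining signal, however dim, means alive.
    From the death day onward intensity sits at ``background_level`` (small
    multiplicative jitter).  Returns a tidy table with columns
    ``neuron_id, cluster_id, group, group_label, day, intensity,
    background_level`` observed on every integer day 0..censor_day.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    days = np.arange(0, spec.censor_day + 1)
    rows = []
    for rec in survival.itertuples(index=False):
        death_day = rec.time if rec.event == 1 else math.inf
        for d in days:
            if d >= death_day:
                intensity = background_level * math.exp(rng.normal(0.0, 0.1))
            else:
                level = bright_level * (dim_factor if rng.random() < dim_day_prob else 1.0)
                intensity = max(
                    level * math.exp(rng.normal(0.0, day_noise_sd)),
                    alive_floor * background_level,
                )
            rows.append(
                {
                    "neuron_id": rec.neuron_id,
                    "cluster_id": rec.cluster_id,
                    "group": rec.group,
                    "group_label": rec.group_label,
                    "day": int(d),
                    "intensity": intensity,
                    "background_level": background_level,
                }
            )
    return pd.DataFrame(rows)
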