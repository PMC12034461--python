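"""Synchronous network events and population metrics.

A network event is a contiguous stretch of frames in which the fraction of
co-active neurons stays at or above a synchrony threshold θ.  θ is either
supplied or derived from a circular-shuffle null: each neuron's active-run
train is circularly shifted by an independent random offset, which preserves
per-neuron activity statistics while destroying inter-neuron synchrony, and
θ is a high quantile of the resulting co-active-fraction distribution.

From the detected events the module computes the cohort metrics reported per
animal — event frequency (events/min), mean event duration (s) and Network
Activation (average proportion of co-active cells per event) — and the
per-neuron Neuronal Network Participation (fraction of a recording's events
a given neuron is active in).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .signal import ActivityRaster, _runs

logger = logging.getLogger("calquench")

#: Default shuffle count for the synchrony null.
DEFAULT_N_SHUFFLES = 1000
#: Tail probability (percent) defining θ as the (100 − alpha) percentile.
DEFAULT_ALPHA_PCT = 1.0
#: Absolute lower bound on θ.
DEFAULT_THETA_FLOOR = 0.1
#: Runs separated by ≤ merge_gap frames are merged.
DEFAULT_MERGE_GAP = 1
#: Minimum event length in frames (~1.8 s at 1.1 Hz).
DEFAULT_EVENT_MIN_FRAMES = 2


@dataclass
class NetworkEvent:
    """One synchrony event, frames half-open [onset, offset)."""

    onset_frame: int
    offset_frame: int
    duration_s: float
    participant_ids: frozenset[str]
    peak_coactive_fraction: float

    def __post_init__(self) -> None:
        if self.offset_frame <= self.onset_frame:
            raise ValueError("offset must exceed onset")


@dataclass
class NetworkMetrics:
    """Per-recording population metrics.

    ``mean_event_duration`` and ``network_activation`` are NaN (missing, not
    zero) when the recording contains no events.
    """

    event_frequency: float  # events / min
    mean_event_duration: float  # s
    network_activation: float  # fraction in [0, 1]
    n_events: int


def coactive_fraction(raster: ActivityRaster) -> np.ndarray:
    """Per-frame fraction of neurons active: active count / total neurons."""
    if raster.n_neurons == 0:
        raise ValueError("raster has zero neurons")
    return raster.matrix.sum(axis=0) / float(raster.n_neurons)


def shuffle_threshold(
    raster: ActivityRaster,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    alpha: float = DEFAULT_ALPHA_PCT,
    seed: int | np.random.Generator = 0,
    floor: float = DEFAULT_THETA_FLOOR,
) -> float:
    """Data-driven synchrony threshold θ from a circular-shuffle null.

    Each neuron's binary train is circularly shifted by an independent
    uniform offset per shuffle; θ is the (100 − alpha) percentile of the
    pooled per-frame co-active fractions across all shuffles, floored at
    ``floor``.  Seeded and reproducible.
    """
    if raster.n_neurons == 0:
        raise ValueError("raster has zero neurons")
    if n_shuffles < 100:
        logger.warning("n_shuffles=%d < 100: threshold estimate will be coarse", n_shuffles)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    mat = raster.matrix.astype(np.uint8)
    n, f = mat.shape
    # circular shift = gather from a doubled copy: row i read at offset o
    # gives mat[i, (t - o) % f] for all t at once
    doubled = np.concatenate([mat, mat], axis=1)
    base = np.arange(f)
    rows = np.arange(n)[None, :, None]
    counts = np.empty((n_shuffles, f), dtype=np.int16)
    chunk = 100  # bound the (chunk, n, f) gather's memory footprint
    done = 0
    while done < n_shuffles:
        m = min(chunk, n_shuffles - done)
        offsets = rng.integers(0, f, size=(m, n))
        idx = base[None, None, :] + offsets[:, :, None]  # (m, n, f) into doubled
        counts[done : done + m] = doubled[rows, idx].sum(axis=1, dtype=np.int16)
        done += m
    quant = float(np.percentile(counts / float(n), 100.0 - alpha))
    return max(quant, floor)


def detect_network_events(
    fraction_trace: np.ndarray,
    frame_rate: float,
    theta: float,
    min_frames: int = DEFAULT_EVENT_MIN_FRAMES,
    merge_gap: int = DEFAULT_MERGE_GAP,
    raster: ActivityRaster | None = None,
) -> list[NetworkEvent]:
    """Detect synchrony events as runs of co-active fraction ≥ θ.

    Maximal runs with ``fraction_trace >= theta`` are found, runs separated
    by at most ``merge_gap`` frames are merged, and merged runs shorter than
    ``min_frames`` are dropped.  If a ``raster`` is supplied each event's
    participant set is filled with the neurons active during at least one
    frame of the event window; otherwise participant sets are empty.
    """
    if not 0.0 < theta <= 1.0:
        raise ValueError("theta must lie in (0, 1]")
    trace = np.asarray(fraction_trace, dtype=float)
    if trace.min(initial=0.0) < 0 or trace.max(initial=0.0) > 1:
        raise ValueError("fraction trace must lie in [0, 1]")

    runs = _runs(trace >= theta)
    merged: list[list[int]] = []
    for start, stop in runs:
        if merged and start - merged[-1][1] <= merge_gap:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])

    events: list[NetworkEvent] = []
    for start, stop in merged:
        if stop - start < min_frames:
            continue
        if raster is not None:
            active = raster.matrix[:, start:stop].any(axis=1)
            participants = frozenset(
                raster.neuron_ids[i] for i in np.flatnonzero(active)
            )
        else:
            participants = frozenset()
        events.append(
            NetworkEvent(
                onset_frame=int(start),
                offset_frame=int(stop),
                duration_s=(stop - start) / frame_rate,
                participant_ids=participants,
                peak_coactive_fraction=float(trace[start:stop].max()),
            )
        )
    return events


def network_metrics(
    events: list[NetworkEvent],
    raster: ActivityRaster,
    frame_rate: float | None = None,
) -> NetworkMetrics:
    """Per-recording event frequency, mean duration and Network Activation.

    Network Activation is the mean over events of |participants| / n_neurons
    — the average proportion of co-active cells per network event.  With no
    events the frequency is 0 and the other metrics are NaN.
    """
    fr = raster.frame_rate if frame_rate is None else frame_rate
    duration_min = raster.n_frames / fr / 60.0
    n_events = len(events)
    if n_events == 0:
        return NetworkMetrics(0.0, math.nan, math.nan, 0)
    mean_duration = float(np.mean([e.duration_s for e in events]))
    activation = float(
        np.mean([len(e.participant_ids) / raster.n_neurons for e in events])
    )
    return NetworkMetrics(
        event_frequency=n_events / duration_min,
        mean_event_duration=mean_duration,
        network_activation=activation,
        n_events=n_events,
    )


def neuronal_network_participation(
    neuron_id: str,
    events: list[NetworkEvent],
    raster: ActivityRaster | None = None,
) -> float:
    """Fraction of the recording's network events this neuron is active in.

    Returns NaN when the recording has no events (the neuron's participation
    is undefined at that timepoint and is excluded from downstream models).
    """
    if not events:
        return math.nan
    hits = sum(1 for e in events if neuron_id in e.participant_ids)
    return hits / len(events)
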