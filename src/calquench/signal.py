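"""Fluorescence preprocessing: ΔF/F normalisation and binary activity rasters.

The population calcium signal arrives as a neuron × frame matrix of raw (or
already-normalised) fluorescence sampled at a known frame rate.  Two steps
turn it into the representation every downstream metric consumes:

1. :func:`compute_dff` — per-neuron baseline F0 as a rolling percentile of
   the trace and normalisation to (F − F0)/F0;
2. :func:`detect_transients` — a robust per-neuron noise scale (MAD scaled
   to Gaussian σ) and a run-length thresholding rule that marks frames as
   "active" when ΔF/F exceeds k·σ for at least ``min_frames`` consecutive
   frames.

Frames are 0-based throughout and intervals are half-open ``[onset, offset)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

logger = logging.getLogger("calquench")

#: Rolling-baseline percentile (GCaMP traces sit near baseline most of the time).
DEFAULT_BASELINE_PERCENTILE = 20.0
#: Rolling-baseline window in seconds.
DEFAULT_BASELINE_WINDOW_S = 60.0
#: Threshold multiplier on the robust noise scale.
DEFAULT_K = 3.0
#: Minimum run length (frames) for an active epoch; ~1.8 s at 1.1 Hz.
DEFAULT_MIN_FRAMES = 2
#: Absolute ΔF/F threshold used when the robust noise scale is zero
#: (noise-free synthetic input).
DEFAULT_FLOOR = 0.1

_MAD_TO_SIGMA = 1.4826  # consistency factor for Gaussian noise


@dataclass
class PopulationRecording:
    """A neuron × frame fluorescence matrix with acquisition metadata.

    ``matrix`` may hold raw intensities or ΔF/F; ``is_dff`` records which.
    ``session`` carries ``animal_id``, ``group`` and ``timepoint`` labels.
    """

    matrix: np.ndarray
    frame_rate: float
    neuron_ids: list[str]
    session: dict = field(default_factory=dict)
    is_dff: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (neurons × frames)")
        if not np.isfinite(self.matrix).all():
            raise ValueError("matrix contains non-finite values")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if len(self.neuron_ids) != self.matrix.shape[0]:
            raise ValueError("neuron_ids length must match matrix rows")
        if len(set(self.neuron_ids)) != len(self.neuron_ids):
            raise ValueError("neuron_ids must be unique")

    @property
    def n_neurons(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]

    @property
    def duration_min(self) -> float:
        """Recording duration in minutes (n_frames / frame_rate / 60)."""
        return self.n_frames / self.frame_rate / 60.0


@dataclass
class ActivityRaster:
    """Binary neuron × frame activity matrix plus the thresholds that made it."""

    matrix: np.ndarray  # uint8, entries in {0, 1}
    frame_rate: float
    neuron_ids: list[str]
    k: float
    min_frames: int
    baseline_sigma: np.ndarray  # per-neuron robust noise scale
    session: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]


def rolling_percentile(trace: np.ndarray, window: int, percentile: float) -> np.ndarray:
    """Centred rolling percentile with the window clipped at the edges.

    For frame ``t`` the window is ``[t - window//2, t - window//2 + window)``
    intersected with ``[0, n)``; percentiles use linear interpolation
    (numpy's default).
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.size
    if window < 1:
        raise ValueError("window must be >= 1")
    half = window // 2
    out = np.empty(n)
    for t in range(n):
        lo = max(0, t - half)
        hi = min(n, t - half + window)
        out[t] = np.percentile(trace[lo:hi], percentile)
    return out


def _rolling_percentile_matrix(mat: np.ndarray, window: int, percentile: float) -> np.ndarray:
    """Row-wise rolling percentile, same edge clipping as :func:`rolling_percentile`."""
    n, f = mat.shape
    window = min(window, f)
    half = window // 2
    out = np.empty_like(mat, dtype=float)
    interior = f - window + 1
    if interior > 0:
        windows = np.lib.stride_tricks.sliding_window_view(mat, window, axis=1)
        out[:, half : half + interior] = np.percentile(windows, percentile, axis=2)
    for t in list(range(half)) + list(range(half + max(interior, 0), f)):
        lo = max(0, t - half)
        hi = min(f, t - half + window)
        out[:, t] = np.percentile(mat[:, lo:hi], percentile, axis=1)
    return out


def compute_dff(
    rec: PopulationRecording,
    baseline_percentile: float = DEFAULT_BASELINE_PERCENTILE,
    baseline_window: int | None = None,
) -> PopulationRecording:
    """Normalise raw fluorescence to ΔF/F = (F − F0)/F0.

    F0 is a per-neuron rolling ``baseline_percentile`` of the raw trace over
    ``baseline_window`` frames (default: 60 s worth of frames), window
    clipped at the recording edges.  Neurons whose trace is identically zero
    (or whose baseline is non-positive anywhere) cannot be normalised; they
    are dropped with a logged warning rather than propagated as NaNs.

    Parameters
    ----------
    rec:
        Raw recording (``is_dff`` must be False).
    baseline_percentile:
        Percentile in (0, 100) for the rolling baseline.
    baseline_window:
        Window length in frames; ``None`` selects 60 s at the recording's
        frame rate.
    """
    if rec.is_dff:
        raise ValueError("recording is already ΔF/F")
    if not 0 < baseline_percentile < 100:
        raise ValueError("baseline_percentile must lie in (0, 100)")
    if baseline_window is None:
        baseline_window = max(1, int(round(DEFAULT_BASELINE_WINDOW_S * rec.frame_rate)))

    f0_all = _rolling_percentile_matrix(rec.matrix, baseline_window, baseline_percentile)
    kept_rows: list[int] = []
    dff_rows: list[np.ndarray] = []
    for i in range(rec.n_neurons):
        trace = rec.matrix[i]
        if not np.any(trace):
            logger.warning(
                "neuron %s: all-zero trace, excluded from ΔF/F", rec.neuron_ids[i]
            )
            continue
        f0 = f0_all[i]
        if np.any(f0 <= 0):
            logger.warning(
                "neuron %s: non-positive baseline, excluded from ΔF/F",
                rec.neuron_ids[i],
            )
            continue
        kept_rows.append(i)
        dff_rows.append((trace - f0) / f0)

    if not dff_rows:
        raise ValueError("no neuron had a valid baseline; cannot compute ΔF/F")
    out = replace(
        rec,
        matrix=np.vstack(dff_rows),
        neuron_ids=[rec.neuron_ids[i] for i in kept_rows],
        is_dff=True,
    )
    return out


def robust_sigma(trace: np.ndarray) -> float:
    """Noise scale as the median absolute deviation scaled to Gaussian σ."""
    trace = np.asarray(trace, dtype=float)
    return _MAD_TO_SIGMA * float(np.median(np.abs(trace - np.median(trace))))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open [start, stop) pairs."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def detect_transients(
    dff: PopulationRecording,
    k: float = DEFAULT_K,
    min_frames: int = DEFAULT_MIN_FRAMES,
    floor: float = DEFAULT_FLOOR,
    center_median: bool = True,
) -> ActivityRaster:
    """Mark calcium transients: runs of ΔF/F strictly above k·σ.

    σ is estimated per neuron by the scaled median absolute deviation, which
    is insensitive to the sparse transients themselves.  Frames with
    ΔF/F > k·σ (strict inequality; a frame exactly at threshold is inactive)
    that form runs of at least ``min_frames`` consecutive frames are marked
    active.  By default the threshold is referenced to the trace median
    (``center_median``): a percentile baseline leaves ΔF/F with a small
    positive offset, and the median recentres the k·σ criterion on the
    actual noise floor, pairing it with the MAD about the median.  When σ is
    exactly zero — noiseless synthetic input — the threshold falls back to
    the absolute ΔF/F ``floor``, with a log notice.
    """
    if not dff.is_dff:
        raise ValueError("detect_transients expects a ΔF/F recording")
    if min_frames < 1:
        raise ValueError("min_frames must be >= 1")

    n, f = dff.matrix.shape
    raster = np.zeros((n, f), dtype=np.uint8)
    sigmas = np.empty(n)
    for i in range(n):
        sigma = robust_sigma(dff.matrix[i])
        sigmas[i] = sigma
        center = float(np.median(dff.matrix[i])) if center_median else 0.0
        if sigma == 0.0:
            logger.info(
                "neuron %s: zero noise scale, using absolute floor %.3g",
                dff.neuron_ids[i],
                floor,
            )
            threshold = center + floor
        else:
            threshold = center + k * sigma
        above = dff.matrix[i] > threshold
        for start, stop in _runs(above):
            if stop - start >= min_frames:
                raster[i, start:stop] = 1

    return ActivityRaster(
        matrix=raster,
        frame_rate=dff.frame_rate,
        neuron_ids=list(dff.neuron_ids),
        k=k,
        min_frames=min_frames,
        baseline_sigma=sigmas,
        session=dict(dff.session),
    )
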