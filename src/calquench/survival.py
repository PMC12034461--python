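"""Quench-based survival analysis with animal-level clustering.

Death of a tracked neuron is operationalised as *fluorophore quenching*:
the permanent disappearance of its soma fluorescence.  A neuron with any
remaining signal — however dim — is still alive.  :func:`call_quench` turns
a longitudinal intensity track into a (time, event) pair; the resulting
survival table feeds the Kaplan–Meier product-limit estimator and a Cox
proportional-hazards model with a single binary group covariate.

Because several slices can come from one animal and neurons within a pup
share a cranial window, event times are correlated within clusters.  The
Cox stage therefore maximises the Efron-tie partial likelihood by Newton
iterations and reports a cluster-robust sandwich variance built from
grouped score residuals, with a G/(G−1) small-cluster correction — the
"clustering on animal identifier" estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = [
    "CoxFit",
    "KaplanMeierCurve",
    "call_quench",
    "call_quench_table",
    "cox_clustered",
    "kaplan_meier",
]

#: A soma is quenched when its intensity is at most k_bg × background.
DEFAULT_K_BG = 1.5


class MonotoneLikelihoodError(RuntimeError):
    """All events fall in one group: the Cox partial likelihood diverges."""


# ---------------------------------------------------------------------------
# quench calling
# ---------------------------------------------------------------------------

def call_quench(
    track: pd.DataFrame,
    k_bg: float = DEFAULT_K_BG,
    persistence: float | None = None,
) -> tuple[float, int]:
    """Call the quench day of one neuron from its intensity track.

    The quench day is the first observed day on which soma intensity is at
    or below ``k_bg × background_level`` *and stays there* on every later
    observed day within the persistence window (``None`` = all remaining
    observed days, the strict reading of "no signal remained").  A dip that
    recovers is not death; dim-but-above-threshold signal never triggers a
    call.  Returns ``(time, 1)`` for a quench, ``(last observed day, 0)``
    for a censored neuron.

    ``track`` needs columns ``day``, ``intensity``, ``background_level``
    for a single neuron; a day-0 observation is required (the neuron's
    baseline identity) and must itself be above threshold.
    """
    if len(track) < 2:
        raise ValueError("need at least two observation days")
    track = track.sort_values("day")
    days = track["day"].to_numpy(dtype=float)
    intensity = track["intensity"].to_numpy(dtype=float)
    if days[0] != 0:
        raise ValueError("missing day-0 observation: baseline identity required")
    if (intensity < 0).any():
        raise ValueError("intensities must be non-negative")

    threshold = track["background_level"].to_numpy(dtype=float) * k_bg
    below = intensity <= threshold
    if below[0]:
        raise ValueError("neuron already at background on day 0")

    for idx in np.flatnonzero(below):
        d = days[idx]
        window = (
            np.ones_like(days, dtype=bool)
            if persistence is None
            else days <= d + persistence
        )
        later = (days >= d) & window
        if below[later].all():
            return float(d), 1
    return float(days[-1]), 0


def call_quench_table(
    tracks: pd.DataFrame,
    k_bg: float = DEFAULT_K_BG,
    persistence: float | None = None,
) -> pd.DataFrame:
    """Apply :func:`call_quench` per neuron; return a tidy survival table.

    Expects the tidy track table (``neuron_id, cluster_id, group,
    group_label, day, intensity, background_level``) and returns one row per
    neuron with ``time`` and ``event`` columns.
    """
    rows = []
    keys = ["neuron_id", "cluster_id", "group"]
    if "group_label" in tracks.columns:
        keys.append("group_label")
    for ids, sub in tracks.groupby(keys, sort=True):
        time, event = call_quench(sub, k_bg=k_bg, persistence=persistence)
        rows.append(dict(zip(keys, ids)) | {"time": time, "event": event})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

@dataclass
class KaplanMeierCurve:
    """Right-continuous, non-increasing product-limit step function."""

    times: np.ndarray      # event times where the curve steps, ascending
    survival: np.ndarray   # S(t) at and after each step time
    n_at_risk: np.ndarray

    def __call__(self, t: float | np.ndarray) -> np.ndarray | float:
        idx = np.searchsorted(self.times, np.asarray(t), side="right")
        padded = np.concatenate([[1.0], self.survival])
        out = padded[idx]
        return float(out) if np.isscalar(t) else out


def kaplan_meier(table: pd.DataFrame, group: int | str | None = None) -> KaplanMeierCurve:
    """Product-limit survival estimate, optionally for one group.

    S(0) = 1 by construction; the curve steps down only at observed event
    times.  Fitted with lifelines' ``KaplanMeierFitter``.
    """
    sub = table if group is None else table[table["group"] == group]
    if len(sub) == 0:
        raise ValueError(f"no records for group {group!r}")
    kmf = KaplanMeierFitter()
    kmf.fit(sub["time"], event_observed=sub["event"])
    sf = kmf.survival_function_["KM_estimate"]
    times = sf.index.to_numpy(dtype=float)
    surv = sf.to_numpy(dtype=float)
    keep = times > 0
    ev = kmf.event_table
    at_risk = ev["at_risk"].reindex(times[keep]).to_numpy(dtype=float)
    return KaplanMeierCurve(times=times[keep], survival=surv[keep], n_at_risk=at_risk)


# ---------------------------------------------------------------------------
# clustered Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Binary-covariate Cox fit with a cluster-robust Wald test."""

    log_hr: float
    hr: float
    robust_se: float
    ci95: tuple[float, float]
    z: float
    p: float
    n_clusters: int
    n_events: int
    model_se: float
    converged: bool


def _efron_loglik_parts(beta: float, time: np.ndarray, event: np.ndarray,
                        x: np.ndarray, ties: str = "efron") -> tuple[float, float, float]:
    """(loglik, score, information) of the partial likelihood.

    ``ties="efron"`` down-weights tied deaths step by step; ``"breslow"``
    keeps the full risk-set denominator for every tied death.
    """
    loglik = score = info = 0.0
    eta = x * beta
    w = np.exp(eta)
    for t in np.unique(time[event == 1]):
        risk = time >= t
        dead = (time == t) & (event == 1)
        d = int(dead.sum())
        s0r, s1r = w[risk].sum(), (w * x)[risk].sum()
        s0d, s1d = w[dead].sum(), (w * x)[dead].sum()
        loglik += eta[dead].sum()
        for l in range(d):
            frac = l / d if ties == "efron" else 0.0
            phi0 = s0r - frac * s0d
            phi1 = s1r - frac * s1d
            loglik -= math.log(phi0)
            score_term = phi1 / phi0
            score -= score_term
            info += phi1 / phi0 - score_term**2  # x binary ⇒ s2 == s1
        score += x[dead].sum()
    return loglik, score, info


def _efron_score_residuals(beta: float, time: np.ndarray, event: np.ndarray,
                           x: np.ndarray, ties: str = "efron") -> np.ndarray:
    """Per-subject score residuals U_i (counting-process decomposition).

    Each tied event time contributes d Efron steps; a dying subject's event
    indicator is spread equally over the steps and its own risk weight is
    down-weighted by l/d at step l.  The residuals sum to the total score
    (zero at the MLE).
    """
    n = len(time)
    w = np.exp(x * beta)
    resid = np.zeros(n)
    for t in np.unique(time[event == 1]):
        risk = time >= t
        dead = (time == t) & (event == 1)
        d = int(dead.sum())
        s0r, s1r = w[risk].sum(), (w * x)[risk].sum()
        s0d, s1d = w[dead].sum(), (w * x)[dead].sum()
        for l in range(d):
            frac = l / d if ties == "efron" else 0.0
            phi0 = s0r - frac * s0d
            xbar = (s1r - frac * s1d) / phi0
            dlam = 1.0 / phi0
            c = risk.astype(float) - frac * dead.astype(float)
            resid += (x - xbar) * (dead / d - c * w * dlam)
    return resid


def cox_clustered(
    table: pd.DataFrame,
    small_sample_correction: bool = True,
    ties: str = "efron",
    max_iter: int = 50,
    tol: float = 1e-10,
) -> CoxFit:
    """Cox proportional-hazards fit with clustering on animal identifier.

    ``table`` needs columns ``time``, ``event``, ``group`` (binary 0/1) and
    ``cluster_id``.  The Efron partial likelihood is maximised by Newton
    iterations; the variance is the Lin–Wei sandwich with score residuals
    summed within clusters and (by default) a G/(G−1) correction for the
    small number of animals.  Ties use Efron's correction by default
    (times resolve on integer days, so ties are guaranteed); ``ties=
    "breslow"`` selects the simpler Breslow denominator.

    Raises
    ------
    MonotoneLikelihoodError
        If all events fall in one group (the partial likelihood has no
        interior maximum) or Newton iterations diverge.
    ValueError
        If a group is absent or there are fewer than two clusters.
    """
    time = table["time"].to_numpy(dtype=float)
    event = table["event"].to_numpy(dtype=int)
    x = table["group"].to_numpy(dtype=float)
    clusters = table["cluster_id"].to_numpy()

    if set(np.unique(x)) != {0.0, 1.0}:
        raise ValueError("group must be binary with both levels present")
    n_clusters = len(np.unique(clusters))
    if n_clusters < 2:
        raise ValueError("need at least two clusters")
    n_events = int(event.sum())
    events_by_group = {g: int(event[x == g].sum()) for g in (0.0, 1.0)}
    if min(events_by_group.values()) == 0:
        raise MonotoneLikelihoodError(
            f"all {n_events} events lie in one group "
            f"(events by group: {events_by_group}); the hazard ratio diverges"
        )

    beta = 0.0
    converged = False
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    for _ in range(max_iter):
        _, score, info = _efron_loglik_parts(beta, time, event, x, ties)
        if info <= 0:
            break
        step = score / info
        beta += step
        if abs(beta) > 20:
            raise MonotoneLikelihoodError(
                "Newton iterations diverged (|log HR| > 20); "
                "check event counts per group"
            )
        if abs(step) < tol:
            converged = True
            break

    _, _, info = _efron_loglik_parts(beta, time, event, x, ties)
    model_se = 1.0 / math.sqrt(info)
    resid = _efron_score_residuals(beta, time, event, x, ties)
    dfbeta = resid / info
    grouped = pd.Series(dfbeta).groupby(clusters).sum().to_numpy()
    var = float((grouped**2).sum())
    if small_sample_correction:
        var *= n_clusters / (n_clusters - 1)
    robust_se = math.sqrt(var)

    z = beta / robust_se
    from scipy.stats import norm

    p = 2.0 * norm.sf(abs(z))
    ci = (math.exp(beta - 1.96 * robust_se), math.exp(beta + 1.96 * robust_se))
    return CoxFit(
        log_hr=beta,
        hr=math.exp(beta),
        robust_se=robust_se,
        ci95=ci,
        z=z,
        p=p,
        n_clusters=n_clusters,
        n_events=n_events,
        model_se=model_se,
        converged=converged,
    )
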