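"""Mixed-effects comparison of neuronal network participation.

Participation of individual neurons is analysed *by neuron* while
accounting for the nesting of neurons within animals: a linear
mixed-effects model with a random intercept per animal (pup or slice)
carries the within-animal correlation, and fixed effects of treatment
group, fate (died vs survived) and timepoint are tested with Type III
F-tests.  Denominator degrees of freedom use the Satterthwaite
approximation by default — computed here from the REML curvature of the
random-intercept model, since no Python library exposes it — with a
coarser "containment" rule available.

The second analysis asks whether baseline participation predicts the day a
neuron later dies: a random-intercept regression of death day on baseline
participation among neurons with an observed death.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, stats

logger = logging.getLogger("calquench")

__all__ = [
    "LmeSpec",
    "FixedEffectTest",
    "LmeFit",
    "SlopeTest",
    "fit_participation_lme",
    "baseline_vs_deathday_regression",
]

#: Relative variance-ratio below which the random intercept is treated as
#: singular and the model is downgraded to ordinary least squares.
_SINGULAR_RATIO = 1e-6


@dataclass
class LmeSpec:
    """Model specification for the participation analysis.

    ``fixed_terms`` are column names of the record table, optionally joined
    by ``:`` for interactions; categorical terms are sum-coded so the
    F-tests are Type III.  ``group_col`` names the clustering variable
    (each animal contributes a random intercept; neurons are nested within
    animals).
    """

    response: str = "participation"
    fixed_terms: tuple[str, ...] = ("group", "fate", "timepoint", "group:fate")
    group_col: str = "animal_id"
    df_method: str = "satterthwaite"  # or "containment"
    categorical: tuple[str, ...] = ("group", "fate", "timepoint")

    def formula(self) -> str:
        def code(term: str) -> str:
            return ":".join(
                f"C({t}, Sum)" if t in self.categorical else t
                for t in term.split(":")
            )

        rhs = " + ".join(code(t) for t in self.fixed_terms) or "1"
        return f"{self.response} ~ {rhs}"


@dataclass
class FixedEffectTest:
    """Type III F-test of one fixed-effect term."""

    effect: str
    F: float
    df_num: int
    df_den: float
    p: float


@dataclass
class LmeFit:
    """Full fit report: tests, estimates and variance components."""

    tests: list[FixedEffectTest]
    fe_params: dict[str, float]
    fe_cov: list[list[float]]
    sigma2_animal: float
    sigma2_resid: float
    df_method: str
    n_obs: int
    n_clusters: int
    downgraded: bool = False

    def test(self, effect: str) -> FixedEffectTest:
        for t in self.tests:
            if t.effect == effect:
                return t
        raise KeyError(effect)

    def to_json(self) -> str:
        payload = asdict(self)
        payload["tests"] = [asdict(t) for t in self.tests]
        return json.dumps(payload, indent=1)


@dataclass
class SlopeTest:
    """Slope of death day on baseline participation, with its F-test."""

    slope: float
    se: float
    F: float
    df_num: int
    df_den: float
    p: float
    ci95: tuple[float, float]
    n_neurons: int
    n_clusters: int


# ---------------------------------------------------------------------------
# random-intercept REML pieces (closed form for the two-variance model)
# ---------------------------------------------------------------------------

class _RandomInterceptModel:
    """Profile-REML machinery for y = Xβ + (animal intercept) + ε."""

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        self.y = y
        self.X = X
        order = np.argsort(groups, kind="stable")
        self.y = y[order]
        self.X = X[order]
        g = np.asarray(groups)[order]
        _, starts = np.unique(g, return_index=True)
        bounds = np.append(np.sort(starts), len(g))
        self.blocks = [slice(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]

    def _vinv_blocks(self, s2b: float, s2e: float):
        for sl in self.blocks:
            n_g = sl.stop - sl.start
            denom = s2e + n_g * s2b
            shrink = s2b / denom if denom > 0 else 0.0
            yield sl, n_g, shrink

    def beta_cov(self, s2b: float, s2e: float) -> tuple[np.ndarray, np.ndarray]:
        """GLS estimate and its covariance (X'V⁻¹X)⁻¹ at given variances."""
        p = self.X.shape[1]
        xtvx = np.zeros((p, p))
        xtvy = np.zeros(p)
        for sl, n_g, shrink in self._vinv_blocks(s2b, s2e):
            Xg, yg = self.X[sl], self.y[sl]
            xs, ys = Xg.sum(axis=0), yg.sum()
            xtvx += (Xg.T @ Xg - shrink * np.outer(xs, xs)) / s2e
            xtvy += (Xg.T @ yg - shrink * xs * ys) / s2e
        cov = np.linalg.inv(xtvx)
        return cov @ xtvy, cov

    def reml_loglik(self, s2b: float, s2e: float) -> float:
        beta, cov = self.beta_cov(s2b, s2e)
        ll = 0.0
        quad = 0.0
        for sl, n_g, shrink in self._vinv_blocks(s2b, s2e):
            rg = self.y[sl] - self.X[sl] @ beta
            ll -= 0.5 * ((n_g - 1) * math.log(s2e) + math.log(s2e + n_g * s2b))
            quad += (rg @ rg - shrink * rg.sum() ** 2) / s2e
        sign, logdet = np.linalg.slogdet(np.linalg.inv(cov))
        return ll - 0.5 * logdet - 0.5 * quad

    def fit_reml(self) -> tuple[float, float]:
        """Variance components by profiled REML.

        The likelihood is profiled down to the single variance ratio
        λ = σ²_animal / σ²_resid: given λ, the GLS residual quadratic form
        yields σ²_resid in closed form.  λ is maximised on the log scale by
        bounded scalar optimisation, with λ = 0 (no animal variance)
        checked explicitly so boundary fits are recognised.
        """
        n, p = self.X.shape

        def profile(log_lam: float) -> tuple[float, float, float]:
            lam = math.exp(log_lam)
            beta, _ = self.beta_cov(lam, 1.0)
            quad = 0.0
            for sl, n_g, shrink in self._vinv_blocks(lam, 1.0):
                rg = self.y[sl] - self.X[sl] @ beta
                quad += rg @ rg - shrink * rg.sum() ** 2
            s2e = quad / (n - p)
            return self.reml_loglik(lam * s2e, s2e), lam * s2e, s2e

        res = optimize.minimize_scalar(
            lambda t: -profile(t)[0], bounds=(-14.0, 10.0), method="bounded",
            options={"xatol": 1e-8},
        )
        ll_hat, s2b, s2e = profile(res.x)
        ll_zero, _, s2e_zero = profile(-30.0)  # effectively λ = 0
        if ll_zero >= ll_hat:
            return 0.0, s2e_zero
        return s2b, s2e

    def satterthwaite_df(self, ell: np.ndarray, s2b: float, s2e: float,
                         rel_step: float = 1e-3) -> float:
        """Satterthwaite df of contrast ℓ'β via the delta method on log-variances."""
        theta = np.log([max(s2b, 1e-12), s2e])

        def f(th: np.ndarray) -> float:
            _, cov = self.beta_cov(math.exp(th[0]), math.exp(th[1]))
            return float(ell @ cov @ ell)

        def ll(th: np.ndarray) -> float:
            return self.reml_loglik(math.exp(th[0]), math.exp(th[1]))

        h = rel_step
        grad = np.array(
            [
                (f(theta + h * e) - f(theta - h * e)) / (2 * h)
                for e in np.eye(2)
            ]
        )
        hess = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                ei, ej = np.eye(2)[i], np.eye(2)[j]
                hess[i, j] = (
                    ll(theta + h * ei + h * ej)
                    - ll(theta + h * ei - h * ej)
                    - ll(theta - h * ei + h * ej)
                    + ll(theta - h * ei - h * ej)
                ) / (4 * h * h)
        try:
            acov = np.linalg.inv(-hess)
        except np.linalg.LinAlgError:
            return math.nan
        f0 = f(theta)
        denom = float(grad @ acov @ grad)
        if denom <= 0:
            return math.nan
        return 2.0 * f0 * f0 / denom


def _containment_df(X: np.ndarray, cols: np.ndarray, groups: np.ndarray) -> float:
    """Containment denominator df.

    Terms constant within every cluster are tested against between-cluster
    variation (G − rank of the cluster-mean design); terms varying within
    clusters are tested at the within-cluster residual level
    (N − G − rank(X) + q_between-only columns ignored).
    """
    g = pd.Series(np.arange(len(groups))).groupby(groups)
    n_clusters = g.ngroups
    n, p = X.shape
    means = pd.DataFrame(X).groupby(groups).transform("mean").to_numpy()
    within = np.abs(X - means)[:, cols].max() > 1e-10
    if within:
        return float(n - n_clusters - (p - 1))
    return float(n_clusters - np.linalg.matrix_rank(
        pd.DataFrame(X).groupby(groups).mean().to_numpy()
    ))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _term_tests(
    design_info, beta, cov, rim, s2b, s2e, X, groups, df_method
) -> list[FixedEffectTest]:
    tests = []
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        cols = np.arange(X.shape[1])[sl]
        q = len(cols)
        L = np.zeros((q, X.shape[1]))
        L[np.arange(q), cols] = 1.0
        lb = L @ beta
        M = L @ cov @ L.T
        scale = max(1.0, float(np.abs(beta).max()))
        if np.allclose(lb, 0.0, atol=1e-10 * scale):
            F = 0.0  # null contrast: F is exactly zero whatever the variance
        else:
            F = float(lb @ np.linalg.pinv(M) @ lb) / q
        if df_method == "satterthwaite" and rim is not None:
            lam, P = np.linalg.eigh(M)
            nus = []
            for j in range(q):
                if lam[j] <= 0:
                    continue
                ell = L.T @ P[:, j]
                nu = rim.satterthwaite_df(ell, s2b, s2e)
                if not math.isnan(nu):
                    nus.append(nu)
            usable = [nu for nu in nus if nu > 2]
            if usable:
                E = sum(nu / (nu - 2) for nu in usable)
                df_den = 2 * E / (E - q) if E > q else float(len(X) - X.shape[1])
            else:
                df_den = float(len(X) - X.shape[1])
        elif df_method == "containment" and rim is not None:
            df_den = _containment_df(X, cols, groups)
        else:  # downgraded OLS path
            df_den = float(len(X) - X.shape[1])
        p = float(stats.f.sf(F, q, df_den)) if df_den > 0 and not math.isnan(F) else math.nan
        tests.append(FixedEffectTest(term, F, q, df_den, p))
    return tests


def _fit_lme(data: pd.DataFrame, spec: LmeSpec) -> LmeFit:
    y_mat, X_mat = patsy.dmatrices(spec.formula(), data, return_type="dataframe")
    y = y_mat.to_numpy(dtype=float).ravel()
    X = X_mat.to_numpy(dtype=float)
    groups = data[spec.group_col].to_numpy()
    design_info = X_mat.design_info
    names = list(design_info.column_names)
    n_clusters = len(np.unique(groups))

    rim = _RandomInterceptModel(y, X, groups)
    downgraded = False
    try:
        s2b, s2e = rim.fit_reml()
    except (np.linalg.LinAlgError, FloatingPointError, ValueError, ZeroDivisionError) as exc:
        logger.warning("REML fit failed (%s); downgrading to OLS", exc)
        downgraded = True
        s2b = s2e = 0.0
    # a numerically perfect fit (zero residual variance) is degenerate for
    # REML-based inference: fall back to the fixed-effects solution
    perfect = not downgraded and s2e <= max(1e-12 * float(np.var(y)), 1e-300)
    if not downgraded and (s2e <= 0 or s2b < _SINGULAR_RATIO * s2e or perfect):
        downgraded = True

    if not downgraded:
        beta, cov = rim.beta_cov(s2b, s2e)
        tests = _term_tests(
            design_info, beta, cov, rim, s2b, s2e, X, groups, spec.df_method
        )
    else:
        logger.warning(
            "singular random-intercept variance: refitting as fixed-effects only"
        )
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        dof = len(y) - np.linalg.matrix_rank(X)
        resid = y - X @ beta
        s2e = float(resid @ resid / dof) if dof > 0 else 0.0
        s2b = 0.0
        cov = s2e * np.linalg.pinv(X.T @ X)
        tests = _term_tests(design_info, beta, cov, None, s2b, s2e, X, groups, "ols")

    return LmeFit(
        tests=tests,
        fe_params=dict(zip(names, map(float, beta))),
        fe_cov=np.asarray(cov).tolist(),
        sigma2_animal=s2b,
        sigma2_resid=s2e,
        df_method=spec.df_method if not downgraded else "residual (OLS downgrade)",
        n_obs=len(y),
        n_clusters=n_clusters,
        downgraded=downgraded,
    )


def fit_participation_lme(records: pd.DataFrame, spec: LmeSpec | None = None) -> LmeFit:
    """Random-intercept LME of participation with Type III fixed-effect tests.

    ``records`` is the per-neuron participation table (columns at least
    ``participation``, ``animal_id`` and the fixed-effect terms).  Rows with
    missing participation — timepoints with zero detected events — are
    excluded listwise.  Each animal must appear with at least one neuron;
    at least two animals per group are required for the group contrast to
    be estimable at the cluster level.

    A singular random-intercept variance triggers a logged downgrade to the
    fixed-effects-only (OLS) model with residual degrees of freedom.
    """
    spec = spec or LmeSpec()
    data = records.dropna(subset=[spec.response]).copy()
    if data.empty:
        raise ValueError("no usable rows after dropping missing participation")
    if "group" in data.columns and "group" in spec.fixed_terms:
        counts = data.groupby("group")[spec.group_col].nunique()
        if (counts < 2).any():
            raise ValueError("need at least two animals per group")
    return _fit_lme(data, spec)


def baseline_vs_deathday_regression(
    records: pd.DataFrame,
    df_method: str = "satterthwaite",
) -> SlopeTest:
    """Regress death day on baseline participation (random pup intercept).

    Only neurons with an observed death day enter; fewer than three deaths
    is refused.  Returns the slope with its standard error, 95% CI and the
    Satterthwaite (or containment) F-test of the slope.
    """
    data = records.dropna(subset=["participation", "death_day"]).copy()
    data = data[np.isfinite(data["death_day"])]
    if len(data) < 3:
        raise ValueError(
            f"only {len(data)} neurons with an observed death day; need >= 3"
        )
    spec = LmeSpec(
        response="death_day",
        fixed_terms=("participation",),
        categorical=(),
        df_method=df_method,
    )
    fit = _fit_lme(data, spec)
    slope = fit.fe_params["participation"]
    idx = list(fit.fe_params).index("participation")
    se = math.sqrt(np.asarray(fit.fe_cov)[idx, idx])
    t = fit.test("participation")
    return SlopeTest(
        slope=slope,
        se=se,
        F=t.F,
        df_num=t.df_num,
        df_den=t.df_den,
        p=t.p,
        ci95=(slope - 1.96 * se, slope + 1.96 * se),
        n_neurons=len(data),
        n_clusters=fit.n_clusters,
    )
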