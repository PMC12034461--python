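"""Quench calling, Kaplan–Meier and the clustered Cox model.

The Cox fit is checked three ways: against a brute-force maximiser of an
independently coded Efron partial likelihood, against lifelines, and
against values from R's survival::coxph with cluster() frozen from the
same deterministic fixture.
"""

import math

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from scipy import optimize

from calquench import synthdata
from calquench.survival import (
    MonotoneLikelihoodError,
    call_quench,
    call_quench_table,
    cox_clustered,
    kaplan_meier,
)


def track_frame(days, intensities, background=10.0):
    return pd.DataFrame(
        {"day": days, "intensity": intensities, "background_level": background}
    )


class TestCallQuench:
    def test_bright_every_day_is_censored_at_last_day(self):
        t = track_frame(range(11), [100.0] * 11)
        assert call_quench(t) == (10.0, 0)

    def test_background_from_day6_onward_is_a_day6_event(self):
        inten = [100.0] * 6 + [10.0] * 5
        t = track_frame(range(11), inten)
        assert call_quench(t) == (6.0, 1)

    def test_transient_dip_does_not_kill(self):
        # at background on day 3 only, recovered on day 4: persistence rule
        inten = [100.0, 90.0, 95.0, 10.0, 100.0, 90.0]
        t = track_frame(range(6), inten)
        assert call_quench(t) == (5.0, 0)

    def test_dim_but_above_threshold_never_triggers(self):
        # 1.5 x background = 15; a dim 20 stays alive
        inten = [100.0, 20.0, 20.0, 20.0]
        t = track_frame(range(4), inten)
        assert call_quench(t) == (3.0, 0)

    def test_finite_persistence_window(self):
        # below threshold on days 3-5, bright again on day 8: a 2-day
        # persistence window calls the quench at day 3 regardless
        inten = [100.0] * 3 + [10.0, 10.0, 10.0] + [100.0, 100.0, 100.0]
        t = track_frame(range(9), inten)
        assert call_quench(t, persistence=2) == (3.0, 1)
        assert call_quench(t, persistence=None) == (8.0, 0)

    def test_missing_day0_is_an_error(self):
        t = track_frame([1, 2, 3], [100.0, 100.0, 100.0])
        with pytest.raises(ValueError, match="day-0"):
            call_quench(t)

    def test_single_observation_is_an_error(self):
        with pytest.raises(ValueError):
            call_quench(track_frame([0], [100.0]))

    def test_quenched_at_baseline_is_an_error(self):
        with pytest.raises(ValueError):
            call_quench(track_frame([0, 1], [10.0, 10.0]))

    def test_table_recovers_true_death_days(self):
        # >= 95% exact recovery at default noise; with the generator's
        # alive-floor construction the caller is exact
        spec = synthdata.in_vivo_survival_spec(n_animals_per_group=3)
        table, truth = synthdata.simulate_survival_cohort(spec, seed=21)
        tracks = synthdata.simulate_intensity_tracks(table, spec, seed=22)
        called = call_quench_table(tracks)
        merged = called.merge(
            table, on=["neuron_id", "cluster_id", "group", "group_label"],
            suffixes=("_called", "_true"),
        )
        exact = (
            (merged["event_called"] == merged["event_true"])
            & (merged["time_called"] == merged["time_true"])
        ).mean()
        assert exact >= 0.95


def km_bruteforce(times, events, t_eval):
    """Independent product-limit oracle: S(t) = prod over event times <= t."""
    s = 1.0
    for u in sorted(set(t for t, e in zip(times, events) if e == 1)):
        if u > t_eval:
            break
        at_risk = sum(1 for t in times if t >= u)
        deaths = sum(1 for t, e in zip(times, events) if t == u and e == 1)
        s *= 1.0 - deaths / at_risk
    return s


class TestKaplanMeier:
    def test_no_events_is_flat_one(self):
        table = pd.DataFrame({"time": [3, 5, 7], "event": [0, 0, 0], "group": 0})
        curve = kaplan_meier(table)
        assert curve(0) == 1.0 and curve(7) == 1.0

    def test_product_limit_example(self):
        # 4 at risk, death at day 2; 3 at risk, death at day 5:
        # S(2) = 3/4, S(5) = 3/4 * 2/3 = 1/2
        table = pd.DataFrame(
            {"time": [2, 5, 6, 7], "event": [1, 1, 0, 0], "group": 0}
        )
        curve = kaplan_meier(table)
        assert curve(2) == pytest.approx(0.75)
        assert curve(5) == pytest.approx(0.5)
        assert curve(1.9) == 1.0

    def test_matches_bruteforce_oracle_on_random_tables(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 25))
            table = pd.DataFrame(
                {
                    "time": rng.integers(1, 12, size=n),
                    "event": rng.integers(0, 2, size=n),
                    "group": 0,
                }
            )
            curve = kaplan_meier(table)
            for t_eval in range(0, 13):
                expected = km_bruteforce(table["time"], table["event"], t_eval)
                assert curve(t_eval) == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_row_order(self, rng):
        table = pd.DataFrame(
            {"time": [2, 5, 5, 7, 9], "event": [1, 1, 0, 1, 0], "group": 0}
        )
        shuffled = table.sample(frac=1.0, random_state=4).reset_index(drop=True)
        c1, c2 = kaplan_meier(table), kaplan_meier(shuffled)
        grid = np.linspace(0, 10, 50)
        assert np.array_equal(c1(grid), c2(grid))

    def test_non_increasing_everywhere(self, rng):
        table = pd.DataFrame(
            {
                "time": rng.integers(1, 12, size=40),
                "event": rng.integers(0, 2, size=40),
                "group": 0,
            }
        )
        vals = kaplan_meier(table)(np.linspace(0, 12, 200))
        assert np.all(np.diff(vals) <= 1e-15)


def efron_loglik_oracle(beta, df):
    """Independent Efron partial log-likelihood (direct transcription)."""
    ll = 0.0
    for t in sorted(df.loc[df.event == 1, "time"].unique()):
        dead = df[(df.time == t) & (df.event == 1)]
        risk = df[df.time >= t]
        d = len(dead)
        sum_risk = float(np.exp(beta * risk.group).sum())
        sum_dead = float(np.exp(beta * dead.group).sum())
        ll += float(beta * dead.group.sum())
        for el in range(d):
            ll -= math.log(sum_risk - el / d * sum_dead)
    return ll


HAND_TABLES = [
    # times with Efron-relevant ties in both groups
    dict(time=[1, 1, 2, 2, 3, 3, 4, 5], event=[1, 1, 1, 0, 1, 1, 0, 0],
         group=[1, 1, 1, 0, 0, 1, 0, 0]),
    dict(time=[2, 2, 2, 4, 4, 6, 8, 8], event=[1, 0, 1, 1, 1, 0, 1, 0],
         group=[0, 0, 1, 1, 0, 1, 1, 0]),
    dict(time=[1, 2, 3, 4, 5, 6, 7, 8], event=[1, 1, 0, 1, 0, 1, 1, 0],
         group=[1, 0, 0, 1, 1, 0, 1, 0]),
]


class TestCoxClustered:
    @pytest.mark.parametrize("raw", HAND_TABLES)
    def test_matches_bruteforce_efron_oracle(self, raw):
        df = pd.DataFrame(raw)
        df["cluster_id"] = [f"c{i}" for i in range(len(df))]
        fit = cox_clustered(df)
        res = optimize.minimize_scalar(
            lambda b: -efron_loglik_oracle(b, df), bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10},
        )
        assert fit.log_hr == pytest.approx(res.x, abs=1e-6)

    def test_matches_lifelines_estimate(self):
        spec = synthdata.in_vivo_survival_spec()
        table, _ = synthdata.simulate_survival_cohort(spec, seed=7)
        fit = cox_clustered(table, small_sample_correction=False)
        cph = CoxPHFitter()
        cph.fit(
            table[["time", "event", "group", "cluster_id"]],
            duration_col="time", event_col="event",
            cluster_col="cluster_id", robust=True,
        )
        assert fit.log_hr == pytest.approx(float(cph.params_.iloc[0]), abs=1e-6)

    def test_matches_frozen_r_coxph_cluster_values(self):
        # R survival::coxph(Surv(time,event) ~ group + cluster(cluster_id),
        # ties="efron") on this exact seeded table: coef 1.183319,
        # robust se 0.121173 (no small-sample factor in R)
        spec = synthdata.in_vivo_survival_spec()
        table, _ = synthdata.simulate_survival_cohort(spec, seed=7)
        fit = cox_clustered(table, small_sample_correction=False)
        assert fit.log_hr == pytest.approx(1.183319, abs=1e-5)
        assert fit.robust_se == pytest.approx(0.121173, abs=1e-5)

    def test_breslow_ties_match_frozen_r_values(self):
        # R coxph(..., ties="breslow") on the same seeded table:
        # coef 1.1532616, robust se 0.1181305
        spec = synthdata.in_vivo_survival_spec()
        table, _ = synthdata.simulate_survival_cohort(spec, seed=7)
        fit = cox_clustered(table, small_sample_correction=False, ties="breslow")
        assert fit.log_hr == pytest.approx(1.1532616, abs=1e-6)
        assert fit.robust_se == pytest.approx(0.1181305, abs=1e-6)
        with pytest.raises(ValueError, match="ties"):
            cox_clustered(table, ties="exact")

    def test_null_data_gives_hr_near_one(self):
        spec = synthdata.in_vivo_survival_spec(
            hazard_ratio=1.0, frailty_sd=0.0, n_animals_per_group=60
        )
        table, _ = synthdata.simulate_survival_cohort(spec, seed=13)
        fit = cox_clustered(table)
        assert fit.hr == pytest.approx(1.0, abs=0.15)
        assert abs(fit.z) < 2.5

    def test_all_events_in_one_group_raises(self):
        df = pd.DataFrame(
            {
                "time": [1, 2, 3, 4, 5, 6],
                "event": [1, 1, 1, 0, 0, 0],
                "group": [1, 1, 1, 0, 0, 0],
                "cluster_id": ["a", "a", "b", "b", "c", "c"],
            }
        )
        with pytest.raises(MonotoneLikelihoodError):
            cox_clustered(df)

    def test_single_group_rejected(self):
        df = pd.DataFrame(
            {"time": [1, 2], "event": [1, 1], "group": [1, 1],
             "cluster_id": ["a", "b"]}
        )
        with pytest.raises(ValueError):
            cox_clustered(df)

    def test_invariant_to_time_rescaling(self):
        spec = synthdata.in_vitro_survival_spec()
        table, _ = synthdata.simulate_survival_cohort(spec, seed=19)
        fit1 = cox_clustered(table)
        scaled = table.assign(time=table["time"] * 3.7)
        fit2 = cox_clustered(scaled)
        assert fit1.log_hr == pytest.approx(fit2.log_hr, abs=1e-12)
        assert fit1.robust_se == pytest.approx(fit2.robust_se, abs=1e-12)

    def test_singleton_cluster_sandwich_approaches_model_se(self):
        # with one neuron per cluster and independent data the robust and
        # model-based variances estimate the same quantity; at large n they
        # must agree closely
        spec = synthdata.in_vivo_survival_spec(
            frailty_sd=0.0, n_animals_per_group=4, neurons_min=500, neurons_max=500
        )
        table, _ = synthdata.simulate_survival_cohort(spec, seed=23)
        table = table.assign(cluster_id=table["neuron_id"])  # singletons
        fit = cox_clustered(table, small_sample_correction=False)
        assert fit.robust_se == pytest.approx(fit.model_se, rel=0.1)
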