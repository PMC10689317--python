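"""Evaluation: concordance, Kaplan-Meier, log-rank, stratification, NRI."""

import numpy as np
import pandas as pd
import pytest

import oracles
from radsurv.evaluation import (
    concordance_index,
    km_curve,
    log_rank,
    nri,
    stratify_and_test,
)
from radsurv.modeling import fit_cox
from radsurv.synthetic import generate_survival


class TestConcordance:
    def test_perfect_concordance(self):
        assert concordance_index([1, 2, 3], [1, 1, 1], [3, 2, 1]) == 1.0

    def test_perfect_discordance(self):
        assert concordance_index([1, 2, 3], [1, 1, 1], [1, 2, 3]) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_enumeration_with_censoring(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        t = rng.exponential(10, n)
        e = rng.integers(0, 2, n)
        s = np.round(rng.standard_normal(n), 1)  # rounding makes score ties
        if not (e == 1).any():
            e[0] = 1
        assert concordance_index(t, e, s) == oracles.harrell_c(t, e, s)

    def test_matches_lifelines(self, rng):
        from lifelines.utils import concordance_index as lifelines_c

        t = rng.exponential(10, 40)
        e = rng.integers(0, 2, 40)
        s = rng.standard_normal(40)
        e[:2] = 1
        # lifelines concordance uses predicted survival time (higher = longer)
        assert concordance_index(t, e, s) == pytest.approx(lifelines_c(t, -s, e))

    def test_uninformative_score_near_half(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 500)
        e = rng.integers(0, 2, 500)
        s = rng.standard_normal(500)
        assert concordance_index(t, e, s) == pytest.approx(0.5, abs=0.05)

    def test_bootstrap_ci_brackets_estimate(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(10, 60)
        e = np.ones(60, dtype=int)
        s = -t + rng.normal(0, 3, 60)
        c, (lo, hi) = concordance_index(t, e, s, n_boot=200, seed=0)
        assert lo <= c <= hi and 0.5 < c <= 1.0

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError):
            concordance_index([1, 1], [0, 0], [1, 2])


class TestKaplanMeier:
    def test_two_event_hand_example(self):
        table = km_curve([1, 2], [1, 1]).set_index("time")
        assert table.loc[1.0, "survival"] == pytest.approx(0.5)
        assert table.loc[2.0, "survival"] == pytest.approx(0.0)

    def test_all_censored_flat_curve(self):
        table = km_curve([3, 5, 7], [0, 0, 0])
        assert (table["survival"] == 1.0).all()

    def test_non_increasing_from_one(self, rng):
        t = rng.exponential(5, 40)
        e = rng.integers(0, 2, 40)
        table = km_curve(t, e)
        assert table["survival"].iloc[0] <= 1.0
        assert (np.diff(table["survival"]) <= 1e-12).all()

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_hand_product_limit(self, seed):
        rng = np.random.default_rng(seed)
        t = np.round(rng.exponential(5, 25), 1)  # rounding creates ties
        e = rng.integers(0, 2, 25)
        table = km_curve(t, e).set_index("time")
        for tt, s in oracles.km_product_limit(t, e).items():
            assert table.loc[tt, "survival"] == pytest.approx(s)

    def test_matches_exponential_survival(self):
        rng = np.random.default_rng(7)
        rate = 0.1
        t = rng.exponential(1 / rate, 2000)
        table = km_curve(t, np.ones(2000, dtype=int))
        mid = table.iloc[len(table) // 4]
        assert mid["survival"] == pytest.approx(np.exp(-rate * mid["time"]), abs=0.03)


class TestLogRank:
    def test_identical_groups_null(self):
        chi2, p = log_rank([1, 2, 3, 1, 2, 3], [1, 0, 1, 1, 0, 1], [0, 0, 0, 1, 1, 1])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_o_minus_e(self):
        t = np.array([2.0, 4.0, 5.0, 6.0, 9.0, 12.0])
        e = np.array([1, 1, 0, 1, 1, 1])
        g = np.array([1, 0, 1, 1, 0, 0])
        chi2, _ = log_rank(t, e, g)
        assert chi2 == pytest.approx(oracles.logrank_chi2(t, e, g), rel=1e-9)

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            log_rank([1, 2], [1, 1], [0, 0])


class TestStratification:
    def test_median_cutoff_splits_training_half(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"x": rng.standard_normal(100)})
        t, e = generate_survival(X.to_numpy(), 0.05, [1.0], censor_rate=0.2, seed=rng)
        model = fit_cox(X, t, e)
        strat = stratify_and_test(model, X, t, e)
        assert strat.high_risk.sum() == 50  # even n: exactly half above median
        assert strat.p_value is not None and strat.km_low is not None

    def test_fixed_cutoff_grouping(self):
        from radsurv.modeling import SurvivalModel

        model = SurvivalModel(features=["x"], coefficients=pd.Series({"x": 1.0}),
                              mean=pd.Series({"x": 0.0}), scale=pd.Series({"x": 1.0}),
                              cutoff=2.5)
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        strat = stratify_and_test(model, X, [5, 6, 2, 1], [1, 1, 1, 1])
        assert strat.high_risk.tolist() == [False, False, True, True]

    def test_effectful_cohort_separates_risk(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame({"x": rng.standard_normal(200)})
            t, e = generate_survival(X.to_numpy(), 0.05, [1.0], censor_rate=0.2,
                                     seed=rng)
            model = fit_cox(X, t, e)
            strat = stratify_and_test(model, X, t, e)
            if strat.p_value is not None and strat.p_value < 0.05:
                hits += 1
        assert hits >= 8


class TestNRI:
    def test_identical_models_zero(self):
        t = np.array([1.0] * 5 + [30.0] * 5)
        e = np.array([1] * 5 + [0] * 5)
        h = np.array([1, 0, 1, 0, 1, 0, 1, 0, 1, 0], bool)
        assert nri(t, e, h, h, horizon=12, n_boot=0)["nri"] == 0.0

    def test_worked_table_arithmetic(self):
        # 10 events: 4 up, 1 down; 10 non-events: 3 down, 1 up -> NRI 0.5
        t = np.array([1.0] * 10 + [30.0] * 10)
        e = np.array([1] * 10 + [0] * 10)
        hn = np.array([1, 1, 1, 1, 0, 1, 0, 0, 0, 0] + [0, 0, 0, 1, 0, 0, 0, 0, 0, 0], bool)
        ho = np.array([0, 0, 0, 0, 1, 1, 0, 0, 0, 0] + [1, 1, 1, 0, 0, 0, 0, 0, 0, 0], bool)
        r = nri(t, e, hn, ho, horizon=24, n_boot=0)
        assert r["nri"] == pytest.approx(0.5)
        assert r["counts"]["events_up"] == 4 and r["counts"]["non_events_down"] == 3

    def test_antisymmetry(self, rng):
        n = 40
        t = rng.exponential(20, n)
        e = rng.integers(0, 2, n)
        a = rng.random(n) > 0.5
        b = rng.random(n) > 0.5
        if not ((t <= 12) & (e == 1)).any():
            t[0], e[0] = 1.0, 1
        r_ab = nri(t, e, a, b, horizon=12, n_boot=0)["nri"]
        r_ba = nri(t, e, b, a, horizon=12, n_boot=0)["nri"]
        assert r_ab == pytest.approx(-r_ba)

    def test_censored_before_horizon_excluded(self):
        t = np.array([5.0, 5.0, 30.0, 30.0])
        e = np.array([1, 0, 0, 0])
        hn = np.array([1, 1, 0, 0], bool)
        ho = np.array([0, 0, 0, 1], bool)
        r = nri(t, e, hn, ho, horizon=12, n_boot=0)
        assert r["counts"]["excluded_censored_before_horizon"] == 1

    def test_truth_beats_noised_copy(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            z = rng.standard_normal(300)
            t, e = generate_survival(z[:, None], 0.03, [1.0], censor_rate=0.2, seed=rng)
            truth_groups = z > np.median(z)
            noisy = z + rng.normal(0, 2.0, 300)
            noisy_groups = noisy > np.median(noisy)
            horizon = float(np.median(t))
            try:
                r = nri(t, e, truth_groups, noisy_groups, horizon, n_boot=0)
            except ValueError:
                continue
            if r["nri"] > 0:
                wins += 1
        assert wins >= 16
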