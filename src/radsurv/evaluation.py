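"""Survival-model evaluation: Harrell's concordance index with bootstrap
confidence intervals, Kaplan-Meier curves, two-group log-rank testing,
median-cutoff risk stratification, and the two-category net reclassification
improvement (NRI) at a fixed horizon.

The NRI variant implemented here is the categorical two-group NRI: risk
categories come from each model's own training-median cutoff, event status
is taken at a fixed horizon, and subjects censored before the horizon are
excluded (their status at the horizon is unknown).  NRI values for censored
survival data are method-dependent and easily over-interpreted, so the
report also returns the raw reclassification counts behind the index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def _harrell(time, event, score) -> float:
    """Harrell's C over usable pairs (the earlier time is an event);
    score ties count 1/2."""
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    s = np.asarray(score, float)
    usable = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    n_pairs = usable.sum()
    if n_pairs == 0:
        raise ValueError("no comparable pairs")
    higher = s[:, None] > s[None, :]
    tied = s[:, None] == s[None, :]
    return float((np.sum(higher & usable) + 0.5 * np.sum(tied & usable)) / n_pairs)


def concordance_index(time, event, score, n_boot: int = 0, seed: int = 0,
                      ci_level: float = 0.95):
    """Harrell's concordance index; optionally a percentile-bootstrap CI.

    Returns C when ``n_boot`` is 0, else ``(C, (lo, hi))`` from ``n_boot``
    subject-level resamples.
    """
    c = _harrell(time, event, score)
    if n_boot <= 0:
        return c
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    s = np.asarray(score, float)
    rng = np.random.default_rng(seed)
    n = len(t)
    stats = []
    while len(stats) < n_boot:
        idx = rng.integers(0, n, n)
        try:
            stats.append(_harrell(t[idx], e[idx], s[idx]))
        except ValueError:
            continue  # resample without comparable pairs
    q = (1 - ci_level) / 2
    lo, hi = np.quantile(stats, [q, 1 - q])
    return c, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

def km_curve(time, event) -> pd.DataFrame:
    """Product-limit survival table: one row per distinct time, with the
    at-risk count, events, censorings and the survival estimate."""
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    if t.size == 0:
        raise ValueError("empty sample")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    table = kmf.event_table.copy()
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame({
        "time": table.index.to_numpy(dtype=float),
        "at_risk": table["at_risk"].to_numpy(dtype=int),
        "events": table["observed"].to_numpy(dtype=int),
        "censored": table["censored"].to_numpy(dtype=int),
        "survival": surv.reindex(table.index).to_numpy(dtype=float),
    }).reset_index(drop=True)
    return out


def log_rank(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p) with 1 df."""
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    g = np.asarray(group)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError(f"log_rank requires exactly 2 groups, got {labels.size}")
    m = g == labels[0]
    if e.sum() == 0:
        raise ValueError("no events")
    res = logrank_test(t[m], t[~m], e[m], e[~m])
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Risk stratification
# ---------------------------------------------------------------------------

@dataclass
class RiskStratification:
    score: np.ndarray
    high_risk: np.ndarray
    cutoff: float
    km_low: pd.DataFrame | None
    km_high: pd.DataFrame | None
    chi2: float | None
    p_value: float | None
    degenerate: bool


def stratify_and_test(model, X: pd.DataFrame, time, event) -> RiskStratification:
    """Apply the model's training-median cutoff, then KM + log-rank per group.

    A single-group (degenerate) split is reported without a test.
    """
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    score = model.linear_predictor(X)
    high = score > model.cutoff
    if high.all() or (~high).all() or e.sum() == 0:
        return RiskStratification(score, high, model.cutoff,
                                  km_low=None, km_high=None,
                                  chi2=None, p_value=None, degenerate=True)
    chi2, p = log_rank(t, e, high)
    return RiskStratification(
        score=score, high_risk=high, cutoff=model.cutoff,
        km_low=km_curve(t[~high], e[~high]), km_high=km_curve(t[high], e[high]),
        chi2=chi2, p_value=p, degenerate=False,
    )


# ---------------------------------------------------------------------------
# Net reclassification improvement
# ---------------------------------------------------------------------------

def _nri_point(high_new, high_old, is_event, known):
    ev = known & is_event
    ne = known & ~is_event
    if ev.sum() == 0 or ne.sum() == 0:
        raise ValueError("need both events and non-events before the horizon")
    up = high_new & ~high_old
    down = ~high_new & high_old
    nri_ev = (up[ev].sum() - down[ev].sum()) / ev.sum()
    nri_ne = (down[ne].sum() - up[ne].sum()) / ne.sum()
    return float(nri_ev + nri_ne), {
        "events": int(ev.sum()), "non_events": int(ne.sum()),
        "events_up": int(up[ev].sum()), "events_down": int(down[ev].sum()),
        "non_events_up": int(up[ne].sum()), "non_events_down": int(down[ne].sum()),
        "excluded_censored_before_horizon": int((~known).sum()),
    }


def nri(time, event, high_new, high_old, horizon: float,
        n_boot: int = 1000, seed: int = 0, ci_level: float = 0.95) -> dict:
    """Two-category NRI at a fixed horizon (months).

    ``high_new`` / ``high_old`` are each model's median-cutoff risk groups.
    Events are subjects progressing by the horizon; non-events are subjects
    followed beyond it; subjects censored before the horizon are excluded.

        NRI = [P(up|event) - P(down|event)] + [P(down|non-event) - P(up|non-event)]

    Returns the NRI, a percentile-bootstrap CI, and the reclassification
    counts (NRI for censored data is method-dependent; read it with care).
    """
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    hn = np.asarray(high_new, bool)
    ho = np.asarray(high_old, bool)
    is_event = (t <= horizon) & (e == 1)
    known = is_event | (t > horizon)
    value, counts = _nri_point(hn, ho, is_event, known)
    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = len(t)
        stats = []
        attempts = 0
        while len(stats) < n_boot and attempts < 20 * n_boot:
            attempts += 1
            idx = rng.integers(0, n, n)
            try:
                v, _ = _nri_point(hn[idx], ho[idx], is_event[idx], known[idx])
            except ValueError:
                continue
            stats.append(v)
        if stats:
            q = (1 - ci_level) / 2
            lo, hi = np.quantile(stats, [q, 1 - q])
            ci = (float(lo), float(hi))
    return {"nri": value, "ci": ci, "horizon": float(horizon), "counts": counts}


def nri_models(model_new, model_old, X_new: pd.DataFrame, X_old: pd.DataFrame,
               time, event, horizon: float, n_boot: int = 1000, seed: int = 0) -> dict:
    """NRI between two fitted models scoring the same subjects."""
    return nri(time, event,
               model_new.risk_groups(X_new), model_old.risk_groups(X_old),
               horizon, n_boot=n_boot, seed=seed)
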