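"""Prognostic model construction.

The pipeline mirrors standard radiomics practice: data cleaning, a greedy
Pearson redundancy filter (|r| > 0.8), L1-penalized Cox (LASSO-Cox)
selection with ten-fold cross-validated choice of lambda at minimum
partial-likelihood deviance, backward elimination by multivariate-Cox
p-values (retain p < 0.05), a VIF multicollinearity screen (flag > 5) and
a final multivariate Cox proportional-hazards fit with Breslow tie
handling.  The combined model decorrelates DCE features against the MR
model's linear predictor before pooling and re-selecting.

Features are standardized to training mean/SD before penalized selection;
the standardization parameters are stored on the fitted model so that
scoring new subjects reproduces training-scale risk scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class SurvivalModel:
    """A fitted Cox model over selected features.

    Stores named coefficients, the training-set standardization (mean/SD per
    selected feature), the LASSO lambda that produced the selection, and the
    training-median risk cutoff used for later risk stratification.  A model
    with no selected features is valid and scores every subject 0.
    """

    features: list[str]
    coefficients: pd.Series
    mean: pd.Series
    scale: pd.Series
    cutoff: float
    lambda_: float | None = None
    provenance: dict = field(default_factory=dict)

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        if not self.features:
            return np.zeros(len(X))
        Z = (X[self.features] - self.mean) / self.scale
        return Z.to_numpy() @ self.coefficients.to_numpy()

    def risk_groups(self, X: pd.DataFrame) -> np.ndarray:
        """High-risk iff score > cutoff; ties at the cutoff go low-risk."""
        return self.linear_predictor(X) > self.cutoff

    def to_dict(self) -> dict:
        return {
            "features": self.features,
            "coefficients": self.coefficients.to_dict(),
            "mean": self.mean.to_dict(),
            "scale": self.scale.to_dict(),
            "cutoff": self.cutoff,
            "lambda": self.lambda_,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SurvivalModel":
        return cls(
            features=list(d["features"]),
            coefficients=pd.Series(d["coefficients"], dtype=float),
            mean=pd.Series(d["mean"], dtype=float),
            scale=pd.Series(d["scale"], dtype=float),
            cutoff=float(d["cutoff"]),
            lambda_=d.get("lambda"),
            provenance=d.get("provenance", {}),
        )


# ---------------------------------------------------------------------------
# Cleaning and redundancy filtering
# ---------------------------------------------------------------------------

def clean_features(table: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop features with missing values, zero variance, or duplicated columns.

    Returns the cleaned table and the dropped names.  Idempotent.
    """
    dropped = []
    keep = []
    seen: dict[bytes, str] = {}
    for col in table.columns:
        v = table[col].to_numpy(dtype=float)
        if np.any(~np.isfinite(v)) or np.all(v == v[0]):
            dropped.append(col)
            continue
        key = v.tobytes()
        if key in seen:
            dropped.append(col)
            continue
        seen[key] = col
        keep.append(col)
    if not keep:
        raise ValueError("all features dropped during cleaning")
    return table[keep], dropped


def pearson_redundancy_filter(table: pd.DataFrame, threshold: float = 0.8
                              ) -> tuple[pd.DataFrame, list[str]]:
    """Greedy redundancy filter: scanning columns in order, drop any later
    feature whose |Pearson r| with an already-kept feature exceeds the
    threshold.  Scale-invariant; deterministic given column order."""
    cols = list(table.columns)
    if len(cols) < 2:
        return table, []
    X = table.to_numpy(dtype=float)
    sd = X.std(axis=0)
    Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    n = X.shape[0]
    kept_idx: list[int] = []
    dropped = []
    for j in range(len(cols)):
        if kept_idx:
            r = np.abs(Z[:, kept_idx].T @ Z[:, j]) / n
            r[~np.isfinite(r)] = 0.0
            if np.any(r > threshold):
                dropped.append(cols[j])
                continue
        kept_idx.append(j)
    return table[[cols[j] for j in kept_idx]], dropped


# ---------------------------------------------------------------------------
# Partial likelihood and cross-validated LASSO-Cox
# ---------------------------------------------------------------------------

def breslow_loglik(time, event, eta) -> float:
    """Breslow log partial likelihood of a linear predictor eta."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    eta = np.asarray(eta, float)
    order = np.argsort(time, kind="stable")
    t, e, h = time[order], event[order], eta[order]
    m = h.max() if h.size else 0.0
    log_risk = m + np.log(np.cumsum(np.exp(h - m)[::-1])[::-1])
    first = np.searchsorted(t, t, side="left")  # tied times share one risk set
    return float(np.sum((h - log_risk[first])[e == 1]))


def _stratified_folds(event, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Event-stratified fold assignment (every fold sees events)."""
    event = np.asarray(event, int)
    assign = np.empty(len(event), dtype=int)
    for grp in (np.flatnonzero(event == 1), np.flatnonzero(event == 0)):
        perm = rng.permutation(grp)
        assign[perm] = np.arange(len(perm)) % folds
    return assign


@dataclass
class LassoCoxResult:
    lambda_min: float
    active: list[str]
    alphas: np.ndarray
    cv_deviance: np.ndarray
    coef_at_min: pd.Series


def lasso_cox_select(X: pd.DataFrame, time, event, folds: int = 10, seed: int = 0,
                     n_alphas: int = 50, standardize: bool = True) -> LassoCoxResult:
    """L1-penalized Cox selection with cross-validated lambda.

    The lambda grid runs downward from the smallest value shrinking every
    coefficient to zero.  Lambda is chosen by K-fold (event-stratified)
    cross-validated partial-likelihood deviance at its minimum, using the
    Verweij & van Houwelingen cross-validated log partial likelihood
    CV(lambda) = sum_k [ l(beta_-k; all) - l(beta_-k; train_-k) ].
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if event.sum() < 2:
        raise ValueError("need at least 2 events")
    Xv = X.to_numpy(dtype=float)
    if standardize:
        mu, sd = Xv.mean(axis=0), Xv.std(axis=0)
        Xv = (Xv - mu) / np.where(sd > 0, sd, 1.0)
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    path_model = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_alphas,
                                        alpha_min_ratio=0.01, max_iter=200000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        path_model.fit(Xv, y)
    alphas = np.asarray(path_model.alphas_)

    folds = int(min(folds, event.sum()))
    rng = np.random.default_rng(seed)
    assign = _stratified_folds(event, folds, rng)
    cvpl = np.zeros(alphas.size)
    for k in range(folds):
        tr = assign != k
        fm = CoxnetSurvivalAnalysis(l1_ratio=1.0, max_iter=200000)
        fm.set_params(alphas=alphas)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                fm.fit(Xv[tr], Surv.from_arrays(event=event[tr].astype(bool), time=time[tr]))
        except Exception as exc:  # a fold may fail at extreme lambdas
            logger.warning("fold %d coxnet failed (%s); skipped", k, exc)
            continue
        fitted = list(fm.alphas_)
        for ai, alpha in enumerate(alphas):
            if alpha not in fitted:
                continue
            beta = fm.coef_[:, fitted.index(alpha)]
            eta_all = Xv @ beta
            cvpl[ai] += breslow_loglik(time, event, eta_all) - breslow_loglik(
                time[tr], event[tr], eta_all[tr])
    deviance = -2.0 * cvpl
    best = int(np.argmin(deviance))
    coef = path_model.coef_[:, best]
    active = [c for c, b in zip(X.columns, coef) if b != 0]
    return LassoCoxResult(
        lambda_min=float(alphas[best]),
        active=active,
        alphas=alphas,
        cv_deviance=deviance,
        coef_at_min=pd.Series(coef, index=X.columns),
    )


# ---------------------------------------------------------------------------
# Cox fitting, backward elimination, VIF
# ---------------------------------------------------------------------------

def _cox_fit(df: pd.DataFrame, penalizer: float = 0.0) -> CoxPHFitter:
    cph = CoxPHFitter(penalizer=penalizer)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    return cph


def _cox_fit_robust(df: pd.DataFrame) -> tuple[CoxPHFitter, bool]:
    """Unpenalized fit; on monotone likelihood / separation escalate a ridge
    penalty until the fit converges.  Returns (fit, penalized_flag)."""
    try:
        return _cox_fit(df), False
    except (ConvergenceError, np.linalg.LinAlgError, ValueError):
        pass
    for pen in (0.1, 1.0, 10.0):
        try:
            return _cox_fit(df, penalizer=pen), True
        except (ConvergenceError, np.linalg.LinAlgError, ValueError):
            continue
    raise ConvergenceError("Cox fit failed even with ridge penalties")


def backward_eliminate(X: pd.DataFrame, time, event, features: list[str] | None = None,
                       alpha: float = 0.05) -> list[str]:
    """Iteratively drop the single largest-p feature from a multivariate Cox
    fit until every retained feature has p < alpha or one feature remains."""
    feats = list(features if features is not None else X.columns)
    if not feats:
        return feats
    df_base = pd.DataFrame({"time": np.asarray(time, float),
                            "event": np.asarray(event, int)}, index=X.index)
    while len(feats) > 1:
        df = pd.concat([X[feats], df_base], axis=1)
        cph, penalized = _cox_fit_robust(df)
        if penalized:
            # non-convergent unpenalized fit: rank p-values under a ridge refit
            logger.warning("Cox fit needed a ridge penalty during elimination")
        pvals = cph.summary["p"]
        worst = pvals.idxmax()
        if pvals.max() < alpha:
            break
        feats.remove(worst)
    return feats


def vif_check(X: pd.DataFrame, features: list[str] | None = None,
              limit: float = 5.0) -> pd.DataFrame:
    """Variance inflation factors VIF_j = 1 / (1 - R_j^2), regressing each
    feature on the others (with intercept).  Exact collinearity -> inf."""
    feats = list(features if features is not None else X.columns)
    if len(feats) < 2:
        return pd.DataFrame({"feature": feats, "vif": [1.0] * len(feats),
                             "flagged": [False] * len(feats)})
    M = X[feats].to_numpy(dtype=float)
    n = M.shape[0]
    rows = []
    for j, name in enumerate(feats):
        yj = M[:, j]
        others = np.column_stack([np.ones(n), np.delete(M, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        sst = np.sum((yj - yj.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / sst if sst > 0 else 1.0
        vif = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"feature": name, "vif": float(vif), "flagged": bool(vif > limit)})
    return pd.DataFrame(rows)


def fit_cox(X: pd.DataFrame, time, event, features: list[str] | None = None,
            lambda_: float | None = None, provenance: dict | None = None) -> SurvivalModel:
    """Fit the final multivariate Cox model (Breslow ties) on standardized
    features and store the training-median risk cutoff.

    Monotone likelihood (perfect separation) falls back to a lightly
    penalized refit, flagged in the provenance.
    """
    feats = list(features if features is not None else X.columns)
    prov = dict(provenance or {})
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if feats and event.sum() < 2:
        raise ValueError("need at least 2 events")
    constant = [f for f in feats if X[f].std(ddof=0) == 0]
    if constant:  # a constant covariate carries no information and breaks Newton steps
        logger.warning("dropping constant feature(s) from Cox fit: %s", constant)
        prov["dropped_constant"] = constant
        feats = [f for f in feats if f not in constant]
    if not feats:
        empty = pd.Series(dtype=float)
        return SurvivalModel([], empty, empty, empty, cutoff=0.0,
                             lambda_=lambda_, provenance={**prov, "empty": True})
    mean = X[feats].mean()
    scale = X[feats].std(ddof=0).replace(0.0, 1.0)
    Z = (X[feats] - mean) / scale
    df = pd.concat([Z, pd.DataFrame({"time": time, "event": event}, index=X.index)], axis=1)
    cph, penalized = _cox_fit_robust(df)
    if penalized:
        logger.warning("Cox fit did not converge unpenalized; ridge refit used")
        prov["penalized"] = True
    coefs = cph.params_.astype(float)
    lp = Z.to_numpy() @ coefs.to_numpy()
    return SurvivalModel(
        features=feats,
        coefficients=coefs,
        mean=mean.astype(float),
        scale=scale.astype(float),
        cutoff=float(np.median(lp)),
        lambda_=lambda_,
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# Cohort splitting and the combined model
# ---------------------------------------------------------------------------

def split_cohort(time, event, ratio: float = 0.7, seed: int = 0
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Event-stratified random train/test split; returns boolean masks.

    Sizes are exact (train = round(ratio * n)); the event fraction differs
    between the parts by at most one subject.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    n = len(time)
    if n < 10:
        raise ValueError("need at least 10 subjects to split")
    rng = np.random.default_rng(seed)
    n_train = int(round(ratio * n))
    ev_idx = rng.permutation(np.flatnonzero(event == 1))
    ce_idx = rng.permutation(np.flatnonzero(event == 0))
    n_ev_train = int(round(ratio * len(ev_idx)))
    n_ce_train = n_train - n_ev_train
    n_ce_train = min(max(n_ce_train, 0), len(ce_idx))
    train = np.zeros(n, dtype=bool)
    train[ev_idx[:n_ev_train]] = True
    train[ce_idx[:n_ce_train]] = True
    test = ~train
    if event[train].sum() == 0 or event[test].sum() == 0:
        logger.warning("degenerate split (a part has no events); reshuffling")
        return split_cohort(time, event, ratio, seed + 1)
    return train, test


MR_PREDICTION = "MR_prediction"


def build_combined_model(mr_model: SurvivalModel, mr_table: pd.DataFrame,
                         dce_table: pd.DataFrame, time, event,
                         threshold: float = 0.8, folds: int = 10, seed: int = 0,
                         alpha: float = 0.05) -> SurvivalModel:
    """Fuse the MR model with DCE features.

    (1) redundancy-filter within DCE features; (2) drop DCE features with
    |r| > threshold against the MR model's linear predictor; (3) pool the
    survivors with the MR prediction as covariates; (4) LASSO-Cox select and
    backward-eliminate; (5) final Cox fit.  If every DCE feature is
    eliminated the MR model is returned unchanged, flagged in provenance.
    """
    if not len(mr_table) == len(dce_table) == len(np.asarray(time)):
        raise ValueError("subject tables are not aligned")
    mr_pred = mr_model.linear_predictor(mr_table)
    dce_clean, dropped_clean = clean_features(dce_table)
    dce_kept, dropped_redundant = pearson_redundancy_filter(dce_clean, threshold)

    sd_pred = mr_pred.std()
    mr_informative = sd_pred > 0
    if mr_informative:
        zc = (mr_pred - mr_pred.mean()) / sd_pred
        D = dce_kept.to_numpy(dtype=float)
        sd = D.std(axis=0)
        Zd = (D - D.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        r = np.abs(Zd.T @ zc) / len(zc)
        decor = [c for c, ri in zip(dce_kept.columns, r) if ri <= threshold]
    else:
        decor = list(dce_kept.columns)
    dropped_vs_mr = [c for c in dce_kept.columns if c not in decor]

    prov = {
        "dce_dropped_cleaning": dropped_clean,
        "dce_dropped_redundant": dropped_redundant,
        "dce_dropped_vs_mr_prediction": dropped_vs_mr,
    }
    if not decor:
        logger.warning("all DCE features eliminated; returning the MR model")
        out = SurvivalModel(
            features=list(mr_model.features),
            coefficients=mr_model.coefficients.copy(),
            mean=mr_model.mean.copy(), scale=mr_model.scale.copy(),
            cutoff=mr_model.cutoff, lambda_=mr_model.lambda_,
            provenance={**prov, "combined_degenerate": True},
        )
        return out

    pooled = dce_kept[decor].copy()
    if mr_informative:
        pooled[MR_PREDICTION] = mr_pred
    fallback = [MR_PREDICTION] if mr_informative else []
    sel = lasso_cox_select(pooled, time, event, folds=folds, seed=seed)
    active = sel.active if sel.active else fallback
    feats = backward_eliminate(pooled, time, event, active, alpha=alpha)
    if not feats:
        feats = fallback
    if not mr_informative:
        prov["mr_prediction_constant"] = True
    prov["vif"] = vif_check(pooled, feats).to_dict("records")
    model = fit_cox(pooled, time, event, feats, lambda_=sel.lambda_min, provenance=prov)
    return model


def combined_design(mr_model: SurvivalModel, mr_table: pd.DataFrame,
                    dce_table: pd.DataFrame) -> pd.DataFrame:
    """Covariate table for scoring a combined model on new subjects."""
    out = dce_table.copy()
    out[MR_PREDICTION] = mr_model.linear_predictor(mr_table)
    return out
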