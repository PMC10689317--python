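"""End-to-end study orchestration on a synthetic cohort.

simulate -> fit PK maps -> extract radiomic features (MR volumes and DCE
parameter maps) -> split 7:3 -> build MR / DCE / combined LASSO-Cox models
-> evaluate (C-index, risk stratification, NRI) -> render feature maps and
figures.  Every stochastic stage derives its seed from the master cohort
seed by a fixed offset, and stage outputs are cached by config hash, so a
rerun with the same config reproduces the report bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from radsurv.evaluation import concordance_index, nri_models, stratify_and_test
from radsurv.feature_map import FeatureMapConfig, compute_feature_map
from radsurv.features.extract import FeatureConfig, extract_all, extract_features
from radsurv.modeling import (
    backward_eliminate,
    build_combined_model,
    clean_features,
    combined_design,
    fit_cox,
    lasso_cox_select,
    pearson_redundancy_filter,
    split_cohort,
    vif_check,
)
from radsurv.synthetic import CohortConfig, generate_cohort
from radsurv.tofts import fit_extended_tofts_linear, pk_maps_to_volumes

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StudyConfig:
    """Full study configuration: cohort, features, model thresholds, outputs.

    DCE parameter maps live on physical scales far below MR intensities, so
    each map gets its own discretization bin width (roughly 25-50 levels over
    the plausible parameter range) while MR images use the standard width 5.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    split_ratio: float = 0.7
    split_seed: int = 101
    mr_bin_width: float = 5.0
    dce_bin_widths: tuple = (("ktrans", 0.02), ("kep", 0.05), ("ve", 0.02), ("vp", 0.005))
    filters: tuple = FeatureConfig().filters
    families: tuple = FeatureConfig().families
    corr_threshold: float = 0.8
    vif_limit: float = 5.0
    p_retain: float = 0.05
    cv_folds: int = 10
    lasso_seed: int = 202
    n_boot: int = 1000
    horizon_months: float = 24.0
    map_feature: str = "original_firstorder_Variance"
    map_window: int = 11
    n_map_subjects: int = 2
    version: str = "1"

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, sort_keys=True, default=str)

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _stage(cache_dir: Path | None, name: str, key: str, fn):
    """Run a pipeline stage with optional on-disk caching keyed by config hash."""
    if cache_dir is None:
        return fn()
    path = cache_dir / f"{name}_{key}.pkl"
    if path.exists():
        logger.info("stage %s: cache hit", name)
        with open(path, "rb") as fh:
            return pickle.load(fh)
    result = fn()
    cache_dir.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:
        pickle.dump(result, fh)
    return result


def _extract_tables(cohort, config: StudyConfig):
    mr_cfg = FeatureConfig(bin_width=config.mr_bin_width, filters=tuple(config.filters),
                           families=tuple(config.families), include_shape=True)
    dce_widths = dict(config.dce_bin_widths)
    mr_rows, dce_rows, pk_exports = [], [], []
    for s in cohort:
        pk = fit_extended_tofts_linear(s.dce, s.roi.data, clip=True)
        pk_vols = pk_maps_to_volumes(pk)
        pk_exports.append(pk_vols)
        mr_rows.append(extract_all(s.volumes, s.roi.data, mr_cfg, s.roi.spacing).rename(s.id))
        dce_feats = {}
        for pname in ("ktrans", "kep", "ve", "vp"):
            cfg_p = FeatureConfig(bin_width=dce_widths[pname], filters=tuple(config.filters),
                                  families=tuple(config.families), include_shape=False)
            feats = extract_features(pk_vols[pname].data, s.roi.data, cfg_p, s.roi.spacing)
            dce_feats.update({f"{pname}__{k}": v for k, v in feats.items()})
        dce_rows.append(pd.Series(dce_feats, dtype=float).rename(s.id))
    mr_table = pd.DataFrame(mr_rows)
    dce_table = pd.DataFrame(dce_rows)
    surv = pd.DataFrame({
        "id": [s.id for s in cohort],
        "time": [s.survival[0] for s in cohort],
        "event": [s.survival[1] for s in cohort],
    }).set_index("id")
    return mr_table, dce_table, surv, pk_exports


def _build_model(table, time, event, config: StudyConfig, redundancy: bool, seed: int):
    clean, dropped = clean_features(table)
    prov = {"dropped_cleaning_count": len(dropped)}
    if redundancy:
        clean, dropped_r = pearson_redundancy_filter(clean, config.corr_threshold)
        prov["dropped_redundant_count"] = len(dropped_r)
    sel = lasso_cox_select(clean, time, event, folds=config.cv_folds, seed=seed)
    active = sel.active if sel.active else []
    feats = backward_eliminate(clean, time, event, active, alpha=config.p_retain)
    prov["lasso_active"] = active
    if feats:
        prov["vif"] = vif_check(clean, feats, config.vif_limit).to_dict("records")
    return fit_cox(clean, time, event, feats, lambda_=sel.lambda_min, provenance=prov)


def _evaluate(model, X_train, X_test, surv_train, surv_test, config: StudyConfig, seed: int):
    out = {}
    for part, X, sv in (("train", X_train, surv_train), ("test", X_test, surv_test)):
        score = model.linear_predictor(X)
        c, ci = concordance_index(sv["time"], sv["event"], score,
                                  n_boot=config.n_boot, seed=seed)
        strat = stratify_and_test(model, X, sv["time"], sv["event"])
        out[part] = {
            "c_index": c, "c_index_ci": list(ci),
            "log_rank_chi2": strat.chi2, "log_rank_p": strat.p_value,
            "stratification_degenerate": strat.degenerate,
            "n": int(len(X)), "events": int(sv["event"].sum()),
        }
    return out


def run_study(config: StudyConfig = StudyConfig(), out_dir=None, use_cache: bool = True) -> dict:
    """Execute the full study; returns the report bundle.

    When ``out_dir`` is given, writes report.json, the model JSONs, the
    feature/survival tables and a manifest of every seed and threshold used;
    stage results are cached there keyed by the config hash.
    """
    out = Path(out_dir) if out_dir is not None else None
    cache = out / "cache" if (out is not None and use_cache) else None
    key = config.digest()

    cohort = _stage(cache, "cohort", key, lambda: generate_cohort(config.cohort))
    mr_table, dce_table, surv, pk_exports = _stage(
        cache, "features", key, lambda: _extract_tables(cohort, config))

    train, test = split_cohort(surv["time"].to_numpy(), surv["event"].to_numpy(),
                               config.split_ratio, config.split_seed)
    surv_tr, surv_te = surv[train], surv[test]
    t_tr, e_tr = surv_tr["time"].to_numpy(), surv_tr["event"].to_numpy()

    def _models():
        mr = _build_model(mr_table[train], t_tr, e_tr, config,
                          redundancy=False, seed=config.lasso_seed)
        dce = _build_model(dce_table[train], t_tr, e_tr, config,
                           redundancy=True, seed=config.lasso_seed + 1)
        combined = build_combined_model(
            mr, mr_table[train], dce_table[train], t_tr, e_tr,
            threshold=config.corr_threshold, folds=config.cv_folds,
            seed=config.lasso_seed + 2, alpha=config.p_retain)
        return mr, dce, combined

    mr_model, dce_model, combined_model = _stage(cache, "models", key, _models)

    comb_tr = combined_design(mr_model, mr_table[train], dce_table[train])
    comb_te = combined_design(mr_model, mr_table[test], dce_table[test])

    evaluation = {
        "mr": _evaluate(mr_model, mr_table[train], mr_table[test],
                        surv_tr, surv_te, config, config.lasso_seed + 10),
        "dce": _evaluate(dce_model, dce_table[train], dce_table[test],
                         surv_tr, surv_te, config, config.lasso_seed + 11),
        "combined": _evaluate(combined_model, comb_tr, comb_te,
                              surv_tr, surv_te, config, config.lasso_seed + 12),
    }
    t_te, e_te = surv_te["time"].to_numpy(), surv_te["event"].to_numpy()
    nri_results = {}
    try:
        nri_results["combined_vs_mr"] = nri_models(
            combined_model, mr_model, comb_te, mr_table[test], t_te, e_te,
            config.horizon_months, n_boot=config.n_boot, seed=config.lasso_seed + 20)
        nri_results["combined_vs_dce"] = nri_models(
            combined_model, dce_model, comb_te, dce_table[test], t_te, e_te,
            config.horizon_months, n_boot=config.n_boot, seed=config.lasso_seed + 21)
    except ValueError as exc:
        nri_results["error"] = str(exc)

    report = {
        "config_digest": key,
        "n_subjects": len(cohort),
        "n_train": int(train.sum()),
        "n_test": int(test.sum()),
        "models": {
            "mr": {"features": mr_model.features,
                   "coefficients": mr_model.coefficients.to_dict(),
                   "lambda": mr_model.lambda_, "cutoff": mr_model.cutoff},
            "dce": {"features": dce_model.features,
                    "coefficients": dce_model.coefficients.to_dict(),
                    "lambda": dce_model.lambda_, "cutoff": dce_model.cutoff},
            "combined": {"features": combined_model.features,
                         "coefficients": combined_model.coefficients.to_dict(),
                         "lambda": combined_model.lambda_, "cutoff": combined_model.cutoff},
        },
        "evaluation": evaluation,
        "nri": nri_results,
        "manifest": {
            "cohort_seed": config.cohort.seed,
            "split_seed": config.split_seed,
            "lasso_seed": config.lasso_seed,
            "thresholds": {"correlation": config.corr_threshold,
                           "vif": config.vif_limit, "p_retain": config.p_retain},
            "cv_folds": config.cv_folds,
            "horizon_months": config.horizon_months,
            "config": json.loads(config.to_json()),
        },
    }
    bundle = {
        "config": config,
        "report": report,
        "cohort": cohort,
        "pk_exports": pk_exports,
        "models": {"mr": mr_model, "dce": dce_model, "combined": combined_model},
        "tables": {"mr": mr_table, "dce": dce_table, "survival": surv,
                   "train": train, "test": test},
    }
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        for name, model in bundle["models"].items():
            (out / f"model_{name}.json").write_text(
                json.dumps(model.to_dict(), indent=1, sort_keys=True))
        mr_table.to_csv(out / "features_mr.csv")
        dce_table.to_csv(out / "features_dce.csv")
        surv.assign(split=np.where(train, "train", "test")).to_csv(out / "survival.csv")
    return bundle


def make_figures(bundle: dict, out_dir) -> list[str]:
    """Kaplan-Meier plots per model and per-subject panels of source images,
    a radiomics feature map and the four PK parameter maps."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from lifelines import KaplanMeierFitter

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config: StudyConfig = bundle["config"]
    surv = bundle["tables"]["survival"]
    written = []

    for name, model in bundle["models"].items():
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        for ax, part in zip(axes, ("train", "test")):
            part_mask = bundle["tables"][part]
            table = bundle["tables"]["mr" if name == "mr" else "dce"]
            if name == "combined":
                table = combined_design(bundle["models"]["mr"],
                                        bundle["tables"]["mr"], bundle["tables"]["dce"])
            X = table[part_mask]
            sv = surv[part_mask]
            high = model.risk_groups(X)
            kmf = KaplanMeierFitter()
            for grp, lab in ((~high, "low risk"), (high, "high risk")):
                if grp.sum() == 0:
                    continue
                kmf.fit(sv["time"][grp], sv["event"][grp], label=lab)
                kmf.plot_survival_function(ax=ax, ci_show=False)
            ax.set_title(f"{name} model, {part} set")
            ax.set_xlabel("months")
            ax.set_ylabel("progression-free survival")
        path = out / f"km_{name}.png"
        fig.savefig(path)
        plt.close(fig)
        written.append(str(path))

    map_cfg = FeatureMapConfig(window=config.map_window, step=1,
                               feature=config.map_feature,
                               bin_width=config.mr_bin_width)
    for s, pk_vols in list(zip(bundle["cohort"], bundle["pk_exports"]))[:config.n_map_subjects]:
        mid = int(np.argmax(s.roi.data.sum(axis=(0, 1))))  # most-ROI slice
        panels = [("PD-w", s.volumes["PD"].data, "gray", ""),
                  ("CET1-w", s.volumes["CET1"].data, "gray", "")]
        maps = compute_feature_map(s.volumes["PD"].data, s.roi.data, map_cfg)
        fmap = next((m for m in maps if m.slice_index == mid), maps[len(maps) // 2])
        units = {"ktrans": "min$^{-1}$", "kep": "min$^{-1}$", "ve": "fraction", "vp": "fraction"}
        fig, axes = plt.subplots(2, 4, figsize=(14, 7))
        for ax, (title, vol, cmap, unit) in zip(
                axes.flat,
                panels + [(f"{p} ({units[p]})", pk_vols[p].data, "jet", units[p])
                          for p in ("ktrans", "kep", "ve", "vp")]):
            im = ax.imshow(vol[:, :, mid].T, cmap=cmap, origin="lower")
            if cmap != "gray":
                fig.colorbar(im, ax=ax, fraction=0.046)
            ax.set_title(title, fontsize=9)
            ax.axis("off")
        ax = axes.flat[6]
        masked = np.ma.masked_invalid(fmap.values)
        ax.imshow(s.volumes["PD"].data[:, :, mid].T, cmap="gray", origin="lower")
        im = ax.imshow(masked.T, cmap="jet", origin="lower", alpha=0.85)
        fig.colorbar(im, ax=ax, fraction=0.046)
        ax.set_title(f"feature map: {config.map_feature}", fontsize=8)
        ax.axis("off")
        t, e = s.survival
        axes.flat[7].axis("off")
        axes.flat[7].text(0.05, 0.5, f"{s.id}\nPFS {t:.1f} months\n"
                          f"{'progressed' if e else 'censored'}", fontsize=11)
        path = out / f"panel_{s.id}.png"
        fig.savefig(path)
        plt.close(fig)
        written.append(str(path))
    return written
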