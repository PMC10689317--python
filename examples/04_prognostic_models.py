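"""Build and evaluate a LASSO-Cox prognostic model on simulated features.

Two of fifty standardized features carry true hazard signal (beta = 1).
The pipeline: 10-fold cross-validated LASSO-Cox selection at minimum
partial-likelihood deviance, backward elimination by Cox p-values
(retain p < 0.05), VIF screen, final Cox fit, held-out evaluation.
"""

import numpy as np
import pandas as pd

from radsurv import (
    backward_eliminate,
    concordance_index,
    fit_cox,
    generate_survival,
    lasso_cox_select,
    split_cohort,
    stratify_and_test,
    vif_check,
)

rng = np.random.default_rng(4)
X = pd.DataFrame(rng.standard_normal((200, 50)), columns=[f"f{i}" for i in range(50)])
beta = np.zeros(50)
beta[:2] = 1.0  # f0 and f1 are truly prognostic
time, event = generate_survival(X.to_numpy(), h0=0.02, beta=beta,
                                censor_rate=0.3, seed=rng)

train, test = split_cohort(time, event, ratio=0.7, seed=0)
sel = lasso_cox_select(X[train], time[train], event[train], folds=10, seed=0)
feats = backward_eliminate(X[train], time[train], event[train], sel.active)
model = fit_cox(X[train], time[train], event[train], feats, lambda_=sel.lambda_min)

print(f"lambda_min = {sel.lambda_min:.4f}; LASSO kept {len(sel.active)} features; "
      f"backward elimination kept {feats}")
print(vif_check(X[train], feats).to_string(index=False))

c_tr, ci_tr = concordance_index(time[train], event[train],
                                model.linear_predictor(X[train]), n_boot=500, seed=1)
c_te, ci_te = concordance_index(time[test], event[test],
                                model.linear_predictor(X[test]), n_boot=500, seed=1)
print(f"\ntrain C-index {c_tr:.3f} (95% CI {ci_tr[0]:.3f}-{ci_tr[1]:.3f})")
print(f"test  C-index {c_te:.3f} (95% CI {ci_te[0]:.3f}-{ci_te[1]:.3f})")

strat = stratify_and_test(model, X[test], time[test], event[test])
print(f"risk stratification at the training-median cutoff: "
      f"log-rank chi2 = {strat.chi2:.2f}, p = {strat.p_value:.2g}")
print("\nA test C-index well above 0.5 and a small log-rank p show the model "
      "recovered the planted prognostic signal on held-out subjects.")
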