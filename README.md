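# lspls

**Logistic classification from combined clinical + high-dimensional genomic
data, with PLS compression of the genomic block only.**

Biomedical prediction studies routinely collect a few clinical covariates
(age, grade, receptor status, …) alongside thousands of genomic measurements
(expression, copy-number alterations, …) on the same patients, with a binary
endpoint such as therapy response or survival status at a landmark.  Fitting
a logistic model to the merged data directly is impossible when p ≫ n, yet
compressing *everything* throws away the interpretability and known
predictive value of the clinical variables.  This package implements the
LS-PLS ("least squares – partial least squares") family of one-step
clinico-genomic classifiers: the clinical design `D` enters the logistic
model at full resolution by (weighted) least squares while the genomic
block `X`, orthogonalized against the clinical design, is compressed to κ
partial-least-squares components.

## Model

With `D̃ = [1 D]`, the Gaussian core is

```
X_orth = (I − D̃(D̃ᵀD̃)⁻¹D̃ᵀ) X            # genomic info not already in D
T      = X_orth V                        # κ PLS1 scores against the residual
ŷ      = D̃ γ̂^D̃ + T γ̂^T,    γ̂^X = V γ̂^T
```

and three extensions carry it to the logistic model
`P(Y=1|d,x) = h(η)`, `h(η) = 1/(1+e^{−η})`:

| method | construction | converges? |
|---|---|---|
| `LSPLSIRLS` | LS-PLS on the 0/1 response for scores, then IRLS on `[D T]` | not guaranteed (separation) |
| `IRLSPLS` | IRLS loop with each weighted LS solve replaced by weighted LS-PLS | not guaranteed (no objective) |
| `RLSPLS` | ridge-IRLS on `[D X]` (genomic penalty only) → pseudo-response `z∞`, weights `W∞`; one weighted LS-PLS | yes, by construction |

Baselines with the same interface: `ClinicalGLM` (clinical only), `RPLS`
(genomic only, ridge + weighted PLS), `LSPCR` (unsupervised PCA scores +
clinical, by IRLS).  Sure-independence screening (`sis_screen`) cuts p to
`p_red` by marginal logistic coefficients; `cv_select` picks κ and the ridge
λ by stratified fivefold cross-validation.  All classifiers follow the
scikit-learn estimator API and compose with its model-selection tools; the
first `n_clinical` columns of the feature matrix are the clinical block.

## Worked example

```python
import numpy as np
from lspls import (SimulationConfig, simulate_dataset, sis_screen, cv_select,
                   RLSPLS, lambda_grid_log10, misclassification_rate, auc)

config = SimulationConfig(seed=7)          # n=100 train / 450 test, p=1000
ds = simulate_dataset(config, replicate_id=0)

keep = sis_screen(ds.Y_train, ds.X_train, p_red=500).selected
Xtr = np.hstack([ds.D_train, ds.X_train[:, keep]])
Xte = np.hstack([ds.D_test, ds.X_test[:, keep]])

sel = cv_select(RLSPLS(n_clinical=4), Xtr, ds.Y_train,
                kappa_grid=[1, 2, 3, 4], lambda_grid=lambda_grid_log10(),
                seed=0)
model = RLSPLS(n_clinical=4, kappa=sel.kappa_star, lam=sel.lambda_star)
model.fit(Xtr, ds.Y_train)

pi = model.predict_proba(Xte)[:, 1]
yhat = model.predict(Xte)
print(f"selected kappa={sel.kappa_star}, lambda={sel.lambda_star:g}, "
      f"converged={model.converged_}")
print(f"test misclassification = {misclassification_rate(ds.Y_test, yhat):.3f}")
print(f"test AUC               = {auc(ds.Y_test, pi):.3f}")
print(f"clinical coefficients  = {np.round(model.coef_clinical_, 3)}")
```

prints

```
selected kappa=1, lambda=10, converged=True
test misclassification = 0.278
test AUC               = 0.696
clinical coefficients  = [-0.036  0.201  0.165 -0.036]
```

Cross-validation settled on a single PLS component with moderate shrinkage;
the fit converged (R-LS-PLS always does), the test error sits near the
≈0.25 class prevalence of this hard n=100 design while the AUC of 0.70
shows genuine discrimination, and the clinical coefficients are shrunk
relative to their true value 0.5 because part of the clinical signal is
absorbed by correlated genomic components.

A command-line interface covers the same workflow on CSV/TSV files
(`lspls simulate`, `lspls fit`, `lspls predict`, `lspls benchmark`); run
`lspls --help`.

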