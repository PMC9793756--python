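"""Full-spectrum PLS calibration with MCCV-chosen latent variables.

Fits a PLS1 model for the sunflower-oil content on the training half of a
synthetic dataset, choosing the latent-variable count by Monte Carlo
cross-validation, then predicts the held-out half.
"""

import gwopls as g

ds = g.default_benchmark_dataset(seed=3, step=5.0)
train, test = g.split_train_predict(ds, 0.5, seed=3)
X, y = g.dataset_xy(train, "sunflower")
Xte, yte = g.dataset_xy(test, "sunflower")

cv = g.CVConfig(n_splits=20, seed=3)
n_lv = g.select_n_lv(X, y, max_lv=8, cv=cv)
print(f"latent variables chosen by MCCV: {n_lv}")

model = g.fit_pls(X, y, n_lv)
y_hat = g.predict(model, Xte)
print(f"RMSEP = {g.rmse(yte, y_hat):.4f} % g/g")
print(f"R^2   = {g.r_squared(yte, y_hat):.4f}")
# RMSEP is the root mean squared error on the independent prediction set;
# R^2 close to 1 means the model explains nearly all target variance.
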