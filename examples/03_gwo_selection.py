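"""Wavelength selection with the discretized grey wolf optimizer.

Runs GWO-PLS on the training half of a synthetic dataset, shows the
monotone alpha-fitness trajectory, the selected wavelengths, and the
prediction improvement over the full spectrum.
"""

import numpy as np

import gwopls as g

ds = g.default_benchmark_dataset(seed=11, step=5.0)
train, test = g.split_train_predict(ds, 0.5, seed=11)
X, y = g.dataset_xy(train, "peanut")
Xte, yte = g.dataset_xy(test, "peanut")

config = g.GWOConfig(n_wolves=20, t_max=40, seed=1, n_lv=4,
                     cv=g.CVConfig(n_splits=12, seed=1))
res = g.gwo_select(X, y, config)

traj = res.alpha_trajectory
print(f"alpha RMSECV: start {traj[0]:.4f} -> final {traj[-1]:.4f} "
      f"(non-increasing: {bool(np.all(np.diff(traj) <= 0))})")
print(f"selected {res.n_selected} of {X.shape[1]} channels")
nm = ds.spectra.wavelengths[res.selected_indices]
print(f"selected wavelengths span {nm.min():.0f}-{nm.max():.0f} nm")

y_full = g.predict(g.fit_pls(X, y, 4), Xte)
y_sel = g.predict(res.final_model, Xte[:, res.selected_indices])
print(f"RMSEP full spectrum : {g.rmse(yte, y_full):.4f}")
print(f"RMSEP GWO selection : {g.rmse(yte, y_sel):.4f}")
# The selected-channel model predicts the independent set more accurately
# with ~1/3 of the channels: the optimizer discards noise-dominated and
# redundant regions of the spectrum.
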