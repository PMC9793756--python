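"""Repeated-run method comparison and optimizer parameter sweeps.

Reproduces the benchmarking protocol: 20 independent runs per stochastic
selector on a fixed train/prediction split, summarized as mean (S.D.) of
RMSEP and R^2 with selected-variable counts; then sweeps the iteration
budget (by trajectory slicing of one long run) and the pack size.
"""

import gwopls as g

ds = g.default_benchmark_dataset(seed=11, step=5.0)
train, test = g.split_train_predict(ds, 0.5, seed=11)
tr = g.dataset_xy(train, "sunflower")
te = g.dataset_xy(test, "sunflower")

out = g.compare_methods(
    tr, te, ["pls", "mcuve", "rt", "gwo"], n_runs=5, base_seed=0, n_lv=4,
    cv=g.CVConfig(n_splits=12, seed=0),
    gwo_params=dict(n_wolves=20, t_max=40),
    mcuve_params=dict(n_mc=100),
    rt_params=dict(n_perm=99),
)
print(g.format_comparison_table(out))
print()

df_t = g.sweep_iterations(tr, [5, 10, 20, 40], n_wolves=20, seed=2, n_lv=4,
                          cv=g.CVConfig(n_splits=12, seed=2))
print("iteration sweep (alpha RMSECV, non-increasing in t):")
print(df_t.to_string(index=False))
plateau = g.plateau_iteration(
    g.gwo_select(*tr, g.GWOConfig(n_wolves=20, t_max=40, seed=2, n_lv=4,
                                  cv=g.CVConfig(n_splits=12, seed=2))).alpha_trajectory
)
print(f"trajectory stabilizes at t = {plateau}")
print()

df_n = g.sweep_wolves(tr, [5, 10, 20], t_max=15, seed=2, n_lv=4,
                      cv=g.CVConfig(n_splits=12, seed=2))
print("pack-size sweep (larger packs search better, time grows ~linearly):")
print(df_n.to_string(index=False))
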