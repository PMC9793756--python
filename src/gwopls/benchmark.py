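"""Evaluation harness: parameter sweeps, pack diagnostics and the
repeated-run method comparison.

The headline protocol mirrors standard chemometric benchmarking of
stochastic selectors: each method selects wavelengths on the training set,
refits PLS on the selection, predicts the independent prediction set, and
the whole cycle is repeated over independent seeds; RMSEP and R^2 are
summarized by mean and sample standard deviation, with min/mean/max of the
selected-variable counts.  Full-spectrum PLS involves no random resampling
and therefore runs once with zero standard deviation.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baselines import mcuve_select, rt_select
from .containers import SpectrumSet, TargetVector
from .gwo import GWOConfig, SelectionResult, gwo_select
from .pls import CVConfig, fit_pls, predict, r_squared, rmse, select_n_lv
from .simulate import SyntheticDataset

__all__ = [
    "RunSummary",
    "compare_methods",
    "format_comparison_table",
    "summaries_to_json",
    "sweep_iterations",
    "sweep_wolves",
    "pack_snapshot",
    "plateau_iteration",
]

KNOWN_METHODS = ("pls", "mcuve", "rt", "gwo")


@dataclass
class RunSummary:
    """Per-method benchmark record: raw per-run metrics plus aggregates
    (aggregates are always recomputable from ``runs``)."""

    method: str
    runs: list[dict] = field(default_factory=list)

    def _col(self, key: str) -> np.ndarray:
        return np.array([r[key] for r in self.runs], dtype=float)

    @property
    def mean_rmsep(self) -> float:
        return float(self._col("rmsep").mean())

    @property
    def sd_rmsep(self) -> float:
        v = self._col("rmsep")
        return float(v.std(ddof=1)) if v.size > 1 else 0.0

    @property
    def mean_r2(self) -> float:
        return float(self._col("r2").mean())

    @property
    def sd_r2(self) -> float:
        v = self._col("r2")
        return float(v.std(ddof=1)) if v.size > 1 else 0.0

    @property
    def mean_n_selected(self) -> float:
        return float(self._col("n_selected").mean())

    @property
    def min_n_selected(self) -> int:
        return int(self._col("n_selected").min())

    @property
    def max_n_selected(self) -> int:
        return int(self._col("n_selected").max())

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "runs": self.runs,
            "mean_rmsep": self.mean_rmsep,
            "sd_rmsep": self.sd_rmsep,
            "mean_r2": self.mean_r2,
            "sd_r2": self.sd_r2,
            "mean_n_selected": self.mean_n_selected,
            "min_n_selected": self.min_n_selected,
            "max_n_selected": self.max_n_selected,
        }


def _run_method(
    method: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    seed: int,
    n_lv: int,
    cv_template: CVConfig,
    gwo_params: dict,
    mcuve_params: dict,
    rt_params: dict,
) -> SelectionResult:
    cv = CVConfig(cv_template.n_splits, cv_template.calibration_fraction, seed)
    if method == "pls":
        p = X_train.shape[1]
        mask = np.ones(p, dtype=np.int8)
        model = fit_pls(X_train, y_train, min(n_lv, p, len(y_train) - 1), mask=mask)
        return SelectionResult(mask, np.asarray([]), model, p)
    if method == "gwo":
        config = GWOConfig(seed=seed, n_lv=n_lv, cv=cv, **gwo_params)
        return gwo_select(X_train, y_train, config)
    if method == "mcuve":
        return mcuve_select(X_train, y_train, n_lv, cv=cv, **mcuve_params)
    if method == "rt":
        return rt_select(X_train, y_train, n_lv, cv=cv, **rt_params)
    raise ValueError(f"unknown method {method!r}; known: {KNOWN_METHODS}")


def compare_methods(
    train: tuple,
    test: tuple,
    methods: list[str],
    n_runs: int = 20,
    base_seed: int = 0,
    n_lv: int | None = None,
    max_lv: int = 10,
    cv: CVConfig | None = None,
    gwo_params: dict | None = None,
    mcuve_params: dict | None = None,
    rt_params: dict | None = None,
) -> dict[str, RunSummary]:
    """Repeated-run comparison of selectors on a train/prediction split.

    ``train`` and ``test`` are (X, y) pairs (arrays, SpectrumSet/
    TargetVector, or a SyntheticDataset plus component name — see
    :func:`dataset_xy`).  Stochastic methods run ``n_runs`` times with
    seeds ``base_seed .. base_seed + n_runs - 1`` (both the selector and
    its CV splits are re-seeded per run); deterministic full-spectrum PLS
    runs once.  When ``n_lv`` is None it is chosen once on the full
    training spectrum by MCCV.
    """
    X_train, y_train = _xy(train)
    X_test, y_test = _xy(test)
    cv = cv or CVConfig()
    if n_lv is None:
        cap = min(max_lv, X_train.shape[0] - 2, X_train.shape[1])
        n_lv = select_n_lv(X_train, y_train, cap, cv)

    summaries: dict[str, RunSummary] = {}
    for method in methods:
        if method not in KNOWN_METHODS:
            raise ValueError(f"unknown method {method!r}; known: {KNOWN_METHODS}")
        reps = 1 if method == "pls" else n_runs
        summary = RunSummary(method=method)
        for i in range(reps):
            seed = base_seed + i
            t0 = time.perf_counter()
            result = _run_method(
                method, X_train, y_train, seed, n_lv, cv,
                gwo_params or {}, mcuve_params or {}, rt_params or {},
            )
            cols = np.flatnonzero(result.best_mask)
            y_hat = predict(result.final_model, X_test[:, cols])
            summary.runs.append(
                {
                    "seed": seed,
                    "rmsep": rmse(y_test, y_hat),
                    "r2": r_squared(y_test, y_hat),
                    "n_selected": int(result.n_selected),
                    "wall_time_s": time.perf_counter() - t0,
                }
            )
        summaries[method] = summary
    return summaries


def _xy(data) -> tuple[np.ndarray, np.ndarray]:
    X, y = data
    if isinstance(X, SpectrumSet):
        X = X.absorbance
    if isinstance(y, TargetVector):
        y = y.values
    return np.atleast_2d(np.asarray(X, dtype=float)), np.asarray(y, dtype=float).ravel()


def dataset_xy(dataset: SyntheticDataset, component: str) -> tuple[np.ndarray, np.ndarray]:
    """Convenience accessor: (absorbance matrix, target vector) for one
    component of a synthetic dataset."""
    return dataset.spectra.absorbance, dataset.targets[component].values


def format_comparison_table(summaries: dict[str, RunSummary]) -> str:
    """Aligned text table: method, variable counts, RMSEP (S.D.),
    R^2 (S.D.)."""
    header = f"{'Method':<10}{'Variables mean (min-max)':<28}{'RMSEP (S.D.)':<22}{'R2 (S.D.)':<20}"
    lines = [header, "-" * len(header)]
    for s in summaries.values():
        nvar = f"{s.mean_n_selected:.1f} ({s.min_n_selected}-{s.max_n_selected})"
        lines.append(
            f"{s.method:<10}{nvar:<28}"
            f"{s.mean_rmsep:.4f} ({s.sd_rmsep:.4f})    "
            f"{s.mean_r2:.4f} ({s.sd_r2:.4f})"
        )
    return "\n".join(lines)


def summaries_to_json(summaries: dict[str, RunSummary], include_timing: bool = False) -> str:
    """Machine-readable summary.  Timing fields are stripped by default so
    the output is byte-identical for a fixed base seed."""
    payload = {}
    for name, s in summaries.items():
        d = s.to_dict()
        if not include_timing:
            d["runs"] = [
                {k: v for k, v in r.items() if k != "wall_time_s"} for r in d["runs"]
            ]
        payload[name] = d
    return json.dumps(payload, indent=2, sort_keys=True)


def sweep_iterations(
    train: tuple,
    t_values: list[int],
    n_wolves: int = 20,
    seed: int = 0,
    n_lv: int = 5,
    cv: CVConfig | None = None,
    gwo_params: dict | None = None,
) -> pd.DataFrame:
    """Alpha RMSECV as a function of the iteration budget.

    A single run at ``max(t_values)`` is performed and its alpha trajectory
    sliced at each requested t — equivalent to independent budgets because
    the greedy memory makes the trajectory the running best.
    """
    X, y = _xy(train)
    t_values = sorted(set(int(t) for t in t_values))
    if min(t_values) < 1:
        raise ValueError("iteration budgets must be >= 1")
    config = GWOConfig(
        n_wolves=n_wolves,
        t_max=max(t_values),
        seed=seed,
        n_lv=n_lv,
        cv=cv or CVConfig(seed=seed),
        **(gwo_params or {}),
    )
    result = gwo_select(X, y, config)
    return pd.DataFrame(
        {"t_max": t_values,
         "rmsecv": [result.alpha_trajectory[t] for t in t_values]}
    )


def plateau_iteration(trajectory: np.ndarray, tol: float = 1e-9) -> int:
    """Smallest t at which the alpha trajectory is within ``tol`` of its
    final value (the iteration where RMSECV stabilizes)."""
    traj = np.asarray(trajectory, dtype=float)
    final = traj[-1]
    hits = np.flatnonzero(traj - final <= tol)
    return int(hits[0])


def sweep_wolves(
    train: tuple,
    n_values: list[int],
    t_max: int = 50,
    seed: int = 0,
    n_lv: int = 5,
    cv: CVConfig | None = None,
    gwo_params: dict | None = None,
) -> pd.DataFrame:
    """Final alpha RMSECV (and wall time, informational only) for a range
    of pack sizes."""
    X, y = _xy(train)
    rows = []
    for n in n_values:
        if n < 3:
            raise ValueError("pack size must be >= 3")
        config = GWOConfig(
            n_wolves=int(n),
            t_max=t_max,
            seed=seed,
            n_lv=n_lv,
            cv=cv or CVConfig(seed=seed),
            **(gwo_params or {}),
        )
        t0 = time.perf_counter()
        result = gwo_select(X, y, config)
        rows.append(
            {
                "n_wolves": int(n),
                "rmsecv": float(result.alpha_trajectory[-1]),
                "wall_time_s": time.perf_counter() - t0,
            }
        )
    return pd.DataFrame(rows)


def pack_snapshot(history: np.ndarray, iterations: list[int]) -> tuple[pd.DataFrame, dict[int, int]]:
    """Per-wolf RMSECV at chosen iterations of a recorded run.

    ``history`` is the (t_max + 1, n_wolves) fitness record of a run with
    ``record_history=True``; iteration 0 is the initial pack.  Returns a
    (wolves x iterations) table and, per column, the index of the alpha
    wolf (the column minimum).
    """
    hist = np.asarray(history, dtype=float)
    table = {}
    alphas = {}
    for t in iterations:
        if not (0 <= t < hist.shape[0]):
            raise ValueError(f"iteration {t} outside recorded history")
        table[t] = hist[t]
        alphas[t] = int(np.argmin(hist[t]))
    df = pd.DataFrame(table)
    df.index.name = "wolf"
    return df, alphas
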