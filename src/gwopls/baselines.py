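"""Baseline wavelength selectors: MCUVE-PLS and RT-PLS.

Monte Carlo uninformative variable elimination (MCUVE) scores each channel
by the stability of its PLS regression coefficient — mean over standard
deviation across many fits on random sub-calibration sets — and keeps the
top-ranked channels, with the kept count chosen by an RMSECV scan.

The randomization test (RT) assesses each channel's coefficient against a
null distribution obtained by refitting PLS on permuted responses; channels
whose add-one-smoothed permutation p-value falls at or below the
significance level are kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .gwo import SelectionResult
from .pls import (
    CVConfig,
    _as_matrix,
    _as_vector,
    fit_pls,
    mccv_rmsecv,
)

__all__ = ["StabilityProfile", "mcuve_select", "rt_select"]

_STABILITY_SENTINEL = 1.0e12


@dataclass
class StabilityProfile:
    """Per-variable selection statistic: MCUVE stability (mean/sd of the
    PLS coefficient) or RT permutation p-value."""

    statistic: np.ndarray
    method: str
    n_resamples: int

    def __post_init__(self) -> None:
        self.statistic = np.asarray(self.statistic, dtype=float).ravel()
        if self.method == "rt" and np.any(
            (self.statistic < 0) | (self.statistic > 1)
        ):
            raise ValueError("RT p-values must lie in [0, 1]")


def _default_candidate_counts(n_vars: int) -> list[int]:
    counts = [k for k in range(10, min(200, n_vars) + 1, 10)]
    if not counts:
        counts = list(range(1, n_vars + 1))
    return counts


def mcuve_select(
    X,
    y,
    n_lv: int,
    n_mc: int = 500,
    cv: CVConfig | None = None,
    candidate_counts: list[int] | None = None,
) -> SelectionResult:
    """MCUVE-PLS wavelength selection.

    ``n_mc`` PLS models are fit on random 80% sub-calibration sets (drawn
    from a stream derived from ``cv.seed`` so it is decoupled from the
    RMSECV splits).  Channels are ranked by absolute stability and, for
    each candidate kept-count, the top channels are scored by RMSECV; the
    count with the lowest RMSECV wins (ties toward fewer channels).
    """
    if n_mc < 2:
        raise ValueError("n_mc must be >= 2")
    Xm = _as_matrix(X)
    yv = _as_vector(y)
    n, p = Xm.shape
    cv = cv or CVConfig()
    if candidate_counts is None:
        candidate_counts = _default_candidate_counts(p)
    candidate_counts = sorted({min(k, p) for k in candidate_counts if k >= 1})
    if not candidate_counts:
        raise ValueError("no feasible candidate counts")

    rng = np.random.default_rng(np.random.SeedSequence([cv.seed, 0x5B]))
    n_sub = max(2, int(np.floor(0.8 * n)))
    k_fit = min(n_lv, n_sub - 1, p)
    coefs = np.empty((n_mc, p))
    for i in range(n_mc):
        idx = rng.permutation(n)[:n_sub]
        model = fit_pls(Xm[idx], yv[idx], k_fit)
        coefs[i] = model.coefficients

    mean = coefs.mean(axis=0)
    sd = coefs.std(axis=0, ddof=1)
    stability = np.empty(p)
    zero_sd = sd <= 0
    if np.any(zero_sd):
        warnings.warn(
            f"{int(zero_sd.sum())} coefficient(s) had zero spread across "
            "resamples; stability set to a signed sentinel",
            stacklevel=2,
        )
        stability[zero_sd] = np.sign(mean[zero_sd]) * _STABILITY_SENTINEL
    ok = ~zero_sd
    stability[ok] = mean[ok] / sd[ok]

    order = np.argsort(-np.abs(stability), kind="stable")
    best_k, best_rmsecv = None, np.inf
    for k in candidate_counts:
        cols = np.sort(order[:k])
        k_lv = min(n_lv, cols.size)
        value = mccv_rmsecv(Xm[:, cols], yv, k_lv, cv)
        if value < best_rmsecv:
            best_k, best_rmsecv = k, value

    cols = np.sort(order[:best_k])
    mask = np.zeros(p, dtype=np.int8)
    mask[cols] = 1
    model = fit_pls(Xm[:, cols], yv, min(n_lv, cols.size, n - 1), mask=mask)
    return SelectionResult(
        best_mask=mask,
        alpha_trajectory=np.asarray([best_rmsecv]),
        final_model=model,
        n_selected=int(mask.sum()),
        profile=StabilityProfile(stability, "mcuve", n_mc),
    )


def rt_select(
    X,
    y,
    n_lv: int,
    n_perm: int = 199,
    alpha_level: float = 0.05,
    cv: CVConfig | None = None,
) -> SelectionResult:
    """RT-PLS wavelength selection by coefficient permutation test.

    For each channel, p = (1 + #{|b_perm| >= |b|}) / (n_perm + 1); channels
    with p <= ``alpha_level`` are kept.  If nothing survives, the single
    smallest-p channel is kept so the downstream PLS model is always
    defined.  The permutation RNG stream is independent of the CV stream.
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19")
    Xm = _as_matrix(X)
    yv = _as_vector(y)
    n, p = Xm.shape
    cv = cv or CVConfig()
    k_fit = min(n_lv, n - 1, p)
    b_obs = np.abs(fit_pls(Xm, yv, k_fit).coefficients)

    rng = np.random.default_rng(np.random.SeedSequence([cv.seed, 0xA7]))
    exceed = np.zeros(p)
    for _ in range(n_perm):
        y_perm = yv[rng.permutation(n)]
        if np.ptp(y_perm) <= 0:  # cannot happen unless y constant
            raise ValueError("constant y cannot be permuted into a valid target")
        b_perm = np.abs(fit_pls(Xm, y_perm, k_fit).coefficients)
        exceed += b_perm >= b_obs
    p_values = (1.0 + exceed) / (n_perm + 1.0)

    keep = p_values <= alpha_level
    if not keep.any():
        keep[np.argmin(p_values)] = True
    cols = np.flatnonzero(keep)
    mask = np.zeros(p, dtype=np.int8)
    mask[cols] = 1
    model = fit_pls(Xm[:, cols], yv, min(n_lv, cols.size, n - 1), mask=mask)
    rmsecv = mccv_rmsecv(Xm[:, cols], yv, min(n_lv, cols.size), cv)
    return SelectionResult(
        best_mask=mask,
        alpha_trajectory=np.asarray([rmsecv]),
        final_model=model,
        n_selected=int(mask.sum()),
        profile=StabilityProfile(p_values, "rt", n_perm),
    )
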