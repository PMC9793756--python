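"""Discretized grey wolf optimizer for wavelength selection.

The optimizer encodes a wavelength subset as a binary vector q over the
spectral channels (q_i = 1 means channel i enters the PLS model).  A pack
of n wolves carries real-valued positions that move according to the
encircling/hunting rules of the grey wolf optimizer — each wolf is pulled
toward the three current best solutions (alpha, beta, delta) — and after
every move the continuous positions are discretized through a steep
logistic transfer function with stochastic thresholding.  Fitness is the
Monte Carlo cross-validated RMSE (RMSECV) of a PLS model restricted to the
selected channels; lower is better.  Each wolf keeps a greedy personal
memory: a move that worsens its fitness is rejected, so the alpha fitness
trajectory is non-increasing by construction.

Position update, for coefficient ``a`` shrinking linearly from 2 to 0 over
the run and fresh uniforms r1, r2 per wolf, leader and coordinate::

    A = 2 a r1 - a,  C = 2 r2
    D_L = |C x_L - x|,   X_L = x_L - A D_L     for L in {alpha, beta, delta}
    x_new = (X_alpha + X_beta + X_delta) / 3

Continuous positions are not clipped; the logistic transfer saturates any
excursion outside [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import SpectrumSet, TargetVector
from .pls import (
    CVConfig,
    PLSModel,
    _as_matrix,
    _as_vector,
    draw_mccv_splits,
    fit_pls,
    mccv_rmsecv_path,
)

__all__ = [
    "GWOConfig",
    "WolfPack",
    "SelectionResult",
    "FitnessEvaluator",
    "convergence_coefficient",
    "discretize",
    "rank_pack",
    "init_pack",
    "update_positions",
    "evaluate_fitness",
    "gwo_select",
]


@dataclass(frozen=True)
class GWOConfig:
    """Settings for one optimizer run.

    ``n_wolves`` and ``t_max`` are the only parameters the optimizer itself
    exposes; everything else configures the fitness function (PLS latent
    variables and the MCCV scheme) or the discretization transfer.
    """

    n_wolves: int = 75
    t_max: int = 100
    seed: int = 0
    n_lv: int = 5
    cv: CVConfig = field(default_factory=CVConfig)
    empty_mask_penalty: float = 1.0e6
    transfer_slope: float = 10.0
    transfer_center: float = 0.5
    deterministic_discretize: bool = False
    record_history: bool = False

    def __post_init__(self) -> None:
        if self.n_wolves < 3:
            raise ValueError("need at least 3 wolves (alpha, beta, delta)")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")


@dataclass
class WolfPack:
    """Pack state: continuous positions, their binary images, fitness and
    the alpha/beta/delta ranking."""

    continuous_positions: np.ndarray  # (n, j)
    binary_positions: np.ndarray      # (n, j) of {0, 1}
    fitness: np.ndarray               # (n,)
    alpha_idx: int
    beta_idx: int
    delta_idx: int
    iteration: int = 0


@dataclass
class SelectionResult:
    """Outcome of a selection run (shared by every selector)."""

    best_mask: np.ndarray
    alpha_trajectory: np.ndarray
    final_model: PLSModel
    n_selected: int
    fitness_history: np.ndarray | None = None
    profile: "object | None" = None  # baseline selectors attach a StabilityProfile

    @property
    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.best_mask)


def convergence_coefficient(t: int, t_max: int) -> float:
    """Linear schedule a(t) = 2 (1 - t / t_max): 2 at the start of the run,
    0 at the last iteration."""
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if not (0 <= t <= t_max):
        raise ValueError(f"iteration {t} outside [0, {t_max}]")
    return 2.0 * (1.0 - t / t_max)


def discretize(
    positions: np.ndarray,
    rng: np.random.Generator | None = None,
    slope: float = 10.0,
    center: float = 0.5,
    deterministic: bool = False,
) -> np.ndarray:
    """Map continuous positions to a binary mask.

    A steep logistic ``s(x) = 1 / (1 + exp(-slope (x - center)))`` converts
    each coordinate to a selection probability, which is then thresholded
    against a fresh uniform draw (stochastic mode, the default) or against
    0.5 (deterministic mode).
    """
    pos = np.asarray(positions, dtype=float)
    if np.any(np.isnan(pos)):
        raise ValueError("positions contain NaN")
    prob = 1.0 / (1.0 + np.exp(-slope * (pos - center)))
    if deterministic:
        return (prob >= 0.5).astype(np.int8)
    if rng is None:
        raise ValueError("stochastic discretization needs an rng")
    return (prob >= rng.random(pos.shape)).astype(np.int8)


def rank_pack(fitness) -> tuple[int, int, int]:
    """Indices of the three lowest fitness values in ascending order;
    ties break toward the lower wolf index."""
    f = np.asarray(fitness, dtype=float)
    if f.size < 3:
        raise ValueError("ranking needs at least 3 wolves")
    order = np.argsort(f, kind="stable")
    return int(order[0]), int(order[1]), int(order[2])


class FitnessEvaluator:
    """RMSECV fitness of a binary mask, with per-run fixed CV splits.

    The MCCV splits are drawn once per optimizer run, which makes the
    fitness a deterministic function of the mask bits and therefore safe to
    cache (keyed by the bit pattern).  An all-zero mask receives a large
    finite penalty instead of a PLS fit.
    """

    def __init__(self, X, y, n_lv: int, cv: CVConfig, empty_mask_penalty: float = 1.0e6):
        self.X = _as_matrix(X)
        self.y = _as_vector(y)
        if self.y.size != self.X.shape[0]:
            raise ValueError("X rows and y length differ")
        self.n_lv = n_lv
        self.splits = draw_mccv_splits(self.X.shape[0], cv)
        self.empty_mask_penalty = empty_mask_penalty
        self._cache: dict[bytes, float] = {}
        self.n_evaluations = 0

    def __call__(self, mask) -> float:
        bits = np.asarray(mask, dtype=np.int8).ravel()
        if bits.size != self.X.shape[1]:
            raise ValueError("mask length does not match number of variables")
        key = bits.tobytes()
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        if not bits.any():
            value = self.empty_mask_penalty
        else:
            cols = np.flatnonzero(bits)
            k = min(self.n_lv, cols.size)
            path = mccv_rmsecv_path(
                self.X[:, cols], self.y, k, cv=None, splits=self.splits
            )
            value = float(path[k - 1])
            self.n_evaluations += 1
        self._cache[key] = value
        return value


def evaluate_fitness(mask, X, y, config: GWOConfig) -> float:
    """One-off RMSECV fitness of a mask (fresh evaluator, config's CV)."""
    ev = FitnessEvaluator(X, y, config.n_lv, config.cv, config.empty_mask_penalty)
    return ev(mask)


def init_pack(
    config: GWOConfig,
    n_vars: int,
    rng: np.random.Generator | None = None,
    evaluator: FitnessEvaluator | None = None,
    X=None,
    y=None,
) -> WolfPack:
    """Random initial pack: continuous positions uniform in [0, 1],
    discretized and fitness-ranked."""
    if n_vars < 1:
        raise ValueError("need at least one variable")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if evaluator is None:
        if X is None or y is None:
            raise ValueError("provide an evaluator or X and y")
        evaluator = FitnessEvaluator(X, y, config.n_lv, config.cv, config.empty_mask_penalty)
    cont = rng.random((config.n_wolves, n_vars))
    bits = discretize(
        cont,
        rng,
        slope=config.transfer_slope,
        center=config.transfer_center,
        deterministic=config.deterministic_discretize,
    )
    fitness = np.array([evaluator(row) for row in bits])
    a_i, b_i, d_i = rank_pack(fitness)
    return WolfPack(cont, bits, fitness, a_i, b_i, d_i, iteration=0)


def update_positions(pack: WolfPack, a: float, rng: np.random.Generator) -> np.ndarray:
    """One synchronous encircling/hunting move of the whole pack.

    Leader positions are read once at iteration start; r1 and r2 are drawn
    independently per wolf, per leader and per coordinate, in the leader
    order alpha, beta, delta (r1 before r2 for each leader).
    """
    Xc = pack.continuous_positions
    n, j = Xc.shape
    new = np.zeros_like(Xc)
    for leader_idx in (pack.alpha_idx, pack.beta_idx, pack.delta_idx):
        x_l = Xc[leader_idx]
        r1 = rng.random((n, j))
        r2 = rng.random((n, j))
        A = 2.0 * a * r1 - a
        C = 2.0 * r2
        D = np.abs(C * x_l - Xc)
        new += x_l - A * D
    return new / 3.0


def gwo_select(X, y, config: GWOConfig) -> SelectionResult:
    """Run the discretized GWO-PLS wavelength selection.

    Returns the final alpha wolf's mask, its RMSECV trajectory (index 0 is
    the post-initialization value), and a PLS model refit on the selected
    channels over the full training set.
    """
    Xm = _as_matrix(X)
    yv = _as_vector(y)
    rng = np.random.default_rng(config.seed)
    evaluator = FitnessEvaluator(Xm, yv, config.n_lv, config.cv, config.empty_mask_penalty)
    pack = init_pack(config, Xm.shape[1], rng=rng, evaluator=evaluator)

    trajectory = [pack.fitness[pack.alpha_idx]]
    history = [pack.fitness.copy()] if config.record_history else None

    for t in range(1, config.t_max + 1):
        a = convergence_coefficient(t, config.t_max)
        cont_new = update_positions(pack, a, rng)
        bits_new = discretize(
            cont_new,
            rng,
            slope=config.transfer_slope,
            center=config.transfer_center,
            deterministic=config.deterministic_discretize,
        )
        fit_new = np.array([evaluator(row) for row in bits_new])
        # greedy personal memory: reject moves that worsen a wolf's fitness
        accept = fit_new <= pack.fitness
        pack.continuous_positions[accept] = cont_new[accept]
        pack.binary_positions[accept] = bits_new[accept]
        pack.fitness[accept] = fit_new[accept]
        pack.alpha_idx, pack.beta_idx, pack.delta_idx = rank_pack(pack.fitness)
        pack.iteration = t
        trajectory.append(pack.fitness[pack.alpha_idx])
        if history is not None:
            history.append(pack.fitness.copy())

    best_mask = pack.binary_positions[pack.alpha_idx].copy()
    cols = np.flatnonzero(best_mask)
    n_lv_fit = min(config.n_lv, cols.size, Xm.shape[0] - 1)
    final_model = fit_pls(Xm[:, cols], yv, n_lv_fit, mask=best_mask)
    return SelectionResult(
        best_mask=best_mask,
        alpha_trajectory=np.asarray(trajectory),
        final_model=final_model,
        n_selected=int(best_mask.sum()),
        fitness_history=None if history is None else np.asarray(history),
    )
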