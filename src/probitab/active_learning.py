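"""Maximum-uncertainty active learning of the survival surrogate.

The loop: label an initial Sobol design with the simulator, fit the GP
surrogate, then repeatedly (i) draw a fresh random constraint-respecting
candidate pool, (ii) query the pool point with the largest posterior standard
deviation, (iii) label it with the simulator and retrain. Validation R^2 and
RMSE against an independently Sobol-sampled, simulator-labelled set are
tracked per iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .design import (DesignSpace, ProcessPoint, normalize, random_design,
                     sobol_design)
from .gp import SquaredExponentialGP

__all__ = ["ALConfig", "ALState", "Metrics", "make_validation",
           "acquire_max_std", "compute_metrics", "run_loop"]

log = logging.getLogger(__name__)

# fixed seed-splitting offsets so each randomness source is independently
# reproducible from one global seed
SEED_OFFSET_VALIDATION = 7919
SEED_OFFSET_POOL = 104729
SEED_OFFSET_TUNER = 15485863


@dataclass(frozen=True)
class ALConfig:
    """Budgets and seeds of one active-learning run."""

    n_init: int = 30        # initial Sobol design size
    n_iter: int = 78        # acquisition budget
    pool_size: int = 4096   # fresh candidate pool per iteration
    n_val: int = 100        # Sobol validation points
    retune_every: int = 1   # hyperparameter retuning period (iterations)
    tune_budget: int = 30   # BO iterations per retune
    seed: int = 0

    def __post_init__(self):
        if self.n_init < 3:
            raise ValueError("n_init must be >= 3")
        for name in ("n_iter", "pool_size", "n_val", "retune_every"):
            if name != "n_iter" and getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_iter < 0:
            raise ValueError("n_iter must be >= 0")


@dataclass(frozen=True)
class Metrics:
    r2: float
    rmse: float


@dataclass
class ALState:
    """Labelled dataset, fitted surrogate and per-iteration history."""

    points: list[ProcessPoint]
    y: np.ndarray
    model: SquaredExponentialGP
    space: DesignSpace
    history: list[dict] = field(default_factory=list)
    val_points: list[ProcessPoint] = field(default_factory=list)
    val_y: np.ndarray = None

    @property
    def n_train(self) -> int:
        return len(self.points)


def _label(oracle, points) -> np.ndarray:
    return np.array([oracle(p) for p in points], dtype=float)


def make_validation(oracle, space: DesignSpace, n_val: int, seed: int):
    """Sobol validation design labelled by the simulator.

    Uses its own scrambling seed, so the validation set is disjoint from any
    training design generated with a different seed.
    """
    pts = sobol_design(space, n_val, seed)
    return pts, _label(oracle, pts)


def acquire_max_std(model: SquaredExponentialGP, pool, space: DesignSpace):
    """Pool point with the largest posterior std (ties: lowest index)."""
    if len(pool) == 0:
        raise ValueError("acquisition pool must be non-empty")
    U = normalize(pool, space)
    _, std = model.predict(U, return_std=True)
    i = int(np.argmax(std))
    return pool[i], float(std[i]), i


def compute_metrics(model: SquaredExponentialGP, val_points, val_y,
                    space: DesignSpace) -> Metrics:
    """Validation R^2 and RMSE of the surrogate's posterior means."""
    val_y = np.asarray(val_y, dtype=float)
    if len(val_y) < 2:
        raise ValueError("validation set must contain at least 2 points")
    ss_tot = np.sum((val_y - val_y.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("validation targets have zero variance; R^2 undefined")
    pred = model.predict(normalize(val_points, space))
    ss_res = np.sum((val_y - pred) ** 2)
    return Metrics(r2=float(1.0 - ss_res / ss_tot),
                   rmse=float(np.sqrt(np.mean((val_y - pred) ** 2))))


def _fit_model(U, y, tune: bool, prev: SquaredExponentialGP | None,
               cfg: ALConfig) -> SquaredExponentialGP:
    if tune or prev is None:
        gp = SquaredExponentialGP(optimizer="bo", n_bo_iter=cfg.tune_budget,
                                  random_state=cfg.seed + SEED_OFFSET_TUNER)
    else:
        h = prev.hyperparams_
        gp = SquaredExponentialGP(l=h.l, sigma2=h.sigma2, noise2=h.noise2,
                                  optimizer=None)
    return gp.fit(U, y)


def run_loop(oracle, space: DesignSpace, config: ALConfig) -> ALState:
    """Run the full active-learning loop; reproducible from ``config.seed``.

    The history gets one entry for the initial model plus one per completed
    iteration, each carrying the validation metrics, the acquired point and
    the pool-maximum posterior std.
    """
    cfg = config
    points = sobol_design(space, cfg.n_init, cfg.seed)
    y = _label(oracle, points)
    val_points, val_y = make_validation(oracle, space, cfg.n_val,
                                        cfg.seed + SEED_OFFSET_VALIDATION)

    U = normalize(points, space)
    model = _fit_model(U, y, tune=True, prev=None, cfg=cfg)
    state = ALState(points=list(points), y=y, model=model, space=space,
                    val_points=val_points, val_y=val_y)

    m = compute_metrics(model, val_points, val_y, space)
    state.history.append({"iteration": 0, "r2": m.r2, "rmse": m.rmse,
                          "acquired": None, "max_std": None})
    log.info("AL init: n=%d R2=%.4f RMSE=%.4f", cfg.n_init, m.r2, m.rmse)

    it = 0
    while it < cfg.n_iter:
        pool = random_design(space, cfg.pool_size,
                             cfg.seed + SEED_OFFSET_POOL + it)
        pt, max_std, _ = acquire_max_std(state.model, pool, space)
        try:
            y_new = oracle(pt)
        except Exception as exc:  # pragma: no cover - defensive
            log.warning("oracle failed at %s (%s); point skipped", pt, exc)
            it += 1
            continue
        state.points.append(pt)
        state.y = np.append(state.y, y_new)
        it += 1

        U = normalize(state.points, space)
        retune = (it % cfg.retune_every) == 0
        state.model = _fit_model(U, state.y, tune=retune, prev=state.model,
                                 cfg=cfg)
        m = compute_metrics(state.model, val_points, val_y, space)
        state.history.append({"iteration": it, "r2": m.r2, "rmse": m.rmse,
                              "acquired": pt, "max_std": max_std})
        log.info("AL iter %d: acquired (%.1f, %.1f, %.1f) max_std=%.4f "
                 "R2=%.4f RMSE=%.4f", it, pt.speed, pt.pre, pt.main,
                 max_std, m.r2, m.rmse)
    return state
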