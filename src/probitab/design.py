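"""Process-parameter design space and experimental designs.

The tabletting process is described by three parameters: compression speed
(mm/min), precompression pressure (MPa) and main compression pressure (MPa),
subject to the physical constraint that precompression never exceeds the main
compression pressure.  This module defines the bounded design space and
generates Sobol (quasi-random), uniform-random and regular-grid designs
inside it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import qmc

__all__ = [
    "ProcessPoint",
    "DesignSpace",
    "sobol_design",
    "random_design",
    "normalize",
    "denormalize",
    "slice_grid",
    "points_to_frame",
    "frame_to_points",
]


@dataclass(frozen=True)
class ProcessPoint:
    """One tabletting condition.

    Attributes
    ----------
    speed : float
        Punch (compression) speed in mm/min.
    pre : float
        Precompression pressure in MPa.
    main : float
        Main compression pressure in MPa.
    """

    speed: float
    pre: float
    main: float

    def __post_init__(self):
        if not np.isfinite([self.speed, self.pre, self.main]).all():
            raise ValueError("process parameters must be finite")
        if self.speed < 0:
            raise ValueError(f"compression speed must be >= 0, got {self.speed}")
        if self.pre < 0:
            raise ValueError(f"precompression pressure must be >= 0, got {self.pre}")
        if self.main <= 0:
            raise ValueError(f"main compression pressure must be > 0, got {self.main}")
        if self.pre > self.main + 1e-9:
            raise ValueError(
                f"precompression ({self.pre} MPa) must not exceed the main "
                f"compression pressure ({self.main} MPa)"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.speed, self.pre, self.main], dtype=float)


@dataclass(frozen=True)
class DesignSpace:
    """Axis-aligned box for (speed, pre, main) with the pre <= main constraint.

    Defaults cover laboratory through industrial press conditions: speeds of
    0-5000 mm/min and main compression pressures of 50-400 MPa, with
    precompression allowed anywhere below the main pressure.
    """

    speed_lo: float = 0.0
    speed_hi: float = 5000.0
    pre_lo: float = 0.0
    pre_hi: float = 400.0
    main_lo: float = 50.0
    main_hi: float = 400.0

    def __post_init__(self):
        for lo, hi, name in [
            (self.speed_lo, self.speed_hi, "speed"),
            (self.pre_lo, self.pre_hi, "pre"),
            (self.main_lo, self.main_hi, "main"),
        ]:
            if name == "pre" and lo == hi:
                continue  # degenerate pre bound (e.g. pre fixed at 0) is allowed
            if not lo < hi:
                raise ValueError(f"{name} bounds must satisfy lo < hi, got [{lo}, {hi}]")
        if self.speed_lo < 0 or self.pre_lo < 0 or self.main_lo <= 0:
            raise ValueError("bounds must be non-negative (main_lo > 0)")

    def contains(self, p: ProcessPoint, atol: float = 1e-9) -> bool:
        return (
            self.speed_lo - atol <= p.speed <= self.speed_hi + atol
            and self.pre_lo - atol <= p.pre <= self.pre_hi + atol
            and self.main_lo - atol <= p.main <= self.main_hi + atol
            and p.pre <= p.main + atol
        )

    @classmethod
    def lab(cls) -> "DesignSpace":
        """Bench-top compaction-analyser envelope: 10-180 mm/min, <= 374 MPa."""
        return cls(speed_lo=10.0, speed_hi=180.0, pre_lo=0.0, pre_hi=374.0,
                   main_lo=50.0, main_hi=374.0)


def _sobol_unit(n: int, seed: int) -> np.ndarray:
    """n scrambled Sobol points in [0,1)^3, skipping the first sequence point."""
    sampler = qmc.Sobol(d=3, scramble=True, seed=seed)
    sampler.fast_forward(1)
    return sampler.random(n)


def sobol_design(space: DesignSpace, n: int, seed: int) -> list[ProcessPoint]:
    """Low-discrepancy Sobol design of ``n`` points.

    The unit-cube coordinates (u1, u2, u3) are mapped as speed from u1,
    main pressure from u3, and precompression as ``pre = u2 * main`` (clipped
    to the pre bounds), so the pre <= main constraint holds by construction
    while the low-discrepancy structure of the sequence is preserved.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if n == 0:
        return []
    u = _sobol_unit(n, seed)
    return _map_unit_to_points(u, space)


def _map_unit_to_points(u: np.ndarray, space: DesignSpace) -> list[ProcessPoint]:
    speed = space.speed_lo + u[:, 0] * (space.speed_hi - space.speed_lo)
    main = space.main_lo + u[:, 2] * (space.main_hi - space.main_lo)
    pre_cap = np.minimum(space.pre_hi, main)
    pre = space.pre_lo + u[:, 1] * (pre_cap - space.pre_lo)
    return [ProcessPoint(s, p, m) for s, p, m in zip(speed, pre, main)]


def random_design(space: DesignSpace, n: int, seed: int) -> list[ProcessPoint]:
    """Uniform-random design with rejection of points violating pre < main.

    Points are drawn uniformly in the full box and redrawn until ``n`` points
    satisfying the strict constraint ``pre < main`` have been retained.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    rng = np.random.default_rng(seed)
    out: list[ProcessPoint] = []
    lo = np.array([space.speed_lo, space.pre_lo, space.main_lo])
    hi = np.array([space.speed_hi, space.pre_hi, space.main_hi])
    while len(out) < n:
        m = max(n - len(out), 64)
        draw = lo + rng.random((m, 3)) * (hi - lo)
        ok = draw[:, 1] < draw[:, 2]
        if space.pre_lo == space.pre_hi:  # degenerate pre bound: draw is exact
            ok = draw[:, 1] <= draw[:, 2]
        for s, p, mn in draw[ok]:
            out.append(ProcessPoint(s, p, mn))
            if len(out) == n:
                break
    return out


def _bounds(space: DesignSpace) -> tuple[np.ndarray, np.ndarray]:
    lo = np.array([space.speed_lo, space.pre_lo, space.main_lo], dtype=float)
    hi = np.array([space.speed_hi, space.pre_hi, space.main_hi], dtype=float)
    return lo, hi


def normalize(points, space: DesignSpace) -> np.ndarray:
    """Affine min-max map of points onto the unit cube.

    Precompression is normalised against its global bounds (``pre_lo`` to
    ``pre_hi``), not against each point's own main pressure, so the map is a
    fixed affine transform and kernel distances are stationary.

    Accepts a single ProcessPoint, a list of them, or an (n, 3) array in
    (speed, pre, main) order; returns an (n, 3) array (or (3,) for a single
    point).
    """
    single = isinstance(points, ProcessPoint)
    arr = _as_array(points)
    lo, hi = _bounds(space)
    if (arr < lo - 1e-6).any() or (arr > hi + 1e-6).any():
        raise ValueError("point outside design-space bounds")
    u = (arr - lo) / (hi - lo)
    return u[0] if single else u


def denormalize(u: np.ndarray, space: DesignSpace) -> np.ndarray:
    """Inverse of :func:`normalize` (unit cube back to physical units)."""
    u = np.atleast_2d(np.asarray(u, dtype=float))
    lo, hi = _bounds(space)
    return lo + u * (hi - lo)


def _as_array(points) -> np.ndarray:
    if isinstance(points, ProcessPoint):
        return points.as_array()[None, :]
    if isinstance(points, (list, tuple)) and points and isinstance(points[0], ProcessPoint):
        return np.array([p.as_array() for p in points])
    return np.atleast_2d(np.asarray(points, dtype=float))


def slice_grid(
    fixed_main: float,
    speed_range: tuple[float, float],
    pre_range: tuple[float, float],
    n_speed: int,
    n_pre: int,
) -> list[ProcessPoint]:
    """Regular lattice over (speed, pre) at one fixed main pressure.

    Row-major ordering: the speed axis varies slowest. Endpoints included.
    """
    if fixed_main < pre_range[1]:
        raise ValueError(
            f"fixed main pressure {fixed_main} MPa is below the slice's "
            f"maximum precompression {pre_range[1]} MPa"
        )
    speeds = np.linspace(speed_range[0], speed_range[1], n_speed)
    pres = np.linspace(pre_range[0], pre_range[1], n_pre)
    return [ProcessPoint(s, p, fixed_main) for s in speeds for p in pres]


_CSV_COLS = ["speed_mm_min", "pre_MPa", "main_MPa"]


def points_to_frame(points, survival=None) -> pd.DataFrame:
    """Tabulate points (and optional survival fractions) as a DataFrame."""
    arr = _as_array(points)
    df = pd.DataFrame(arr, columns=_CSV_COLS)
    if survival is not None:
        df["survival_frac"] = np.asarray(survival, dtype=float)
    return df


def frame_to_points(df: pd.DataFrame) -> list[ProcessPoint]:
    return [ProcessPoint(r.speed_mm_min, r.pre_MPa, r.main_MPa)
            for r in df.itertuples(index=False)]
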