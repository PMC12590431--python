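"""Near-optimal region extraction and survival maps.

Random candidate points are scored with the fitted surrogate; candidates
whose predicted mean survival is within a fraction (default 99 %) of the
maximum are retained and wrapped in a 3-D alpha shape — the union of
Delaunay tetrahedra with circumradius below the alpha radius — delimiting
the high-survival domain of the process space. Survival maps scan
(speed, precompression) slices at fixed main pressures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, ConvexHull

from .design import (DesignSpace, ProcessPoint, normalize, random_design,
                     slice_grid)

__all__ = ["RegionResult", "SurvivalMap", "alpha_shape_3d",
           "find_optimal_region", "survival_map", "AlphaShape"]


@dataclass
class AlphaShape:
    """Union of Delaunay tetrahedra with circumradius <= alpha."""

    vertices: np.ndarray           # all input points (n, 3)
    simplices: np.ndarray          # kept tetrahedra, indices into vertices
    boundary_facets: np.ndarray    # triangles on the boundary (m, 3)
    volume: float
    alpha: float


@dataclass
class RegionResult:
    candidates: list[ProcessPoint]
    means: np.ndarray
    stds: np.ndarray
    retained: list[ProcessPoint]
    retained_means: np.ndarray
    threshold: float
    shape: AlphaShape | None
    degenerate: bool = False


@dataclass
class SurvivalMap:
    fixed_main: float
    speeds: np.ndarray
    pres: np.ndarray
    values: np.ndarray  # (n_speed, n_pre)


def _circumradii(pts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumradius of each tetrahedron (vectorised linear solves)."""
    a = pts[simplices[:, 0]]
    rows = pts[simplices[:, 1:]] - a[:, None, :]          # (m, 3, 3)
    rhs = 0.5 * np.einsum("mij,mij->mi", rows, rows)      # (m, 3)
    det = np.linalg.det(rows)
    out = np.full(len(simplices), np.inf)
    ok = np.abs(det) > 1e-300
    if ok.any():
        x = np.linalg.solve(rows[ok], rhs[ok][..., None])[..., 0]
        out[ok] = np.linalg.norm(x, axis=1)
    return out


def _tet_volumes(pts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    a = pts[simplices[:, 0]]
    rows = pts[simplices[:, 1:]] - a[:, None, :]
    return np.abs(np.linalg.det(rows)) / 6.0


def _boundary_facets(simplices: np.ndarray) -> np.ndarray:
    """Triangles belonging to exactly one kept tetrahedron."""
    faces = {}
    idx = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
    for tet in simplices:
        for i, j, k in idx:
            key = tuple(sorted((tet[i], tet[j], tet[k])))
            faces[key] = faces.get(key, 0) + 1
    return np.array([f for f, c in faces.items() if c == 1], dtype=int).reshape(-1, 3)


def alpha_shape_3d(points: np.ndarray, alpha: float) -> AlphaShape:
    """Alpha shape of a 3-D point cloud.

    Keeps Delaunay tetrahedra whose circumradius is at most ``alpha``;
    ``alpha = inf`` reduces to the convex hull. Raises on degenerate
    (coplanar or collinear) input.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise ValueError("alpha shape needs >= 4 points in 3-D")
    try:
        tri = Delaunay(pts)
    except Exception as exc:
        raise ValueError(f"degenerate point cloud: {exc}") from exc
    if tri.simplices.size == 0:
        raise ValueError("degenerate point cloud: no tetrahedra")
    radii = _circumradii(pts, tri.simplices)
    keep = tri.simplices[radii <= alpha]
    if len(keep) == 0:
        return AlphaShape(vertices=pts, simplices=keep,
                          boundary_facets=np.empty((0, 3), int),
                          volume=0.0, alpha=alpha)
    return AlphaShape(
        vertices=pts,
        simplices=keep,
        boundary_facets=_boundary_facets(keep),
        volume=float(_tet_volumes(pts, keep).sum()),
        alpha=alpha,
    )


def _default_alpha(pts: np.ndarray) -> float:
    """Smallest circumradius threshold at which all points join one
    connected component of the kept tetrahedra (binary search over the
    candidate circumradii)."""
    tri = Delaunay(pts)
    radii = np.sort(np.unique(_circumradii(pts, tri.simplices)))
    radii = radii[np.isfinite(radii)]
    simp = tri.simplices

    def connected(alpha: float) -> bool:
        keep = simp[_circumradii(pts, simp) <= alpha]
        if len(keep) == 0:
            return False
        used = np.unique(keep)
        if len(used) != len(pts):
            return False
        # union-find over vertices of kept tets
        parent = np.arange(len(pts))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for tet in keep:
            r = find(tet[0])
            for v in tet[1:]:
                parent[find(v)] = r
        roots = {find(int(v)) for v in used}
        return len(roots) == 1

    lo, hi = 0, len(radii) - 1
    if not connected(radii[hi]):
        return float("inf")
    while lo < hi:
        mid = (lo + hi) // 2
        if connected(radii[mid]):
            hi = mid
        else:
            lo = mid + 1
    return float(radii[lo])


def find_optimal_region(model, space: DesignSpace, n_candidates: int = 5000,
                        frac: float = 0.99, seed: int = 0,
                        alpha: float | None = None) -> RegionResult:
    """High-survival region of the design space under the fitted surrogate.

    ``n_candidates`` uniform random points (respecting pre < main) are scored;
    points with predicted mean >= ``frac`` x max mean are retained and wrapped
    in an alpha shape computed in normalised coordinates. When ``alpha`` is
    None, the smallest radius keeping the retained points in one connected
    component is used.
    """
    cands = random_design(space, n_candidates, seed)
    U = normalize(cands, space)
    means, stds = model.predict(U, return_std=True)
    threshold = frac * float(means.max())
    mask = means >= threshold
    retained = [p for p, m in zip(cands, mask) if m]
    ret_u = U[mask]

    shape = None
    degenerate = False
    if mask.sum() >= 4:
        try:
            a = _default_alpha(ret_u) if alpha is None else alpha
            shape = alpha_shape_3d(ret_u, a)
        except ValueError:
            degenerate = True
    else:
        degenerate = True
    return RegionResult(candidates=cands, means=means, stds=stds,
                        retained=retained, retained_means=means[mask],
                        threshold=threshold, shape=shape, degenerate=degenerate)


def survival_map(evaluator, fixed_main: float, speed_range, pre_range,
                 resolution: int | tuple[int, int] = 11,
                 space: DesignSpace | None = None) -> SurvivalMap:
    """Survival over a (speed, pre) lattice at one fixed main pressure.

    ``evaluator`` is either a callable mapping a ProcessPoint to a survival
    fraction (e.g. a simulator) or a fitted surrogate with ``predict``
    (requires ``space`` for input normalisation).
    """
    n_speed, n_pre = ((resolution, resolution)
                      if isinstance(resolution, int) else resolution)
    grid = slice_grid(fixed_main, speed_range, pre_range, n_speed, n_pre)
    if callable(evaluator):
        vals = np.array([evaluator(p) for p in grid])
    else:
        if space is None:
            raise ValueError("a DesignSpace is required for surrogate maps")
        vals = evaluator.predict(normalize(grid, space))
    return SurvivalMap(
        fixed_main=fixed_main,
        speeds=np.linspace(speed_range[0], speed_range[1], n_speed),
        pres=np.linspace(pre_range[0], pre_range[1], n_pre),
        values=vals.reshape(n_speed, n_pre),
    )
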