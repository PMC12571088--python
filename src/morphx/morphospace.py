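"""Ordination and geometric summaries of morphospace occupation.

The main analysis ordinates species-mean shapes by PCA and tracks, under
species removals, the convex-hull area and the centroid of the surviving
scores in the *fixed* baseline ordination (scores are never re-ordinated
after an extinction), plus an interpolated depth surface over the score
plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import griddata
from scipy.spatial import ConvexHull, QhullError

from .shape_core import AlignedShapes


@dataclass
class Ordination:
    """PCA of entity-by-coordinate data (species means or specimens)."""

    ids: list[str]
    scores: np.ndarray
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    mean: np.ndarray
    loadings: np.ndarray  # axis-by-coordinate

    @property
    def pc12(self) -> np.ndarray:
        return self.scores[:, :2]


@dataclass
class HullSummary:
    vertex_indices: np.ndarray
    area: float
    centroid: np.ndarray  # mean of *member* scores, not just hull vertices


@dataclass
class CentroidShift:
    delta: np.ndarray
    magnitude: float
    direction: float
    degenerate: bool  # zero-magnitude shift: direction reported as 0


def species_mean_shapes(
    aligned: AlignedShapes, subset: str = "both"
) -> tuple[list[str], np.ndarray]:
    """Per-species arithmetic means of aligned coordinates.

    ``subset`` selects upper-jaw, lower-jaw, or all teeth; species with no
    specimen in the subset are dropped with a warning.
    """
    if subset not in ("both", "upper", "lower"):
        raise ValueError("subset must be both|upper|lower")
    meta = aligned.meta
    mask = np.ones(len(meta), dtype=bool) if subset == "both" else (meta["jaw"] == subset).values
    if not mask.any():
        raise ValueError(f"no specimens in subset {subset!r}")
    species = sorted(meta["species_id"].unique())
    ids, means = [], []
    flat = aligned.flat
    for sp in species:
        sel = mask & (meta["species_id"] == sp).values
        if not sel.any():
            warnings.warn(f"species {sp} has no specimens in subset {subset!r}; dropped")
            continue
        ids.append(sp)
        means.append(flat[sel].mean(axis=0))
    return ids, np.vstack(means)


def ordinate(matrix: np.ndarray, ids: list[str] | None = None) -> Ordination:
    """PCA by eigendecomposition of the covariance of centered rows.

    Axis signs follow a deterministic rule: each axis is oriented so its
    largest-magnitude loading is positive.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("ordination needs at least 2 entities")
    n = M.shape[0]
    mean = M.mean(axis=0)
    Xc = M - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (n - 1)
    scores = U * s
    for j in range(Vt.shape[0]):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] = -Vt[j]
            scores[:, j] = -scores[:, j]
    total = eig.sum()
    pct = eig / total * 100.0 if total > 0 else np.zeros_like(eig)
    return Ordination(
        ids=list(ids) if ids is not None else [str(i) for i in range(n)],
        scores=scores,
        eigenvalues=eig,
        percent_variance=pct,
        mean=mean,
        loadings=Vt,
    )


def _shoelace(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def hull_area(scores: np.ndarray) -> HullSummary:
    """Convex hull of (PC1, PC2) points; degenerate inputs have area 0."""
    pts = np.atleast_2d(np.asarray(scores, dtype=float))
    if pts.shape[0] == 0:
        raise ValueError("no points")
    centroid = pts.mean(axis=0)
    if pts.shape[0] < 3:
        return HullSummary(np.arange(pts.shape[0]), 0.0, centroid)
    try:
        hull = ConvexHull(pts)
    except QhullError:  # collinear
        return HullSummary(np.arange(pts.shape[0]), 0.0, centroid)
    return HullSummary(hull.vertices, _shoelace(pts[hull.vertices]), centroid)


def centroid_shift(baseline_scores: np.ndarray, survivor_idx: np.ndarray) -> CentroidShift:
    """Vector from baseline score centroid to survivor centroid.

    Computed in the fixed baseline ordination; survivors must be a subset
    of the baseline entities.
    """
    base = np.asarray(baseline_scores, dtype=float)
    idx = np.asarray(survivor_idx, dtype=int)
    if idx.size == 0:
        raise ValueError("empty survivor set")
    if idx.min() < 0 or idx.max() >= base.shape[0]:
        raise ValueError("survivor indices outside baseline")
    delta = base[idx].mean(axis=0) - base.mean(axis=0)
    mag = float(np.linalg.norm(delta))
    if mag < 1e-15:
        return CentroidShift(delta, 0.0, 0.0, True)
    return CentroidShift(delta, mag, float(np.arctan2(delta[1], delta[0])), False)


def interpolate_surface(
    points: np.ndarray, values: np.ndarray, grid: int = 200
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Piecewise-linear interpolation of a value field over the score plane.

    Returns grid axes and a (grid, grid) array of interpolated values;
    nodes outside the convex hull of the data are NaN.  Used for the depth
    (bathymetry) surface over PC1–PC2.
    """
    pts = np.asarray(points, dtype=float)
    vals = np.asarray(values, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points")
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite values")
    gx = np.linspace(pts[:, 0].min(), pts[:, 0].max(), grid)
    gy = np.linspace(pts[:, 1].min(), pts[:, 1].max(), grid)
    GX, GY = np.meshgrid(gx, gy)
    try:
        Z = griddata(pts, vals, (GX, GY), method="linear")
    except QhullError as exc:
        raise ValueError("all points collinear; cannot triangulate") from exc
    return gx, gy, Z
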