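"""Procrustes machinery.

Generalized Procrustes analysis (GPA) superimposes landmark configurations
by removing translation (centroid at the origin), scale (unit centroid
size) and rotation (least-squares fit to an iteratively updated consensus,
proper rotations only).  Semilandmarks may additionally be slid along their
local curve tangent to minimize the thin-plate-spline bending energy of
each specimen against the current consensus — the standard treatment of
points whose position *along* a curve is not homologous.

The bending energy matrix is the upper-left block of the inverse of the
thin-plate-spline system built from the radial basis kernel
``U(r) = r^2 log r^2``; it is symmetric positive semi-definite and
annihilates affine transforms of the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import Curve, LandmarkConfiguration


def centroid_size(points: np.ndarray) -> float:
    """Square root of the summed squared distances of points from their centroid."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("centroid size needs at least 2 points")
    d = pts - pts.mean(axis=0)
    cs = float(np.sqrt((d * d).sum()))
    if cs <= 0.0:
        raise ValueError("coincident points: centroid size is zero")
    return cs


def resample_equidistant(curve_points: np.ndarray, k: int) -> np.ndarray:
    """Resample a polyline to ``k`` points with equal arc-length spacing.

    The first and last input points are preserved exactly; intermediate
    points are linearly interpolated along the polyline, so the output is
    invariant to the input's parametrization.
    """
    pts = np.asarray(curve_points, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 input points")
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(steps)])
    if s[-1] <= 0.0:
        raise ValueError("zero-length polyline")
    targets = np.linspace(0.0, s[-1], k)
    out = np.column_stack([np.interp(targets, s, pts[:, j]) for j in range(pts.shape[1])])
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


class BendingEnergyModel:
    """Thin-plate-spline bending energy relative to a reference configuration."""

    def __init__(self, reference: np.ndarray):
        Q = np.asarray(reference, dtype=float)
        p = Q.shape[0]
        diff = Q[:, None, :] - Q[None, :, :]
        r2 = (diff * diff).sum(axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            K = np.where(r2 > 0.0, r2 * np.log(r2), 0.0)
        P = np.column_stack([np.ones(p), Q])
        L = np.zeros((p + 3, p + 3))
        L[:p, :p] = K
        L[:p, p:] = P
        L[p:, :p] = P.T
        Linv = np.linalg.inv(L)
        Le = Linv[:p, :p]
        self.reference = Q
        self.bending_matrix = 0.5 * (Le + Le.T)

    def energy(self, config: np.ndarray) -> float:
        """Total bending energy of mapping the reference onto ``config``.

        Zero (to numerical precision) for any affine transform of the
        reference; sums the quadratic form over both coordinate axes.
        """
        X = np.asarray(config, dtype=float)
        Le = self.bending_matrix
        return float(sum(X[:, j] @ Le @ X[:, j] for j in range(X.shape[1])))


@dataclass
class AlignedShapes:
    """Procrustes-superimposed coordinates for a specimen set.

    ``coordinates`` is (n_specimens, p, 2); every aligned configuration is
    centered at the origin with unit centroid size, and ``consensus`` is the
    arithmetic mean of the aligned coordinates.  ``meta`` carries specimen /
    species / jaw identifiers for downstream grouping.
    """

    coordinates: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    iterations_run: int
    converged: bool
    meta: pd.DataFrame
    roles: np.ndarray | None = None
    curves: list[Curve] | None = None
    slid: bool = False

    @property
    def n_specimens(self) -> int:
        return self.coordinates.shape[0]

    @property
    def flat(self) -> np.ndarray:
        """(n, 2p) matrix of superimposed landmarks."""
        return self.coordinates.reshape(self.n_specimens, -1)


def _center_unit(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    cs = np.sqrt((Xc * Xc).sum())
    if cs <= 0.0:
        raise ValueError("degenerate configuration: zero centroid size")
    return Xc / cs


def _rotate_to(X: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Rotate ``X`` onto ``ref`` by the proper least-squares rotation."""
    H = X.T @ ref
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, d])
    R = U @ D @ Vt
    return X @ R


def _curve_neighbors(curves: list[Curve], n_points: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Semilandmark indices and their previous/next neighbors along each curve."""
    semis, prevs, nexts = [], [], []
    for c in curves:
        seq = [c.anchors[0], *range(c.start, c.stop), c.anchors[1]]
        for j in range(1, len(seq) - 1):
            semis.append(seq[j])
            prevs.append(seq[j - 1])
            nexts.append(seq[j + 1])
    return (np.array(semis, dtype=int), np.array(prevs, dtype=int), np.array(nexts, dtype=int))


def _slide_once(
    X: np.ndarray,
    ref: np.ndarray,
    Le: np.ndarray,
    semis: np.ndarray,
    prevs: np.ndarray,
    nexts: np.ndarray,
) -> np.ndarray:
    """One bending-energy-minimizing slide of all semilandmarks.

    Each semilandmark moves along its unit tangent (central difference of
    curve neighbors); the vector of signed displacements jointly minimizes
    the TPS bending energy of the configuration against the reference.
    Because bending energy is exactly quadratic in the coordinates, the
    solved step can only decrease it; a trust-region cap (half the median
    neighbor spacing, applied as a uniform scaling, which preserves the
    descent property) keeps the tangent linearization honest and prevents
    semilandmark bunching.  Fixed landmarks never move.
    """
    T = X[nexts] - X[prevs]
    norms = np.linalg.norm(T, axis=1)
    ok = norms > 0.0
    T = np.where(ok[:, None], T / np.where(ok, norms, 1.0)[:, None], 0.0)
    d = X - ref
    Ld = Le @ d
    b = (T * Ld[semis]).sum(axis=1)
    G = Le[np.ix_(semis, semis)] * (T @ T.T)
    m = semis.size
    ridge = 1e-10 * (np.trace(G) / m if m else 1.0)
    try:
        t = np.linalg.solve(G + ridge * np.eye(m), -b)
    except np.linalg.LinAlgError:
        t, *_ = np.linalg.lstsq(G, -b, rcond=None)
    step_max = float(np.abs(t).max())
    cap = 0.25 * float(np.median(norms[ok])) if ok.any() else 0.0
    if step_max > cap > 0.0:
        t = t * (cap / step_max)
    out = X.copy()
    out[semis] += t[:, None] * T
    return out


def _gpa_converge(
    X: np.ndarray, consensus: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, int, bool]:
    """Plain GPA loop (rotation-to-consensus) run to convergence, in place."""
    n = X.shape[0]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(n):
            X[i] = _rotate_to(X[i], consensus)
        new_cons = _center_unit(X.mean(axis=0))
        new_cons = _rotate_to(new_cons, consensus)
        delta = float(np.sqrt(np.mean((new_cons - consensus) ** 2)))
        consensus = new_cons
        if delta < tol:
            converged = True
            break
    return consensus, it, converged


def _canonical_orientation(consensus: np.ndarray) -> np.ndarray:
    """Deterministic global rotation: consensus principal axes to (x, y).

    The major-axis sign is chosen so the projection with the largest third
    central moment (falling back to the largest magnitude) is positive;
    the minor axis completes a proper rotation.  Applying this at the end
    removes the arbitrary global orientation of the Procrustes solution,
    making the output coordinates invariant to input rotations.
    """
    C = consensus.T @ consensus
    _, vecs = np.linalg.eigh(C)
    v1 = vecs[:, -1]  # major axis
    proj = consensus @ v1
    skew = float(np.mean(proj**3))
    ref = skew if abs(skew) > 1e-12 else proj[np.argmax(np.abs(proj))]
    if ref < 0:
        v1 = -v1
    v2 = np.array([-v1[1], v1[0]])  # det = +1
    return np.column_stack([v1, v2])


def superimpose(
    configs: list[LandmarkConfiguration],
    slide: bool = True,
    max_iter: int = 100,
    tol: float = 1e-8,
    slide_rounds: int = 10,
    slide_tol: float = 1e-6,
) -> AlignedShapes:
    """Generalized Procrustes superimposition, optionally with sliding.

    All configurations must share one point-count / role / curve structure.
    Plain GPA iterates rotation-to-consensus until the root-mean-square
    consensus change drops below ``tol``.  With ``slide``, up to
    ``slide_rounds`` outer rounds follow, each sliding every specimen's
    semilandmarks against the current consensus by the bending-energy
    criterion and then re-converging the plain GPA; rounds stop early when
    the total Procrustes sum of squares changes by less than ``slide_tol``
    (relative).  The final solution is rotated to a canonical orientation
    (consensus principal axes), so the output does not depend on the
    orientation, position or scale the specimens were digitized in.
    """
    if not configs:
        raise ValueError("no configurations")
    sig = configs[0].structure_signature()
    for c in configs[1:]:
        if c.structure_signature() != sig:
            raise ValueError(
                f"configuration structure mismatch: {c.specimen_id} differs from {configs[0].specimen_id}"
            )
    curves = configs[0].curves
    roles = configs[0].roles
    sizes = np.array([centroid_size(c.points) for c in configs])
    X = np.stack([_center_unit(c.points) for c in configs])
    n = X.shape[0]

    do_slide = slide and any(len(c) for c in curves)

    consensus = _center_unit(X.mean(axis=0))
    consensus, it, converged = _gpa_converge(X, consensus, max_iter, tol)

    if do_slide:
        semis, prevs, nexts = _curve_neighbors(curves, X.shape[1])
        q_prev = None
        for _ in range(slide_rounds):
            Le = BendingEnergyModel(consensus).bending_matrix
            for i in range(n):
                X[i] = _slide_once(X[i], consensus, Le, semis, prevs, nexts)
                X[i] = _rotate_to(_center_unit(X[i]), consensus)
            consensus, inner_it, converged = _gpa_converge(X, consensus, max_iter, tol)
            it += inner_it
            q = float(np.sum((X - consensus) ** 2))
            if q_prev is not None and abs(q_prev - q) <= slide_tol * max(q, 1e-30):
                break
            q_prev = q

    # canonical global orientation, then a final pass so the stored
    # consensus is exactly the mean of the output
    R = _canonical_orientation(consensus)
    consensus = consensus @ R
    for i in range(n):
        X[i] = _rotate_to(X[i] @ R, consensus)
    meta = pd.DataFrame(
        {
            "specimen_id": [c.specimen_id for c in configs],
            "species_id": [c.species_id for c in configs],
            "jaw": [c.jaw for c in configs],
        }
    )
    return AlignedShapes(
        coordinates=X,
        consensus=X.mean(axis=0),
        centroid_sizes=sizes,
        iterations_run=it,
        converged=converged,
        meta=meta,
        roles=roles,
        curves=curves,
        slid=do_slide,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean norm of the coordinate-vector difference of two aligned shapes."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))
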