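"""Compositional diet analyses.

Diet compositions live on the simplex, so Euclidean operations are applied
after a centered log-ratio (CLR) transform; zeros are handled by
multiplicative replacement before logging.  Dietary niche breadth follows
the ordinated-breadth construction: prey categories are embedded by
principal coordinates analysis of their consumer-incidence dissimilarity
and each species' breadth (ODB) is the summed squared distance of its used
prey from their centroid — zero for an extreme specialist.  Ecological
homogenization under extinction is measured as the mean distance of
surviving species to their (recomputed) diet centroid in CLR space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa
from scipy.spatial.distance import pdist, squareform

from .extinction import ExtinctionScenario


@dataclass
class BreadthResult:
    odb: pd.Series
    prey_coordinates: pd.DataFrame
    thresholds: tuple[float, float]  # 33rd / 66th percentile banding


@dataclass
class DispersionResult:
    distances: pd.Series
    group_means: pd.Series
    overall_mean: float
    f: float
    p: float
    n_perm: int
    degenerate: bool
    singleton_groups: list


def clr_transform(
    diets: pd.DataFrame,
    zero_strategy: str = "multiplicative",
    delta_factor: float = 0.65,
) -> pd.DataFrame:
    """Centered log-ratio transform of a proportional diet matrix.

    Rows are renormalized to sum to one.  Zeros are replaced
    multiplicatively (delta = ``delta_factor`` times the smallest nonzero
    proportion in the matrix) before logging, or rejected when
    ``zero_strategy="error"``.  Every output row sums to zero.
    """
    X = diets.to_numpy(dtype=float)
    if np.any(X < 0):
        raise ValueError("negative diet proportions")
    row_sums = X.sum(axis=1)
    if np.any(row_sums <= 0):
        empty = diets.index[row_sums <= 0].tolist()
        raise ValueError(f"rows with all-zero composition: {empty}")
    X = X / row_sums[:, None]
    if (X == 0).any():
        if zero_strategy == "error":
            raise ValueError("composition contains zeros")
        if zero_strategy != "multiplicative":
            raise ValueError(f"unknown zero strategy {zero_strategy!r}")
        delta = delta_factor * X[X > 0].min()
        X = np.where(X == 0, delta, X)
        X = X / X.sum(axis=1, keepdims=True)
    logX = np.log(X)
    clr = logX - logX.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=diets.index, columns=diets.columns)


def ordinated_breadth(incidence: pd.DataFrame) -> BreadthResult:
    """Ordinated dietary breadth (ODB) from a binary species-by-prey matrix.

    Prey are embedded by PCoA of the Euclidean dissimilarity between their
    consumer-incidence profiles; ODB for a species is the sum of squared
    Euclidean distances of its used prey from the centroid of those prey in
    the embedding.  The 33rd/66th percentiles of ODB delimit the
    specialist / intermediate / generalist bands.
    """
    B = (incidence.to_numpy(dtype=float) > 0).astype(float)
    empty = incidence.index[B.sum(axis=1) == 0].tolist()
    if empty:
        raise ValueError(f"species with empty diets: {empty}")
    used = B.sum(axis=0) > 0
    if used.sum() < 2:
        raise ValueError("need at least 2 prey categories used overall")
    if not used.all():
        warnings.warn(
            f"dropping unused prey categories: {list(incidence.columns[~used])}"
        )
    B = B[:, used]
    prey = list(incidence.columns[used])
    D = squareform(pdist(B.T, metric="euclidean"))
    ord_res = pcoa(DistanceMatrix(D, ids=prey), method="eigh")
    coords = ord_res.samples.to_numpy()
    keep = ord_res.eigvals.to_numpy() > 1e-10
    coords = coords[:, keep]
    odb = {}
    for i, sp in enumerate(incidence.index):
        pts = coords[B[i] > 0]
        cen = pts.mean(axis=0)
        odb[sp] = float(((pts - cen) ** 2).sum())
    odb = pd.Series(odb, name="odb")
    q33, q66 = np.percentile(odb.to_numpy(), [33, 66])
    return BreadthResult(
        odb=odb,
        prey_coordinates=pd.DataFrame(coords, index=prey),
        thresholds=(float(q33), float(q66)),
    )


def _dist_to_group_centroids(X: np.ndarray, groups: np.ndarray) -> np.ndarray:
    d = np.empty(X.shape[0])
    for g in pd.unique(groups):
        sel = groups == g
        cen = X[sel].mean(axis=0)
        d[sel] = np.linalg.norm(X[sel] - cen, axis=1)
    return d


def _anova_f(values: np.ndarray, groups: np.ndarray) -> float:
    grand = values.mean()
    ssb = ssw = 0.0
    g = 0
    for lvl in pd.unique(groups):
        sel = groups == lvl
        m = values[sel].mean()
        ssb += sel.sum() * (m - grand) ** 2
        ssw += ((values[sel] - m) ** 2).sum()
        g += 1
    dfb, dfw = g - 1, values.size - g
    if ssw <= 0 or dfw <= 0:
        return np.inf if ssb > 0 else np.nan
    return (ssb / dfb) / (ssw / dfw)


def group_dispersion(
    clr_matrix: pd.DataFrame,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> DispersionResult:
    """Homogeneity of multivariate dispersions in CLR diet space.

    Each species' dispersion is its Euclidean distance to its own group
    centroid; groups are compared by a one-way F on these distances with a
    permutation p (distances reshuffled among groups, which is exchangeable
    under the null of equal dispersions).  Singleton groups contribute a
    zero distance and are flagged; a fully degenerate dataset (no distance
    variation) is flagged with p = 1.
    """
    X = clr_matrix.to_numpy(dtype=float)
    groups = np.asarray(groups, dtype=object)
    if groups.shape[0] != X.shape[0]:
        raise ValueError("group labels do not match matrix rows")
    counts = pd.Series(groups).value_counts()
    singletons = counts.index[counts == 1].tolist()
    if singletons:
        warnings.warn(f"singleton groups (distance 0): {singletons}")
    d = _dist_to_group_centroids(X, groups)
    dser = pd.Series(d, index=clr_matrix.index, name="dist_to_centroid")
    gmeans = dser.groupby(groups).mean()
    if np.allclose(d, d[0]):
        return DispersionResult(dser, gmeans, float(d.mean()), float("nan"), 1.0,
                                n_perm, True, singletons)
    f_obs = _anova_f(d, groups)
    rng = np.random.default_rng(seed)
    f_perm = np.empty(n_perm)
    for r in range(n_perm):
        f_perm[r] = _anova_f(d, groups[rng.permutation(groups.size)])
    f_perm = np.nan_to_num(f_perm, nan=np.inf)
    p = float((1 + np.sum(f_perm >= f_obs)) / (n_perm + 1))
    return DispersionResult(dser, gmeans, float(d.mean()), float(f_obs), p,
                            n_perm, False, singletons)


def scenario_dispersion(
    clr_matrix: pd.DataFrame, scenarios: list[ExtinctionScenario]
) -> pd.DataFrame:
    """Mean (and sd of) distance to the survivor diet centroid per scenario.

    The centroid is recomputed over each scenario's survivors; a shrinking
    mean distance across nested scenarios indicates homogenization of the
    surviving prey base.
    """
    rows = []
    for sc in scenarios:
        surv = [s for s in sc.survivors if s in clr_matrix.index]
        if len(surv) < 2:
            raise ValueError(f"scenario {sc.name}: fewer than 2 survivors with diets")
        X = clr_matrix.loc[surv].to_numpy(dtype=float)
        d = np.linalg.norm(X - X.mean(axis=0), axis=1)
        rows.append(
            {"scenario": sc.name, "n_survivors": len(surv),
             "mean_dist": float(d.mean()), "sd_dist": float(d.std(ddof=1))}
        )
    return pd.DataFrame(rows)
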