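"""Extinction-scenario engine.

Species are removed sequentially by IUCN threat status (CR, then CR+EN,
then CR+EN+VU, then CR+EN+VU+NT) and the surviving morphospace is
summarized by convex-hull area, centroid shift, average pairwise
Procrustes distance (APPD) and depth range.  Monte Carlo nulls remove the
same numbers of species uniformly at random and report 95% envelopes for
mean PC1, mean PC2 and APPD, against which each targeted scenario is
classified.

APPD = 2 / (n (n-1)) * sum_{i<j} d_ij, the arithmetic mean of all pairwise
Procrustes distances; lower values indicate morphological homogenization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .morphospace import CentroidShift, HullSummary, centroid_shift, hull_area

#: the four canonical nested removal sequences
SCENARIO_SEQUENCE: tuple[tuple[str, ...], ...] = (
    ("CR",),
    ("CR", "EN"),
    ("CR", "EN", "VU"),
    ("CR", "EN", "VU", "NT"),
)


@dataclass
class ExtinctionScenario:
    name: str
    removed_statuses: tuple[str, ...]
    removed: list[str]
    survivors: list[str]


@dataclass
class NullDistribution:
    statistic: str
    k: int
    values: np.ndarray
    mean: float = field(init=False)
    lower: float = field(init=False)
    upper: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mean = float(self.values.mean())
        self.lower = float(np.percentile(self.values, 2.5))
        self.upper = float(np.percentile(self.values, 97.5))


@dataclass
class ScenarioResult:
    scenario: ExtinctionScenario
    hull: HullSummary
    pct_area_loss: float
    shift: CentroidShift
    appd: float
    depth_range: tuple[float, float] | None


def canonical_scenarios(statuses: pd.Series) -> list[ExtinctionScenario]:
    """The four nested threat-ordered scenarios from a species -> IUCN map."""
    scenarios = []
    for seq in SCENARIO_SEQUENCE:
        removed = sorted(statuses.index[statuses.isin(seq)])
        survivors = sorted(statuses.index[~statuses.isin(seq)])
        scenarios.append(ExtinctionScenario("+".join(seq), seq, removed, survivors))
    return scenarios


def appd(coordinates: np.ndarray) -> float:
    """Average pairwise Procrustes distance of n >= 2 aligned configurations."""
    X = np.asarray(coordinates, dtype=float)
    X = X.reshape(X.shape[0], -1)
    if X.shape[0] < 2:
        raise ValueError("APPD is undefined for fewer than 2 configurations")
    return float(pdist(X).mean())


def procrustes_variance(coordinates: np.ndarray, groups) -> dict:
    """Per-group mean squared Procrustes distance from the group mean shape.

    Equivalent to the trace of the within-group covariance of the aligned
    coordinates (sum of squared distances divided by group size).  Singleton
    groups are reported as NaN with a warning.
    """
    X = np.asarray(coordinates, dtype=float)
    X = X.reshape(X.shape[0], -1)
    groups = np.asarray(groups)
    out: dict = {}
    for g in pd.unique(groups):
        sel = groups == g
        n = int(sel.sum())
        if n < 2:
            warnings.warn(f"group {g!r} has a single member; Procrustes variance undefined")
            out[g] = float("nan")
            continue
        D = X[sel] - X[sel].mean(axis=0)
        out[g] = float((D * D).sum() / n)
    return out


def apply_scenario(
    scores: np.ndarray,
    coordinates: np.ndarray,
    ids: list[str],
    scenario: ExtinctionScenario,
    depths: pd.Series | None = None,
) -> ScenarioResult:
    """Summarize morphospace erosion for one removal scenario.

    ``scores`` are the fixed baseline (PC1, PC2) scores, ``coordinates``
    the aligned shapes used for APPD, both ordered as ``ids``.  Percent
    area loss is 100 * (1 - area_survivors / area_baseline).
    """
    scores = np.asarray(scores, dtype=float)[:, :2]
    coords = np.asarray(coordinates, dtype=float).reshape(len(ids), -1)
    index = {s: i for i, s in enumerate(ids)}
    unknown = [s for s in scenario.removed + scenario.survivors if s not in index]
    if unknown:
        raise ValueError(f"scenario references unknown species: {unknown}")
    surv_idx = np.array([index[s] for s in scenario.survivors], dtype=int)
    if surv_idx.size == 0:
        raise ValueError("scenario removes all species")
    base_hull = hull_area(scores)
    surv_hull = hull_area(scores[surv_idx])
    loss = (
        100.0 * (1.0 - surv_hull.area / base_hull.area) if base_hull.area > 0 else float("nan")
    )
    shift = centroid_shift(scores, surv_idx)
    if surv_idx.size >= 2:
        disp = appd(coords[surv_idx])
    else:
        warnings.warn("single survivor: APPD undefined")
        disp = float("nan")
    depth_range = None
    if depths is not None:
        d = depths.reindex(scenario.survivors).dropna()
        if len(d):
            depth_range = (float(d.min()), float(d.max()))
    return ScenarioResult(scenario, surv_hull, loss, shift, disp, depth_range)


def random_extinction_null(
    scores: np.ndarray,
    coordinates: np.ndarray,
    k: int,
    n_reps: int = 100,
    seed: int | None = None,
) -> dict[str, NullDistribution]:
    """Monte Carlo random-extinction null at intensity ``k``.

    Each replicate removes ``k`` species uniformly without replacement and
    records survivor mean PC1, mean PC2 and APPD.  Replicates draw from
    per-(k, replicate) substreams of one root seed, so results are
    reproducible and independent across intensities.
    """
    scores = np.asarray(scores, dtype=float)[:, :2]
    X = np.asarray(coordinates, dtype=float)
    X = X.reshape(X.shape[0], -1)
    n = X.shape[0]
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if not (0 < k < n):
        raise ValueError(f"intensity k={k} must be in (0, {n})")
    if n - k < 2:
        raise ValueError(f"intensity k={k} leaves fewer than 2 survivors")
    D = squareform(pdist(X))
    reps = {"mean_pc1": np.empty(n_reps), "mean_pc2": np.empty(n_reps), "appd": np.empty(n_reps)}
    for r in range(n_reps):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(k, r)))
        surv = np.sort(rng.choice(n, size=n - k, replace=False))
        reps["mean_pc1"][r] = scores[surv, 0].mean()
        reps["mean_pc2"][r] = scores[surv, 1].mean()
        sub = D[np.ix_(surv, surv)]
        m = surv.size
        reps["appd"][r] = sub[np.triu_indices(m, 1)].mean()
    return {name: NullDistribution(name, k, vals) for name, vals in reps.items()}


def targeted_vs_null(
    scenario_stat: float, null: NullDistribution, k: int | None = None
) -> str:
    """Classify a targeted-scenario statistic against the null 95% envelope.

    ``k``, when given, must match the intensity the null was built at.
    """
    if k is not None and k != null.k:
        raise ValueError(f"intensity mismatch: scenario k={k}, null k={null.k}")
    if not np.isfinite(scenario_stat):
        raise ValueError("non-finite scenario statistic")
    if scenario_stat < null.lower:
        return "below"
    if scenario_stat > null.upper:
        return "above"
    return "within"
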