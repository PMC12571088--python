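"""Permutation-based inference on shape data.

Linear models on high-dimensional Procrustes coordinates are tested with a
residual-randomization permutation procedure (RRPP): sums of squares are
traces of residual cross-products (Goodall-style), the reference
distribution comes from permuting reduced-model residuals, and effect
sizes Z are standard deviates of the log-transformed statistic within its
permutation distribution.  The observed statistic is counted in the
reference set, so p >= 1/(n_perm + 1).

Phylogenetic signal uses a multivariate generalization of Blomberg's K:
the ratio of tip-level to phylogenetically-corrected sums of squares,
summed over all coordinates and standardized by its Brownian-motion
expectation, so K has expectation 1 under Brownian evolution on the given
tree.  Significance comes from permuting species across the tips.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

_LOG_CLIP = (1e-12, 1e12)


@dataclass
class PermutationTestResult:
    r2: float
    f: float
    z: float
    p: float
    n_perm: int
    seed: int | None
    df_effect: int
    df_resid: int
    ss_effect: float
    ss_total: float


@dataclass
class PhyloSignalResult:
    k: float
    z: float
    p: float
    n_perm: int
    seed: int | None


def _z_score(obs: float, perms: np.ndarray, log: bool = True) -> float:
    ref = np.concatenate([[obs], perms])
    if log:
        ref = np.log(np.clip(ref, *_LOG_CLIP))
        obs = float(np.log(np.clip(obs, *_LOG_CLIP)))
    sd = ref.std(ddof=1)
    if sd == 0.0:
        return 0.0
    return float((obs - ref.mean()) / sd)


def _p_value(obs: float, perms: np.ndarray) -> float:
    return float((1 + np.sum(perms >= obs)) / (perms.size + 1))


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X)


def rrpp_lm(
    Y: np.ndarray,
    X_full: np.ndarray,
    X_reduced: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermutationTestResult:
    """RRPP test of a full against a nested reduced linear model.

    SS_effect = SSE(reduced) - SSE(full) where SSE is the Frobenius norm of
    the residual matrix; permuted datasets are reduced-model fitted values
    plus row-permuted reduced-model residuals.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    Hf, Hr = _hat(X_full), _hat(X_reduced)
    rank_f = int(np.linalg.matrix_rank(X_full))
    rank_r = int(np.linalg.matrix_rank(X_reduced))
    df_e = rank_f - rank_r
    df_r = n - rank_f
    if df_e < 1 or df_r < 1:
        raise ValueError("degenerate design: no effect or residual degrees of freedom")
    Rf = np.eye(n) - Hf
    Rr = np.eye(n) - Hr

    def _f_stat(Ys: np.ndarray) -> np.ndarray:
        # Ys: (..., n, p); returns F over leading axes
        ef = np.einsum("...ip,...ip->...", Rf @ Ys, Ys)
        er = np.einsum("...ip,...ip->...", Rr @ Ys, Ys)
        ss_eff = er - ef
        return (ss_eff / df_e) / np.where(ef > 0, ef / df_r, np.nan)

    ef_obs = float(np.sum((Rf @ Y) * Y))
    er_obs = float(np.sum((Rr @ Y) * Y))
    ss_effect = er_obs - ef_obs
    Yc = Y - Y.mean(axis=0)
    ss_total = float(np.sum(Yc * Yc))
    f_obs = (ss_effect / df_e) / (ef_obs / df_r) if ef_obs > 0 else np.inf

    fitted_r = Hr @ Y
    resid_r = Rr @ Y
    rng = np.random.default_rng(seed)
    f_perm = np.empty(n_perm)
    chunk = max(1, min(n_perm, int(2e7 // max(1, n * Y.shape[1]))))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        idx = np.argsort(rng.random((b, n)), axis=1)
        Ys = fitted_r[None, :, :] + resid_r[idx]
        f_perm[done : done + b] = _f_stat(Ys)
        done += b
    f_perm = np.nan_to_num(f_perm, nan=np.inf)
    p = _p_value(f_obs, f_perm)
    z = _z_score(min(f_obs, _LOG_CLIP[1]), np.minimum(f_perm, _LOG_CLIP[1]))
    r2 = ss_effect / ss_total if ss_total > 0 else float("nan")
    return PermutationTestResult(
        r2=float(r2), f=float(f_obs), z=z, p=p, n_perm=n_perm, seed=seed,
        df_effect=df_e, df_resid=df_r, ss_effect=float(ss_effect), ss_total=ss_total,
    )


def _design_factor(groups) -> np.ndarray:
    groups = pd.Series(np.asarray(groups, dtype=object))
    counts = groups.value_counts()
    if (counts == 0).any():
        raise ValueError("factor level with zero members")
    if len(counts) < 2:
        raise ValueError("need at least 2 factor levels")
    return pd.get_dummies(groups, drop_first=True).to_numpy(dtype=float)


def perm_anova(
    Y: np.ndarray,
    groups,
    covariates: np.ndarray | None = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermutationTestResult:
    """One-way (or covariate-adjusted) permutation ANOVA on shape data.

    With covariates the factor is tested against a reduced model containing
    intercept and covariates (sequential SS, covariates first); without,
    residual randomization reduces to label permutation.
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    G = _design_factor(groups)
    ones = np.ones((n, 1))
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X_red = np.hstack([ones, C])
    else:
        X_red = ones
    X_full = np.hstack([X_red, G])
    return rrpp_lm(Y, X_full, X_red, n_perm=n_perm, seed=seed)


def rrpp_terms(
    Y: np.ndarray,
    terms: list[tuple[str, np.ndarray]],
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sequential (type-I) RRPP table: each term tested against the model of
    all preceding terms.  ``terms`` are (name, design-columns) pairs in
    fitting order, e.g. log centroid size first, then species, then the
    interaction, then jaw."""
    n = np.asarray(Y).shape[0]
    X = np.ones((n, 1))
    rows = []
    for i, (name, cols) in enumerate(terms):
        cols = np.asarray(cols, dtype=float)
        if cols.ndim == 1:
            cols = cols[:, None]
        X_full = np.hstack([X, cols])
        res = rrpp_lm(Y, X_full, X, n_perm=n_perm, seed=None if seed is None else seed + i)
        rows.append(
            {"term": name, "df": res.df_effect, "ss": res.ss_effect, "r2": res.r2,
             "f": res.f, "z": res.z, "p": res.p}
        )
        X = X_full
    return pd.DataFrame(rows)


def pairwise_groups(
    Y: np.ndarray, groups, n_perm: int = 999, seed: int | None = None
) -> pd.DataFrame:
    """Permutation tests of all pairwise distances between group mean shapes.

    For each unordered pair the statistic is the Euclidean distance between
    the two group means; labels are reshuffled within the pooled pair.
    Singleton groups are allowed (the distance is defined) but flagged.
    """
    Y = np.asarray(Y, dtype=float)
    groups = np.asarray(groups, dtype=object)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    rng = np.random.default_rng(seed)
    rows = []
    for g1, g2 in itertools.combinations(levels, 2):
        sel = (groups == g1) | (groups == g2)
        Yp = Y[sel]
        lab = groups[sel] == g1
        n1 = int(lab.sum())
        d_obs = float(np.linalg.norm(Yp[lab].mean(axis=0) - Yp[~lab].mean(axis=0)))
        d_perm = np.empty(n_perm)
        for r in range(n_perm):
            perm = rng.permutation(lab.size)
            m = np.zeros(lab.size, dtype=bool)
            m[perm[:n1]] = True
            d_perm[r] = np.linalg.norm(Yp[m].mean(axis=0) - Yp[~m].mean(axis=0))
        rows.append(
            {
                "group_1": g1,
                "group_2": g2,
                "distance": d_obs,
                "z": _z_score(d_obs, d_perm, log=False),
                "p": _p_value(d_obs, d_perm),
                "singleton": n1 == 1 or (lab.size - n1) == 1,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Phylogenetic signal
# ---------------------------------------------------------------------------

def phylo_cov_matrix(tree: dendropy.Tree, taxa: list[str]) -> np.ndarray:
    """Phylogenetic covariance matrix (shared root-to-MRCA path lengths)."""
    tree = tree.clone(depth=1)
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    label = {}
    for leaf in tree.leaf_node_iter():
        label[leaf.taxon.label.replace(" ", "_")] = leaf
    missing = [t for t in taxa if t not in label]
    if missing:
        raise ValueError(f"species not found as tree tips: {missing}")
    pdm = tree.phylogenetic_distance_matrix()
    n = len(taxa)
    C = np.empty((n, n))
    for i, ti in enumerate(taxa):
        C[i, i] = label[ti].root_distance
        for j in range(i + 1, n):
            d = pdm.patristic_distance(label[ti].taxon, label[taxa[j]].taxon)
            C[i, j] = C[j, i] = 0.5 * (C[i, i] + label[taxa[j]].root_distance - d)
    return C


def _k_stat(Y: np.ndarray, Cinv: np.ndarray, w: np.ndarray, expectation: float) -> float:
    a = w @ Y  # phylogenetic mean, (p,)
    D = Y - a
    num = float(np.sum(D * D))
    den = float(np.sum(D * (Cinv @ D)))
    return (num / den) / expectation


def phylo_signal(
    Y: np.ndarray,
    tree: dendropy.Tree,
    species_ids: list[str],
    n_perm: int = 999,
    seed: int | None = None,
) -> PhyloSignalResult:
    """Multivariate Blomberg-type K with permutation p and effect size Z.

    Tree tips must exactly match ``species_ids``.  p is the proportion of
    permutations (species shuffled across tips) with K at least as large as
    observed; Z standardizes log K within its permutation distribution.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    tips = sorted(t.label.replace(" ", "_") for t in tree.taxon_namespace)
    if tips != sorted(species_ids):
        raise ValueError("tree tips do not exactly match species ids")
    if float(np.sum((Y - Y.mean(axis=0)) ** 2)) <= 0.0:
        raise ValueError("zero-variance data: phylogenetic signal undefined")
    C = phylo_cov_matrix(tree, list(species_ids))
    Cinv = np.linalg.inv(C)
    w = Cinv.sum(axis=0) / Cinv.sum()
    expectation = (np.trace(C) - n / Cinv.sum()) / (n - 1)
    k_obs = _k_stat(Y, Cinv, w, expectation)
    rng = np.random.default_rng(seed)
    k_perm = np.empty(n_perm)
    for r in range(n_perm):
        k_perm[r] = _k_stat(Y[rng.permutation(n)], Cinv, w, expectation)
    return PhyloSignalResult(
        k=float(k_obs),
        z=_z_score(k_obs, k_perm),
        p=_p_value(k_obs, k_perm),
        n_perm=n_perm,
        seed=seed,
    )
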