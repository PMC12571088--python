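"""Synthetic data generator.

Produces full datasets with the statistical structure the analysis
assumes: tooth-crown-like landmark configurations (3 fixed anchors + two
semilandmark curves, 160 points) whose species means evolve by Brownian
motion on a pure-birth tree over a low-dimensional crown parameterization
(cusp obliquity, cusp height/base-width ratio, distal-shoulder curvature);
within-species iid landmark noise plus a dignathic-heterodonty jaw effect;
5-level ordered threat statuses whose selectivity on morphology is tuned
by a single log-odds slope ``beta``; Dirichlet diet compositions whose
concentration is linked to body-size class; log-normal maximum depths.

Every quantity derives from one root seed, so a bundle is reproducible
bit-for-bit, and bundles round-trip through the TPS/CSV/newick writers and
loaders without warnings.
"""

from __future__ import annotations

import json
import random
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .io_formats import (
    Curve,
    LandmarkConfiguration,
    ROLE_FIXED,
    ROLE_SEMI,
    write_tps,
)
from .shape_core import resample_equidistant

PREY_CATEGORIES = (
    "teleosts", "elasmobranchs", "cephalopods", "crustaceans", "molluscs",
    "reptiles", "mammals", "birds", "echinoderms", "polychaetes",
)

#: valid template ranges: cusp elongation continuum, residual log height
#: ratio, distal-shoulder curvature offset
PARAM_BOUNDS = ((-3.5, 3.5), (-0.8, 0.8), (-0.15, 0.3))
PARAM_NAMES = ("elongation", "log_height", "shoulder")


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset."""

    n_species: int = 30
    teeth_per_species: tuple[int, int] = (14, 69)
    n_fixed: int = 3
    n_semi: int = 157
    sigma2_b: float = 1.0                       # BM rate multiplier (unit-depth tree)
    param_scales: tuple[float, float, float] = (0.2, 0.12, 0.05)
    jump_prob: float = 0.15                     # per-species chance of a specialization jump
    jump_scale: float = 0.6                     # exponential scale of jumps (elongation axis)
    sigma_w: float = 0.01                       # within-species landmark noise (coordinate units)
    beta: float = 0.0                           # threat selectivity on the first crown parameter
    status_counts: dict = field(
        default_factory=lambda: {"CR": 4, "EN": 8, "VU": 10, "NT": 4, "LC": 4}
    )
    genus_total_species: int = 35               # pool the sampled species are drawn from
    lower_jaw_width_factor: float = 0.85        # dignathic heterodonty: narrower lower cusps
    diet_concentration: dict = field(
        default_factory=lambda: {"small": 0.6, "medium": 1.2, "large": 2.5}
    )
    diet_zero_threshold: float = 0.03           # proportions below this are recorded as 0
    depth_lognorm: tuple[float, float] = (4.6, 0.9)
    length_lognorm: tuple[float, float] = (5.19, 0.45)
    length_shape_slope: float = 0.4             # couples body length to cusp obliquity

    def validate(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if sum(self.status_counts.values()) != self.n_species:
            raise ValueError(
                f"status counts {self.status_counts} do not sum to n_species={self.n_species}"
            )
        lo, hi = self.teeth_per_species
        if not (1 <= lo <= hi):
            raise ValueError("invalid teeth_per_species range")


@dataclass
class Bundle:
    configurations: list[LandmarkConfiguration]
    traits: pd.DataFrame
    diets: pd.DataFrame
    tree: dendropy.Tree
    species_params: pd.DataFrame
    config: GeneratorConfig
    seed: int


def _child_seed(seed: int, key: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(key,)).generate_state(1)[0] % 2**31)


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------

def simulate_tree(n_species: int, seed: int | None = None) -> dendropy.Tree:
    """Ultrametric pure-birth tree scaled to unit depth, tips sp001..spN."""
    if n_species < 2:
        raise ValueError("need at least 2 species")
    from dendropy.simulate import treesim

    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=rng,
    )
    # the process stops exactly at the n-th speciation, leaving zero-length
    # terminal edges on the last cherry; run the clock for one more waiting
    # time so every tip edge is positive
    extra = rng.expovariate(n_species)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    depth = max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    # equalize residual floating error so the tree is exactly ultrametric
    for leaf in tree.leaf_node_iter():
        leaf.edge.length += 1.0 - leaf.distance_from_root()
    width = max(3, len(str(n_species)))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{i:0{width}d}"
    return tree


# ---------------------------------------------------------------------------
# Crown template
# ---------------------------------------------------------------------------

def _bezier(p0, c, p2, n=300) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * c + t**2 * p2


def crown_template(
    params: np.ndarray, n_semi: int = 157, width_factor: float = 1.0
) -> tuple[np.ndarray, np.ndarray, list[Curve]]:
    """Map crown parameters to a 160-point tooth outline.

    Fixed landmarks: mesial crown-root corner, apex, distal corner.  Two
    equidistantly resampled quadratic curves run base-to-apex (mesial) and
    apex-to-base (distal).  The apex is the unique global y-maximum by
    construction.  Returns (points, roles, curves) in the canonical order:
    the 3 fixed landmarks first, then the two curves' semilandmarks.

    The first parameter is the main morphological continuum (elongation):
    high values give upright, elongated triangular cusps, low values give
    distally oblique, short crowns — obliquity and crown height co-vary,
    as they do along the dominant axis of real tooth morphospaces.
    Obliquity saturates smoothly (the apex cannot lean past the distal
    corner) while crown height responds log-linearly, so strongly
    divergent species become genuine shape outliers rather than piling up
    at a geometric bound.  The second parameter is residual (log) crown
    height, the third the distal-shoulder curvature.
    """
    s1, s2, s3 = (float(np.clip(v, lo, hi)) for v, (lo, hi) in zip(params, PARAM_BOUNDS))
    obliq = 1.0 / (1.0 + np.exp(s1 / 0.2))  # 0 = upright/elongate, 1 = oblique/short
    h = 1.2 * np.exp(s2 + 0.9 * np.clip(s1, -2.5, 2.5)) * (1.6 - 1.1 * obliq) / 1.05
    base_m = np.array([-0.5, 0.0])
    base_d = np.array([0.5, 0.0])
    apex = np.array([0.45 * obliq, h])
    ctrl_m = np.array([(base_m[0] + apex[0]) / 2 - 0.15, 0.45 * h])
    ctrl_d = np.array([(base_d[0] + apex[0]) / 2 + 0.18 + s3, 0.45 * h])
    n_mesial = n_semi // 2
    n_distal = n_semi - n_mesial
    mesial = resample_equidistant(_bezier(base_m, ctrl_m, apex), n_mesial + 2)[1:-1]
    distal = resample_equidistant(_bezier(apex, ctrl_d, base_d), n_distal + 2)[1:-1]
    points = np.vstack([base_m, apex, base_d, mesial, distal])
    points[:, 0] *= width_factor
    roles = np.array(
        [ROLE_FIXED] * 3 + [ROLE_SEMI] * n_semi, dtype=object
    )
    curves = [
        Curve(3, 3 + n_mesial, (0, 1)),
        Curve(3 + n_mesial, 3 + n_semi, (1, 2)),
    ]
    return points, roles, curves


def _clipped(values: np.ndarray) -> np.ndarray:
    lo = np.array([b[0] for b in PARAM_BOUNDS])
    hi = np.array([b[1] for b in PARAM_BOUNDS])
    clipped = np.clip(values, lo, hi)
    if np.any(clipped != values):
        warnings.warn("crown parameters outside template range were clipped")
    return clipped


# ---------------------------------------------------------------------------
# Brownian evolution of species shapes
# ---------------------------------------------------------------------------

def simulate_species_shapes(
    tree: dendropy.Tree,
    sigma2_b: float = 1.0,
    seed: int | None = None,
    param_scales: tuple[float, float, float] = (0.2, 0.12, 0.05),
    n_semi: int = 157,
    jump_prob: float = 0.15,
    jump_scale: float = 0.6,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Crown parameters evolved on the tree plus tip mean configurations.

    Each parameter diffuses by Brownian motion with per-unit-depth
    standard deviation ``scale * sqrt(sigma2_b)`` from a zero root.  On
    top of the diffusion, each species independently experiences (with
    probability ``jump_prob``) one exponential specialization jump of
    scale ``jump_scale * sqrt(sigma2_b)`` along the positive elongation
    axis — punctuated divergence toward distinctive, elongate-cusped
    morphologies, which places a handful of species in the morphospace
    periphery the way real specialist lineages are.  Values outside the
    template's valid range are clipped with a warning.
    """
    if sigma2_b < 0:
        raise ValueError("sigma2_b must be non-negative")
    rng = np.random.default_rng(seed)
    scales = np.asarray(param_scales, dtype=float)
    values: dict[int, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = np.zeros(3)
        else:
            el = node.edge.length or 0.0
            step = rng.normal(0.0, np.sqrt(max(el, 0.0) * sigma2_b) * scales)
            values[id(node)] = values[id(node.parent_node)] + step
    rows = {}
    for leaf in tree.leaf_node_iter():
        rows[leaf.taxon.label.replace(" ", "_")] = values[id(leaf)]
    params = pd.DataFrame.from_dict(rows, orient="index", columns=list(PARAM_NAMES))
    params = params.sort_index()
    if jump_prob > 0 and sigma2_b > 0:
        n = len(params)
        jumps = (rng.random(n) < jump_prob) * rng.exponential(
            jump_scale * np.sqrt(sigma2_b), size=n
        )
        params.iloc[:, 0] += jumps
    params.loc[:, :] = _clipped(params.to_numpy())
    means = {
        sp: crown_template(params.loc[sp].to_numpy(), n_semi=n_semi)[0]
        for sp in params.index
    }
    return params, means


# ---------------------------------------------------------------------------
# Specimens
# ---------------------------------------------------------------------------

def simulate_specimens(
    species_params: pd.DataFrame,
    cfg: GeneratorConfig,
    seed: int | None = None,
) -> list[LandmarkConfiguration]:
    """Draw per-species tooth specimens with landmark noise and a jaw effect.

    Tooth counts are uniform over ``cfg.teeth_per_species``; each tooth is
    the species template (lower-jaw teeth built with a narrowed cusp,
    emulating dignathic heterodonty) plus iid Gaussian coordinate noise
    ``sigma_w``.
    """
    if cfg.sigma_w < 0:
        raise ValueError("sigma_w must be non-negative")
    rng = np.random.default_rng(seed)
    lo, hi = cfg.teeth_per_species
    configs: list[LandmarkConfiguration] = []
    serial = 0
    for sp in species_params.index:
        p = species_params.loc[sp].to_numpy()
        n_teeth = int(rng.integers(lo, hi + 1))
        pos = {"upper": 0, "lower": 0}
        for _ in range(n_teeth):
            jaw = "upper" if rng.random() < 0.5 else "lower"
            pos[jaw] += 1
            wf = cfg.lower_jaw_width_factor if jaw == "lower" else 1.0
            pts, roles, curves = crown_template(p, n_semi=cfg.n_semi, width_factor=wf)
            pts = pts + rng.normal(0.0, cfg.sigma_w, size=pts.shape)
            serial += 1
            configs.append(
                LandmarkConfiguration(
                    specimen_id=f"{sp}__{jaw}__{pos[jaw]}__right__{serial:05d}",
                    species_id=sp,
                    jaw=jaw,
                    tooth_position=pos[jaw],
                    side="right",
                    points=pts,
                    roles=roles,
                    curves=curves,
                    scale=1.0,
                )
            )
    return configs


# ---------------------------------------------------------------------------
# Statuses, traits, diets
# ---------------------------------------------------------------------------

def assign_statuses_and_traits(
    species_params: pd.DataFrame,
    cfg: GeneratorConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Threat statuses (morphology-selective when beta > 0), traits and diets.

    Species are ranked by ``beta * z1 + Gumbel noise`` where z1 is the
    standardized first crown parameter; the top ranks fill CR, then EN, VU,
    NT, LC according to the configured counts, so beta = 0 makes threat
    independent of shape.  Body length couples to z1, size classes cut at
    150/300 cm, diets are Dirichlet with size-class-linked concentration
    (larger classes more even), depths log-normal.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    species = list(species_params.index)
    n = len(species)
    s1 = species_params.iloc[:, 0].to_numpy()
    sd = s1.std()
    z1 = (s1 - s1.mean()) / (sd if sd > 0 else 1.0)
    utility = cfg.beta * z1 + rng.gumbel(0.0, 1.0, size=n)
    order = np.argsort(-utility)
    status = np.empty(n, dtype=object)
    cursor = 0
    for cat in ("CR", "EN", "VU", "NT", "LC"):
        c = cfg.status_counts.get(cat, 0)
        status[order[cursor : cursor + c]] = cat
        cursor += c
    mu_l, sd_l = cfg.length_lognorm
    length = np.exp(mu_l + cfg.length_shape_slope * z1 + rng.normal(0.0, sd_l, size=n))
    size_class = np.where(length < 150, "small", np.where(length <= 300, "medium", "large"))
    mu_d, sd_d = cfg.depth_lognorm
    depth = np.clip(np.exp(rng.normal(mu_d, sd_d, size=n)), 5.0, 2000.0)
    coastal = rng.random(n) < 0.7
    reef = coastal & (rng.random(n) < 0.6)
    traits = pd.DataFrame(
        {
            "iucn": status,
            "body_size_class": size_class,
            "habitat": np.where(coastal, "coastal", "pelagic"),
            "reef_associated": reef,
            "max_depth_m": np.round(depth, 1),
            "total_length_cm": np.round(length, 1),
        },
        index=pd.Index(species, name="species_id"),
    )
    diet_rows = np.empty((n, len(PREY_CATEGORIES)))
    for i in range(n):
        conc = cfg.diet_concentration[str(size_class[i])]
        row = rng.dirichlet(np.full(len(PREY_CATEGORIES), conc))
        row[row < cfg.diet_zero_threshold] = 0.0
        if row.sum() == 0:  # pathological draw; fall back to uniform
            row[:] = 1.0
        diet_rows[i] = row / row.sum()
    diets = pd.DataFrame(
        diet_rows, index=pd.Index(species, name="species_id"), columns=list(PREY_CATEGORIES)
    )
    return traits, diets


# ---------------------------------------------------------------------------
# Bundle assembly and serialization
# ---------------------------------------------------------------------------

def generate_bundle(
    cfg: GeneratorConfig | None = None,
    seed: int = 0,
    include_specimens: bool = True,
) -> Bundle:
    """Generate a complete dataset from one root seed."""
    cfg = cfg or GeneratorConfig()
    cfg.validate()
    tree = simulate_tree(cfg.n_species, seed=_child_seed(seed, 0))
    params, _means = simulate_species_shapes(
        tree, cfg.sigma2_b, seed=_child_seed(seed, 1),
        param_scales=cfg.param_scales, n_semi=cfg.n_semi,
        jump_prob=cfg.jump_prob, jump_scale=cfg.jump_scale,
    )
    if include_specimens:
        configs = simulate_specimens(params, cfg, seed=_child_seed(seed, 2))
    else:
        configs = species_mean_configurations(params, cfg)
    traits, diets = assign_statuses_and_traits(params, cfg, seed=_child_seed(seed, 3))
    return Bundle(configs, traits, diets, tree, params, cfg, seed)


def species_mean_configurations(
    species_params: pd.DataFrame, cfg: GeneratorConfig | None = None
) -> list[LandmarkConfiguration]:
    """One noise-free upper-jaw configuration per species (its true mean)."""
    cfg = cfg or GeneratorConfig()
    configs = []
    for i, sp in enumerate(species_params.index, start=1):
        pts, roles, curves = crown_template(
            species_params.loc[sp].to_numpy(), n_semi=cfg.n_semi
        )
        configs.append(
            LandmarkConfiguration(
                specimen_id=f"{sp}__upper__1__right__{i:05d}",
                species_id=sp,
                jaw="upper",
                tooth_position=1,
                side="right",
                points=pts,
                roles=roles,
                curves=curves,
            )
        )
    return configs


def write_bundle(bundle: Bundle, out_dir: str | Path) -> dict[str, Path]:
    """Serialize a bundle as TPS + CSV + newick + a ground-truth manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tps": out / "landmarks.tps",
        "traits": out / "traits.csv",
        "diets": out / "diets.csv",
        "tree": out / "tree.nwk",
        "manifest": out / "truth.json",
    }
    paths["tps"].write_text(write_tps(bundle.configurations))
    bundle.traits.to_csv(paths["traits"])
    bundle.diets.to_csv(paths["diets"])
    bundle.tree.write(path=str(paths["tree"]), schema="newick", suppress_rooting=True)
    manifest = {
        "seed": bundle.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(bundle.config).items()},
        "species_params": {
            sp: bundle.species_params.loc[sp].tolist() for sp in bundle.species_params.index
        },
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=1))
    return paths
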