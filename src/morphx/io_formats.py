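"""Readers and writers for the pipeline's external formats.

Landmark data travel as TPS files (the dialect emitted by TpsDig-style
digitizers: ``LM=`` blocks of fixed landmarks, optional ``CURVES=`` /
``POINTS=`` blocks of semilandmark curves, plus ``ID=``, ``IMAGE=`` and
``SCALE=`` records).  Species traits and diet compositions are CSV tables,
the phylogeny is newick.  ``load_dataset`` joins everything into a single
validated :class:`Dataset`.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

IUCN_LEVELS = ("CR", "EN", "VU", "NT", "LC")
THREATENED = frozenset({"CR", "EN", "VU"})
BODY_SIZE_CLASSES = ("small", "medium", "large")

ROLE_FIXED = "fixed"
ROLE_SEMI = "semilandmark"

#: specimen id convention used by the synthetic generator and understood by
#: the parser: ``<species>__<jaw>__<position>__<side>__<serial>``
_SPECIMEN_ID_RE = re.compile(
    r"^(?P<species>.+?)__(?P<jaw>upper|lower)__(?P<pos>\d+)__"
    r"(?P<side>left|right)__(?P<serial>\w+)$"
)


class TPSParseError(ValueError):
    """Raised on malformed TPS records."""


class DatasetError(ValueError):
    """Raised when the joined dataset violates its contracts."""


@dataclass(frozen=True)
class Curve:
    """Index range of one semilandmark curve plus its fixed anchors.

    ``start``/``stop`` are a half-open range into the configuration's point
    array; ``anchors`` are the indices of the two fixed landmarks flanking
    the curve (start side, end side).
    """

    start: int
    stop: int
    anchors: tuple[int, int]

    @property
    def indices(self) -> np.ndarray:
        return np.arange(self.start, self.stop)

    def __len__(self) -> int:
        return self.stop - self.start


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 2D landmark configuration.

    Coordinates are stored after scale application (a common physical length
    unit) and after mirroring left-side specimens about the vertical axis, so
    every configuration shares one standard orientation (labial view, apex
    up, right side).
    """

    specimen_id: str
    species_id: str
    points: np.ndarray
    roles: np.ndarray
    curves: list[Curve]
    jaw: str = "upper"
    tooth_position: int = 1
    side: str = "right"
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.roles = np.asarray(self.roles, dtype=object)
        self.validate()

    # -- structure --------------------------------------------------------
    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def fixed_mask(self) -> np.ndarray:
        return self.roles == ROLE_FIXED

    @property
    def semi_mask(self) -> np.ndarray:
        return self.roles == ROLE_SEMI

    def structure_signature(self) -> tuple:
        """Hashable summary used to check that configurations are conformable."""
        return (
            self.n_points,
            tuple(self.roles),
            tuple((c.start, c.stop, c.anchors) for c in self.curves),
        )

    def validate(self) -> None:
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError(
                f"{self.specimen_id}: points must be (n, 2), got {self.points.shape}"
            )
        if self.points.shape[0] != self.roles.shape[0]:
            raise ValueError(f"{self.specimen_id}: roles/points length mismatch")
        if not np.all(np.isfinite(self.points)):
            raise ValueError(f"{self.specimen_id}: non-finite coordinates")
        bad = set(self.roles) - {ROLE_FIXED, ROLE_SEMI}
        if bad:
            raise ValueError(f"{self.specimen_id}: unknown roles {bad}")
        if self.jaw not in ("upper", "lower"):
            raise ValueError(f"{self.specimen_id}: jaw must be upper|lower")
        if self.side not in ("left", "right"):
            raise ValueError(f"{self.specimen_id}: side must be left|right")
        # every semilandmark belongs to exactly one curve
        membership = np.zeros(self.n_points, dtype=int)
        for c in self.curves:
            if not (0 <= c.start <= c.stop <= self.n_points):
                raise ValueError(f"{self.specimen_id}: curve range out of bounds")
            membership[c.start : c.stop] += 1
            for a in c.anchors:
                if self.roles[a] != ROLE_FIXED:
                    raise ValueError(
                        f"{self.specimen_id}: curve anchor {a} is not a fixed landmark"
                    )
            # no two consecutive curve points coincident (including anchors)
            seq = np.vstack(
                [self.points[c.anchors[0]], self.points[c.start : c.stop], self.points[c.anchors[1]]]
            )
            steps = np.linalg.norm(np.diff(seq, axis=0), axis=1)
            if np.any(steps == 0.0):
                raise ValueError(f"{self.specimen_id}: coincident consecutive curve points")
        if np.any(membership[self.semi_mask] != 1):
            raise ValueError(
                f"{self.specimen_id}: every semilandmark must belong to exactly one curve"
            )
        if np.any(membership[self.fixed_mask] != 0):
            raise ValueError(f"{self.specimen_id}: fixed landmark inside a curve range")


# ---------------------------------------------------------------------------
# TPS parsing / writing
# ---------------------------------------------------------------------------

def _parse_specimen_id(raw: str) -> dict:
    m = _SPECIMEN_ID_RE.match(raw)
    if m is None:
        return {"species_id": raw, "jaw": "upper", "tooth_position": 1, "side": "right"}
    return {
        "species_id": m.group("species"),
        "jaw": m.group("jaw"),
        "tooth_position": int(m.group("pos")),
        "side": m.group("side"),
    }


def _read_coord_lines(lines: list[str], pos: int, count: int, record: str) -> tuple[np.ndarray, int]:
    pts = np.empty((count, 2), dtype=float)
    for i in range(count):
        if pos >= len(lines):
            raise TPSParseError(f"record {record}: expected {count} points, file ended after {i}")
        parts = lines[pos].split()
        if len(parts) != 2:
            raise TPSParseError(
                f"record {record}: expected {count} coordinate lines, "
                f"found non-coordinate line {lines[pos]!r} after {i}"
            )
        try:
            pts[i] = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise TPSParseError(f"record {record}: bad coordinate line {lines[pos]!r}") from exc
        pos += 1
    return pts, pos


def _infer_anchors(n_fixed: int, n_curves: int, fixed_pts: np.ndarray,
                   curve_pts: list[np.ndarray]) -> list[tuple[int, int]]:
    """Anchor assignment for curves read from a TPS file.

    With ``n_curves == n_fixed - 1`` the fixed landmarks are taken as the
    ordered chain of anchors (curve i runs between fixed i and i+1, the
    digitization convention).  Otherwise the nearest fixed landmark to each
    curve endpoint is used.
    """
    if n_curves == n_fixed - 1:
        return [(i, i + 1) for i in range(n_curves)]
    anchors = []
    for pts in curve_pts:
        a0 = int(np.argmin(np.linalg.norm(fixed_pts - pts[0], axis=1)))
        a1 = int(np.argmin(np.linalg.norm(fixed_pts - pts[-1], axis=1)))
        anchors.append((a0, a1))
    return anchors


def parse_tps(stream: str) -> list[LandmarkConfiguration]:
    """Parse TPS text into landmark configurations.

    ``SCALE=`` multiplies the raw digitizer coordinates; left-side specimens
    are mirrored about the vertical axis so that all output shares the
    standard (right-side) orientation.  Unknown key=value records are
    ignored with a warning.
    """
    lines = [ln.strip() for ln in stream.splitlines() if ln.strip()]
    configs: list[LandmarkConfiguration] = []
    pos = 0
    record_no = 0
    while pos < len(lines):
        line = lines[pos]
        if not line.upper().startswith("LM="):
            raise TPSParseError(f"expected LM= record at line {pos + 1}, got {line!r}")
        record_no += 1
        rec = f"#{record_no}"
        n_fixed = int(line.split("=", 1)[1])
        pos += 1
        fixed_pts, pos = _read_coord_lines(lines, pos, n_fixed, rec)
        curve_pts: list[np.ndarray] = []
        meta: dict[str, str] = {}
        while pos < len(lines) and not lines[pos].upper().startswith("LM="):
            key, _, value = lines[pos].partition("=")
            key = key.upper()
            if key == "CURVES":
                n_curves = int(value)
                pos += 1
                for _ in range(n_curves):
                    if pos >= len(lines) or not lines[pos].upper().startswith("POINTS="):
                        raise TPSParseError(f"record {rec}: expected POINTS= block")
                    m = int(lines[pos].split("=", 1)[1])
                    pos += 1
                    pts, pos = _read_coord_lines(lines, pos, m, rec)
                    curve_pts.append(pts)
            elif key in ("ID", "SCALE", "IMAGE"):
                meta[key] = value
                pos += 1
            elif "=" in lines[pos]:
                warnings.warn(f"record {rec}: ignoring unsupported TPS key {key!r}")
                pos += 1
            else:
                raise TPSParseError(f"record {rec}: unexpected line {lines[pos]!r}")
        if "ID" not in meta:
            raise TPSParseError(f"record {rec}: missing ID= field")
        scale = float(meta.get("SCALE", 1.0))
        ident = _parse_specimen_id(meta["ID"])
        anchors = _infer_anchors(n_fixed, len(curve_pts), fixed_pts, curve_pts)
        points = [fixed_pts]
        roles = [ROLE_FIXED] * n_fixed
        curves = []
        offset = n_fixed
        for pts, anc in zip(curve_pts, anchors):
            points.append(pts)
            roles += [ROLE_SEMI] * len(pts)
            curves.append(Curve(offset, offset + len(pts), anc))
            offset += len(pts)
        pts_all = np.vstack(points) * scale
        if ident["side"] == "left":
            pts_all = pts_all.copy()
            pts_all[:, 0] = -pts_all[:, 0]
        configs.append(
            LandmarkConfiguration(
                specimen_id=meta["ID"],
                points=pts_all,
                roles=np.array(roles, dtype=object),
                curves=curves,
                scale=scale,
                **ident,
            )
        )
    return configs


def write_tps(configs: Sequence[LandmarkConfiguration], decimals: int = 6) -> str:
    """Serialize configurations to TPS text (inverse of :func:`parse_tps`)."""
    out: list[str] = []
    fmt = f"%.{decimals}f %.{decimals}f"
    for cfg in configs:
        pts = cfg.points / cfg.scale
        if cfg.side == "left":
            pts = pts.copy()
            pts[:, 0] = -pts[:, 0]
        fixed_idx = np.flatnonzero(cfg.fixed_mask)
        out.append(f"LM={fixed_idx.size}")
        out += [fmt % tuple(pts[i]) for i in fixed_idx]
        if cfg.curves:
            out.append(f"CURVES={len(cfg.curves)}")
            for c in cfg.curves:
                out.append(f"POINTS={len(c)}")
                out += [fmt % tuple(pts[i]) for i in c.indices]
        out.append(f"ID={cfg.specimen_id}")
        out.append(f"SCALE={cfg.scale:g}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Tables, tree, dataset
# ---------------------------------------------------------------------------

def load_traits(path: str | Path) -> pd.DataFrame:
    """Species trait table: IUCN status, size class, habitat, depth, length."""
    df = pd.read_csv(path)
    required = {"species_id", "iucn", "body_size_class", "habitat",
                "reef_associated", "max_depth_m", "total_length_cm"}
    missing = required - set(df.columns)
    if missing:
        raise DatasetError(f"traits table missing columns: {sorted(missing)}")
    bad = set(df["iucn"]) - set(IUCN_LEVELS)
    if bad:
        raise DatasetError(f"unknown IUCN categories: {sorted(bad)}")
    if df["species_id"].duplicated().any():
        dups = df.loc[df["species_id"].duplicated(), "species_id"].tolist()
        raise DatasetError(f"duplicate species in traits: {dups}")
    return df.set_index("species_id")


def load_diets(path: str | Path, tol: float = 1e-6) -> pd.DataFrame:
    """Species-by-prey proportional diet matrix.

    Rows are renormalized to sum to one; prey columns that are zero in every
    species carry no information and are dropped with a warning.
    """
    df = pd.read_csv(path).set_index("species_id")
    if (df.values < 0).any():
        raise DatasetError("diet proportions must be non-negative")
    zero_cols = df.columns[(df == 0).all(axis=0)]
    if len(zero_cols):
        warnings.warn(f"dropping all-zero prey categories: {list(zero_cols)}")
        df = df.drop(columns=zero_cols)
    row_sums = df.sum(axis=1)
    if (row_sums <= 0).any():
        empty = row_sums.index[row_sums <= 0].tolist()
        raise DatasetError(f"species with all-zero diets: {empty}")
    df = df.div(row_sums, axis=0)
    assert np.allclose(df.sum(axis=1), 1.0, atol=tol)
    return df


def load_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


@dataclass
class Dataset:
    """Joined landmark + trait + diet + tree bundle for one analysis run."""

    configurations: list[LandmarkConfiguration]
    traits: pd.DataFrame
    diets: pd.DataFrame | None = None
    tree: dendropy.Tree | None = None
    coverage: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def species_ids(self) -> list[str]:
        return sorted({c.species_id for c in self.configurations})

    @property
    def n_specimens(self) -> int:
        return len(self.configurations)


def load_dataset(
    tps_files: Iterable[str | Path] | str | Path,
    traits: str | Path,
    diets: str | Path | None = None,
    tree: str | Path | None = None,
) -> Dataset:
    """Assemble and cross-validate the full dataset.

    Species present in the landmark files but absent from the traits table
    are a hard error; species missing from the diets table or the tree are
    retained and flagged in ``coverage`` (shape coverage typically exceeds
    diet coverage).
    """
    if isinstance(tps_files, (str, Path)):
        tps_files = [tps_files]
    configs: list[LandmarkConfiguration] = []
    for f in tps_files:
        configs.extend(parse_tps(Path(f).read_text()))
    seen: set[str] = set()
    for c in configs:
        if c.specimen_id in seen:
            raise DatasetError(f"duplicate specimen_id: {c.specimen_id}")
        seen.add(c.specimen_id)

    traits_df = load_traits(traits)
    species = sorted({c.species_id for c in configs})
    missing = [s for s in species if s not in traits_df.index]
    if missing:
        raise DatasetError(f"species missing from traits table: {missing}")

    diets_df = load_diets(diets) if diets is not None else None
    tree_obj = load_tree(tree) if tree is not None else None
    if tree_obj is not None:
        tips = {t.label.replace(" ", "_") for t in tree_obj.taxon_namespace}
        extra = sorted(tips - set(species))
        if extra:
            raise DatasetError(f"tree tips not matching any landmark species: {extra}")

    cov = pd.DataFrame(index=pd.Index(species, name="species_id"))
    cov["has_diet"] = (
        [s in diets_df.index for s in species] if diets_df is not None else False
    )
    if tree_obj is not None:
        tips = {t.label.replace(" ", "_") for t in tree_obj.taxon_namespace}
        cov["has_tree"] = [s in tips for s in species]
    else:
        cov["has_tree"] = False
    return Dataset(configs, traits_df, diets_df, tree_obj, cov)
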