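"""Landmark point schema, landmark configurations and cohort tables.

The pipeline works on ordered 2-D landmark outlines of the left proximal
femur plus the superior acetabulum (85 points by default, coordinates in
mm).  A handful of anatomically named index sets drive every downstream
measurement: the femoral-head points used for the head-circle fit, the
superior head and acetabular points used for minimum joint-space width,
the lateral acetabular edge used for the centre-edge angle, and the neck,
shaft and trochanter regions used for the remaining morphometrics.

Conventions
-----------
* Point indices are **1-based** everywhere in the public API ("points
  15-28" style); conversion to 0-based happens only internally.
* Coordinates are in mm with x medial-positive and y superior-positive
  (left hip, AP view).  Image-native y-down files can be flipped at read
  time with ``flip_y=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "PointSchema",
    "LandmarkConfiguration",
    "CohortTable",
    "SchemaError",
    "PointsParseError",
    "DEFAULT_SCHEMA",
    "COHORT_COLUMNS",
    "OSTEOPHYTE_SITES",
    "read_points",
    "write_points",
    "read_points_dir",
    "write_points_dir",
    "read_cohort",
    "write_cohort",
]


class SchemaError(ValueError):
    """A landmark configuration or index set violates the point schema."""


class PointsParseError(ValueError):
    """A landmark points file could not be parsed."""


def _as_index_tuple(idx: Iterable[int]) -> tuple[int, ...]:
    return tuple(int(i) for i in idx)


def _rng_tuple(lo: int, hi: int) -> tuple[int, ...]:
    return tuple(range(lo, hi + 1))


# Osteophyte sites graded on hip DXA: lateral acetabulum, superolateral
# femoral head, inferomedial femoral head.
OSTEOPHYTE_SITES = ("lat_acetabulum", "sup_lat_head", "inf_med_head")


@dataclass(frozen=True)
class PointSchema:
    """Named anatomical index sets over an ordered landmark outline.

    Defaults follow the 85-point left-hip annotation scheme: femoral head
    circle points 15-28, superior femoral head 22-31, acetabulum 78-84
    with the lateral acetabular edge at point 78.  The remaining sets
    (neck borders, shaft borders, trochanters) are configuration defaults
    matching :func:`hipshape.simulate.make_template`.
    """

    n_points: int = 85
    head_circle_idx: tuple[int, ...] = field(default_factory=lambda: _rng_tuple(15, 28))
    superior_head_idx: tuple[int, ...] = field(default_factory=lambda: _rng_tuple(22, 31))
    acetabulum_idx: tuple[int, ...] = field(default_factory=lambda: _rng_tuple(78, 84))
    lateral_acetabular_edge_idx: int = 78
    superior_neck_idx: tuple[int, ...] = field(default_factory=lambda: _rng_tuple(35, 42))
    inferior_neck_idx: tuple[int, ...] = field(default_factory=lambda: _rng_tuple(11, 14))
    shaft_medial_idx: tuple[int, ...] = field(default_factory=lambda: _rng_tuple(1, 6))
    shaft_lateral_idx: tuple[int, ...] = field(default_factory=lambda: _rng_tuple(59, 70))
    lesser_troch_idx: tuple[int, ...] = field(default_factory=lambda: _rng_tuple(7, 10))
    greater_troch_idx: tuple[int, ...] = field(default_factory=lambda: _rng_tuple(43, 58))
    # Outline order of the head-neck walk used by the alpha angle: superior
    # head continuing into the superior neck and greater trochanter.
    head_neck_junction_idx: tuple[int, ...] = field(default_factory=lambda: _rng_tuple(29, 34))

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise SchemaError(f"n_points must be >= 3, got {self.n_points}")
        for name, idx in self._index_sets().items():
            if len(idx) == 0:
                raise SchemaError(f"index set {name!r} is empty")
            bad = [i for i in idx if not 1 <= i <= self.n_points]
            if bad:
                raise SchemaError(
                    f"index set {name!r} has indices {bad} outside [1, {self.n_points}]"
                )
        if len(self.head_circle_idx) < 3:
            raise SchemaError("head_circle_idx needs >= 3 points to fit a circle")
        if not 1 <= self.lateral_acetabular_edge_idx <= self.n_points:
            raise SchemaError(
                f"lateral_acetabular_edge_idx {self.lateral_acetabular_edge_idx} "
                f"outside [1, {self.n_points}]"
            )

    def _index_sets(self) -> dict[str, tuple[int, ...]]:
        return {
            "head_circle_idx": self.head_circle_idx,
            "superior_head_idx": self.superior_head_idx,
            "acetabulum_idx": self.acetabulum_idx,
            "superior_neck_idx": self.superior_neck_idx,
            "inferior_neck_idx": self.inferior_neck_idx,
            "shaft_medial_idx": self.shaft_medial_idx,
            "shaft_lateral_idx": self.shaft_lateral_idx,
            "lesser_troch_idx": self.lesser_troch_idx,
            "greater_troch_idx": self.greater_troch_idx,
            "head_neck_junction_idx": self.head_neck_junction_idx,
        }

    def to0(self, idx: int | Iterable[int]) -> np.ndarray:
        """1-based index/indices -> 0-based numpy index array."""
        if isinstance(idx, (int, np.integer)):
            return np.asarray([int(idx) - 1])
        return np.asarray([int(i) - 1 for i in idx])

    def to_dict(self) -> dict:
        d = {"n_points": self.n_points,
             "lateral_acetabular_edge_idx": self.lateral_acetabular_edge_idx}
        d.update({k: list(v) for k, v in self._index_sets().items()})
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PointSchema":
        kwargs = dict(d)
        for k, v in list(kwargs.items()):
            if isinstance(v, list):
                kwargs[k] = _as_index_tuple(v)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PointSchema":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


DEFAULT_SCHEMA = PointSchema()


@dataclass
class LandmarkConfiguration:
    """One subject's ordered 2-D landmark outline (mm, left hip AP view)."""

    subject_id: str
    points: np.ndarray  # (n_points, 2) float64
    side: str = "left"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise SchemaError(f"points must be (n, 2), got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise SchemaError(f"subject {self.subject_id}: non-finite coordinates")
        if pts.shape[0] == 0:
            raise SchemaError(f"subject {self.subject_id}: empty configuration")
        d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(d <= 0):
            j = int(np.argmin(d)) + 1  # 1-based first point of coincident pair
            raise SchemaError(
                f"subject {self.subject_id}: consecutive points {j} and {j + 1} coincide"
            )
        if self.side != "left":
            raise SchemaError(f"only left hips are supported, got side={self.side!r}")
        self.points = pts

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def validate_against(self, schema: PointSchema) -> None:
        if self.n_points != schema.n_points:
            raise SchemaError(
                f"subject {self.subject_id}: {self.n_points} points, "
                f"schema expects {schema.n_points}"
            )

    def get(self, idx: int | Iterable[int]) -> np.ndarray:
        """Coordinates for 1-based index/indices, shape (k, 2)."""
        if isinstance(idx, (int, np.integer)):
            idx = [int(idx)]
        return self.points[np.asarray([int(i) - 1 for i in idx])]

    def flat(self) -> np.ndarray:
        """Row-flattened (x1, y1, x2, y2, ...) coordinate vector."""
        return self.points.reshape(-1)

    def copy(self, **changes) -> "LandmarkConfiguration":
        out = replace(self, **changes) if changes else replace(self)
        out.points = np.array(out.points, copy=True)
        return out


# ---------------------------------------------------------------------------
# Landmark points files: integer count header, then one "x y" pair per line.
# ---------------------------------------------------------------------------

def read_points(
    path: str | Path,
    schema: PointSchema | None = None,
    flip_y: bool = False,
) -> LandmarkConfiguration:
    """Read a plain-text landmark points file.

    Format: first non-empty line is the point count, followed by that many
    whitespace-separated ``x y`` lines.  BOM and CRLF are tolerated.  If a
    *schema* is given the point count is validated against it.  With
    ``flip_y`` image-native y-down coordinates are negated into the y-up
    convention.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8-sig")
    lines = text.splitlines()
    nums: list[tuple[float, float]] = []
    declared: int | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tok = line.split()
        if declared is None:
            if len(tok) != 1:
                raise PointsParseError(
                    f"{path}:{lineno}: expected a point-count header, got {line!r}"
                )
            try:
                declared = int(tok[0])
            except ValueError as exc:
                raise PointsParseError(
                    f"{path}:{lineno}: non-integer point count {tok[0]!r}"
                ) from exc
            continue
        if len(tok) != 2:
            raise PointsParseError(
                f"{path}:{lineno}: expected 'x y', got {line!r}"
            )
        try:
            nums.append((float(tok[0]), float(tok[1])))
        except ValueError as exc:
            raise PointsParseError(
                f"{path}:{lineno}: non-numeric coordinate in {line!r}"
            ) from exc
    if declared is None:
        raise PointsParseError(f"{path}: missing point-count header")
    if len(nums) != declared:
        raise SchemaError(
            f"{path}: header declares {declared} points but file has {len(nums)}"
        )
    pts = np.asarray(nums, dtype=float)
    if flip_y:
        pts[:, 1] = -pts[:, 1]
    config = LandmarkConfiguration(subject_id=path.stem, points=pts)
    if schema is not None:
        config.validate_against(schema)
    return config


def write_points(config: LandmarkConfiguration, path: str | Path, decimals: int = 6) -> None:
    """Write a landmark configuration as a count-header points file."""
    if config.n_points == 0:  # pragma: no cover - constructor already refuses
        raise SchemaError("refusing to write an empty configuration")
    path = Path(path)
    fmt = f"{{:.{decimals}f}} {{:.{decimals}f}}"
    lines = [str(config.n_points)]
    lines += [fmt.format(x, y) for x, y in config.points]
    path.write_text("\n".join(lines) + "\n")


def read_points_dir(
    directory: str | Path,
    schema: PointSchema | None = None,
    pattern: str = "*.pts",
) -> list[LandmarkConfiguration]:
    """Read every points file in *directory*, sorted by filename."""
    files = sorted(Path(directory).glob(pattern))
    if not files:
        raise FileNotFoundError(f"no {pattern} files in {directory}")
    return [read_points(f, schema=schema) for f in files]


def write_points_dir(
    configs: Sequence[LandmarkConfiguration],
    directory: str | Path,
    decimals: int = 6,
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for c in configs:
        write_points(c, directory / f"{c.subject_id}.pts", decimals=decimals)


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

COHORT_COLUMNS = (
    "subject_id",
    "age",
    "sex",
    "height",
    "weight",
    "ethnicity_white",
    "osteo_area_lat_acetabulum",
    "osteo_area_sup_lat_head",
    "osteo_area_inf_med_head",
    "hoa_hospital",
    "thr_event",
    "thr_time",
)


@dataclass
class CohortTable:
    """Per-subject covariates, osteophyte areas and OA outcome columns.

    Wraps a pandas DataFrame with the mandatory :data:`COHORT_COLUMNS`
    (age in years, height cm, weight kg, sex in {M, F}, osteophyte areas
    in mm^2 at three sites, hospital-diagnosed-HOA flag, and time-to-THR
    with event indicator).  Extra columns are carried through untouched.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COHORT_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"cohort table missing mandatory column(s): {missing}")
        bad_sex = set(self.df["sex"].dropna().unique()) - {"M", "F"}
        if bad_sex:
            raise SchemaError(f"sex must be 'M' or 'F', got {sorted(bad_sex)}")
        sub = self.df.dropna(subset=list(COHORT_COLUMNS))
        if (sub["height"] <= 0).any() or (sub["weight"] <= 0).any():
            raise SchemaError("heights and weights must be positive")
        if (sub["thr_time"] < 0).any():
            raise SchemaError("thr_time must be >= 0")

    def __len__(self) -> int:
        return len(self.df)

    def complete_case(self, extra_columns: Sequence[str] = ()) -> "CohortTable":
        """Rows with no missing value in the mandatory (+extra) columns.

        The number excluded is logged, mirroring a study-flow account of
        available n -> complete-case n.
        """
        cols = list(COHORT_COLUMNS) + [c for c in extra_columns if c in self.df.columns]
        kept = self.df.dropna(subset=cols)
        n_excl = len(self.df) - len(kept)
        logger.info(
            "complete-case filter: %d of %d rows kept (%d excluded)",
            len(kept), len(self.df), n_excl,
        )
        return CohortTable(kept.reset_index(drop=True))


def read_cohort(path: str | Path) -> CohortTable:
    """Read a cohort CSV, validating mandatory columns."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {missing}")
    return CohortTable(df)


def write_cohort(table: CohortTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)
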