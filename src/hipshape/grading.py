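"""Radiographic hip-OA grading from osteophyte areas and joint-space width.

Osteophytes at three sites (lateral acetabulum, superolateral femoral
head, inferomedial femoral head) are graded 0-3 from their area in mm^2;
minimum joint-space width is height-adjusted and categorized into a
joint-space-narrowing (JSN) grade 0-3; the summed score (three osteophyte
grades + JSN grade, range 0-12) maps onto four overall rHOA grades, from
which the binary study outcomes (moderate rHOA = grade 2 only; rHOA
grade >= 3) are flagged.

The area and JSN cut-points and the sum-to-overall map are configuration
defaults: the upstream literature defines them outside this package, so
they are explicit, documented and overridable rather than hard-coded.
Boundary convention everywhere: a value equal to a cut-point takes the
lower grade.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .schema import OSTEOPHYTE_SITES

logger = logging.getLogger(__name__)

__all__ = [
    "GradingConfig",
    "RHOAGrading",
    "GradingError",
    "grade_osteophyte",
    "jsn_grade",
    "height_adjust_mjsw",
    "grade_rhoa",
    "grade_cohort",
]


class GradingError(ValueError):
    pass


@dataclass(frozen=True)
class GradingConfig:
    """Cut-points and the sum-to-overall map for rHOA grading.

    ``osteophyte_thresholds`` are strictly increasing mm^2 cut-points per
    site (grade = number of thresholds strictly exceeded);
    ``jsn_thresholds`` are strictly decreasing mm cut-points on
    height-adjusted mJSW (grade = number of thresholds the value falls
    strictly below); ``sum_to_overall`` maps every total score 0-12 to an
    overall grade 0-3.
    """

    osteophyte_thresholds: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {site: (2.5, 8.0, 20.0) for site in OSTEOPHYTE_SITES}
    )
    jsn_thresholds: tuple[float, float, float] = (2.6, 2.0, 1.4)
    sum_to_overall: tuple[int, ...] = (0, 1, 2, 2, 3, 3, 3, 3, 3, 3, 3, 3, 3)

    def __post_init__(self) -> None:
        for site, th in self.osteophyte_thresholds.items():
            if not all(a < b for a, b in zip(th, th[1:])):
                raise GradingError(f"osteophyte thresholds for {site} not strictly increasing")
        if not all(a > b for a, b in zip(self.jsn_thresholds, self.jsn_thresholds[1:])):
            raise GradingError("JSN thresholds must be strictly decreasing")
        if len(self.sum_to_overall) != 13:
            raise GradingError("sum_to_overall must map every total score 0-12")
        if any(g not in (0, 1, 2, 3) for g in self.sum_to_overall):
            raise GradingError("overall grades must be 0-3")
        if any(b < a for a, b in zip(self.sum_to_overall, self.sum_to_overall[1:])):
            raise GradingError("sum_to_overall must be monotone non-decreasing")

    def to_yaml(self, path) -> None:
        d = {
            "osteophyte_thresholds": {k: list(v) for k, v in self.osteophyte_thresholds.items()},
            "jsn_thresholds": list(self.jsn_thresholds),
            "sum_to_overall": list(self.sum_to_overall),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GradingConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            osteophyte_thresholds={k: tuple(v) for k, v in d["osteophyte_thresholds"].items()},
            jsn_thresholds=tuple(d["jsn_thresholds"]),
            sum_to_overall=tuple(d["sum_to_overall"]),
        )


@dataclass(frozen=True)
class RHOAGrading:
    """Site osteophyte grades, JSN grade, summed score and overall rHOA grade."""

    osteophyte_grades: dict[str, int]
    jsn_grade: int
    total_score: int
    overall_grade: int
    rhoa_grade2_only: bool
    rhoa_ge3: bool


def grade_osteophyte(area_mm2: float, site: str,
                     config: GradingConfig | None = None) -> int:
    """Osteophyte grade 0-3: number of area cut-points strictly exceeded."""
    config = config or GradingConfig()
    if area_mm2 < 0:
        raise GradingError(f"negative osteophyte area {area_mm2}")
    if site not in config.osteophyte_thresholds:
        raise GradingError(f"unknown osteophyte site {site!r}")
    return int(sum(area_mm2 > t for t in config.osteophyte_thresholds[site]))


def jsn_grade(adjusted_mjsw: float, config: GradingConfig | None = None) -> int:
    """JSN grade 0-3: number of mJSW cut-points the value falls strictly below."""
    config = config or GradingConfig()
    return int(sum(adjusted_mjsw < t for t in config.jsn_thresholds))


def height_adjust_mjsw(mjsw: pd.Series | np.ndarray,
                       height: pd.Series | np.ndarray) -> np.ndarray:
    """Height-adjusted mJSW: regression residual plus the cohort mean.

    Least-squares regression of mJSW on height; the adjusted value is the
    residual shifted back to the cohort mean mJSW, so it is uncorrelated
    with height but on the original mm scale.  If height has zero variance
    the adjustment is skipped with a warning and the raw values returned.
    """
    y = np.asarray(mjsw, float)
    x = np.asarray(height, float)
    if len(y) < 10:
        raise GradingError("height adjustment needs >= 10 subjects")
    if np.ptp(x) == 0 or np.var(x) == 0:
        logger.warning("zero height variance; mJSW height adjustment skipped")
        return y.copy()
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return resid + y.mean()


def grade_rhoa(osteophyte_grades: dict[str, int], jsn: int,
               config: GradingConfig | None = None) -> RHOAGrading:
    """Combine site grades + JSN into total score, overall grade and flags."""
    config = config or GradingConfig()
    for site, g in osteophyte_grades.items():
        if g not in (0, 1, 2, 3):
            raise GradingError(f"osteophyte grade for {site} must be 0-3, got {g}")
    if jsn not in (0, 1, 2, 3):
        raise GradingError(f"JSN grade must be 0-3, got {jsn}")
    total = int(sum(osteophyte_grades.values()) + jsn)
    if not 0 <= total <= 12:
        raise GradingError(f"total score {total} outside 0-12")
    overall = config.sum_to_overall[total]
    return RHOAGrading(
        osteophyte_grades=dict(osteophyte_grades),
        jsn_grade=int(jsn),
        total_score=total,
        overall_grade=int(overall),
        rhoa_grade2_only=overall == 2,
        rhoa_ge3=overall >= 3,
    )


def grade_cohort(measures: pd.DataFrame, cohort: pd.DataFrame,
                 config: GradingConfig | None = None) -> pd.DataFrame:
    """Grade a whole cohort from geometric measures + osteophyte areas.

    *measures* needs ``subject_id`` and ``mjsw``; *cohort* needs
    ``subject_id``, ``height`` and the three ``osteo_area_*`` columns.
    Returns one row per subject with site grades, JSN grade, total score,
    overall grade and the two binary rHOA flags.
    """
    config = config or GradingConfig()
    df = measures[["subject_id", "mjsw"]].merge(
        cohort[["subject_id", "height",
                "osteo_area_lat_acetabulum", "osteo_area_sup_lat_head",
                "osteo_area_inf_med_head"]],
        on="subject_id", how="inner",
    )
    adj = height_adjust_mjsw(df["mjsw"], df["height"])
    rows = []
    for i, row in df.iterrows():
        og = {
            "lat_acetabulum": grade_osteophyte(row["osteo_area_lat_acetabulum"], "lat_acetabulum", config),
            "sup_lat_head": grade_osteophyte(row["osteo_area_sup_lat_head"], "sup_lat_head", config),
            "inf_med_head": grade_osteophyte(row["osteo_area_inf_med_head"], "inf_med_head", config),
        }
        g = grade_rhoa(og, jsn_grade(adj[i], config), config)
        rows.append({
            "subject_id": row["subject_id"],
            "osteophyte_grade_lat_acetabulum": og["lat_acetabulum"],
            "osteophyte_grade_sup_lat_head": og["sup_lat_head"],
            "osteophyte_grade_inf_med_head": og["inf_med_head"],
            "adjusted_mjsw": adj[i],
            "jsn_grade": g.jsn_grade,
            "total_score": g.total_score,
            "overall_grade": g.overall_grade,
            "rhoa_grade2_only": int(g.rhoa_grade2_only),
            "rhoa_ge3": int(g.rhoa_ge3),
        })
    return pd.DataFrame(rows)
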