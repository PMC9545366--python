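"""Automated geometric morphometrics from one landmark configuration.

Implements the standard AP-view hip measurements used alongside a
statistical shape model:

* head circle — least-squares circle through the femoral-head points,
* AA (alpha angle) — cam-morphology measure at the superior head-neck
  junction,
* LCEA (lateral centre-edge angle) — acetabular coverage of the head,
* NSA (neck-shaft angle) — obtuse angle between neck and shaft axes,
* NNW (narrowest neck width) — minimum width of the femoral neck, mm,
* mJSW (minimum joint-space width) — minimum distance between the
  superior head contour and the acetabular contour, mm.

All angle measures are invariant under rigid motion of the configuration;
mm measures scale linearly under uniform scaling.  Measures that are
geometrically undefined on a given outline (e.g. the contour never leaves
the head circle) are returned as NaN sentinels with a diagnostic message,
never as exceptions, so cohort-level runs degrade gracefully.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .schema import LandmarkConfiguration, PointSchema, DEFAULT_SCHEMA

logger = logging.getLogger(__name__)

__all__ = [
    "HeadCircle",
    "GeometricMeasures",
    "GeometryError",
    "fit_head_circle",
    "neck_axis",
    "narrowest_neck_width",
    "alpha_angle",
    "lcea",
    "neck_shaft_angle",
    "mjsw",
    "measure",
    "measure_cohort",
    "polyline_min_distance",
]


class GeometryError(ValueError):
    """A geometric construction is degenerate (collinear points, crossing borders...)."""


@dataclass(frozen=True)
class HeadCircle:
    """Least-squares circle through the femoral-head landmark points."""

    center: tuple[float, float]
    radius: float
    rms_residual: float


@dataclass
class GeometricMeasures:
    """Per-subject morphometrics; NaN marks an undefined measure."""

    subject_id: str
    alpha_angle: float
    lcea: float
    nsa: float
    nnw: float
    mjsw: float
    head_fit_residual: float
    diagnostics: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Low-level polyline machinery
# ---------------------------------------------------------------------------

def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distances from points p (n,2) to each segment (a_i, b_i) (m,2): (n, m)."""
    ab = b - a  # (m, 2)
    ap = p[:, None, :] - a[None, :, :]  # (n, m, 2)
    denom = np.einsum("md,md->m", ab, ab)
    denom = np.where(denom > 0, denom, 1.0)
    t = np.clip(np.einsum("nmd,md->nm", ap, ab) / denom, 0.0, 1.0)
    foot = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    return np.linalg.norm(p[:, None, :] - foot, axis=2), foot, t


def polyline_min_distance(P: np.ndarray, Q: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Minimum distance between two polylines (vertex-to-segment, both ways).

    Returns ``(distance, point_on_P, point_on_Q)`` for the minimising pair.
    Polylines are taken as the open chains through the given vertices; for
    single-vertex inputs the chain degenerates to the point itself.
    """
    P = np.atleast_2d(np.asarray(P, float))
    Q = np.atleast_2d(np.asarray(Q, float))

    best = (np.inf, P[0], Q[0])
    if len(Q) >= 2:
        d, foot, _ = _point_segment_distance(P, Q[:-1], Q[1:])
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if d[i, j] < best[0]:
            best = (float(d[i, j]), P[i], foot[i, j])
    if len(P) >= 2:
        d, foot, _ = _point_segment_distance(Q, P[:-1], P[1:])
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if d[i, j] < best[0]:
            best = (float(d[i, j]), foot[i, j], Q[i])
    if not np.isfinite(best[0]):  # both single points
        dist = float(np.linalg.norm(P[0] - Q[0]))
        best = (dist, P[0], Q[0])
    return best


def _segments(P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return P[:-1], P[1:]


def _polylines_intersect(P: np.ndarray, Q: np.ndarray) -> bool:
    """True if any segment of P properly intersects any segment of Q."""
    P, Q = np.atleast_2d(P), np.atleast_2d(Q)
    if len(P) < 2 or len(Q) < 2:
        return False
    a, b = _segments(P)
    c, d = _segments(Q)

    def cross(u, v):
        return u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]

    r = (b - a)[:, None, :]
    s = (d - c)[None, :, :]
    qp = c[None, :, :] - a[:, None, :]
    denom = cross(r, s)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = cross(qp, s) / denom
        u = cross(qp, r) / denom
    hit = (np.abs(denom) > 1e-12) & (t > 0) & (t < 1) & (u > 0) & (u < 1)
    return bool(np.any(hit))


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Unsigned angle between two vectors, degrees in [0, 180]."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# Head circle
# ---------------------------------------------------------------------------

def fit_head_circle(
    config: LandmarkConfiguration,
    schema: PointSchema = DEFAULT_SCHEMA,
    refine: bool = True,
) -> HeadCircle:
    """Least-squares circle through the femoral-head points (default 15-28).

    An algebraic (Kasa) fit provides the initial estimate; by default it is
    refined by minimising the sum of squared radial residuals, the geometric
    least-squares criterion.
    """
    pts = config.get(schema.head_circle_idx)
    if len(pts) < 3:
        raise GeometryError("need >= 3 head points to fit a circle")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x * x + y * y
    # Collinearity check: area-based rank test on the point spread.
    _, sv, _ = np.linalg.svd(pts - pts.mean(axis=0))
    if sv[-1] < 1e-9 * max(sv[0], 1.0):
        raise GeometryError("head points are (near-)collinear; circle fit is degenerate")
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r = float(np.sqrt(c + cx * cx + cy * cy))

    if refine:
        def resid(p):
            return np.hypot(x - p[0], y - p[1]) - p[2]

        out = least_squares(resid, x0=[cx, cy, r], method="lm")
        cx, cy, r = out.x
    rms = float(np.sqrt(np.mean((np.hypot(x - cx, y - cy) - r) ** 2)))
    if r <= 0:
        raise GeometryError("degenerate circle fit (non-positive radius)")
    return HeadCircle(center=(float(cx), float(cy)), radius=float(r), rms_residual=rms)


# ---------------------------------------------------------------------------
# Neck axis and narrowest neck width
# ---------------------------------------------------------------------------

def narrowest_neck_width(
    config: LandmarkConfiguration,
    schema: PointSchema = DEFAULT_SCHEMA,
) -> tuple[float, np.ndarray]:
    """Minimum width of the femoral neck and the midpoint of the minimising span.

    Width is the minimum point-to-segment distance between the superior and
    inferior neck border polylines.  Raises :class:`GeometryError` if the
    borders cross (a negative width has no meaning).
    """
    sup = config.get(schema.superior_neck_idx)
    inf = config.get(schema.inferior_neck_idx)
    if _polylines_intersect(sup, inf):
        raise GeometryError("superior and inferior neck borders cross")
    d, p, q = polyline_min_distance(sup, inf)
    if d <= 0:
        raise GeometryError("neck borders touch; width is not positive")
    return float(d), (p + q) / 2.0


def neck_axis(
    config: LandmarkConfiguration,
    schema: PointSchema = DEFAULT_SCHEMA,
    circle: HeadCircle | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Femoral neck axis as (head centre, unit direction toward the neck).

    The axis runs from the head-circle centre through the midpoint of the
    narrowest-neck span — the operational "centre of the neck".
    """
    circle = circle or fit_head_circle(config, schema)
    _, mid = narrowest_neck_width(config, schema)
    c = np.asarray(circle.center)
    d = mid - c
    n = np.linalg.norm(d)
    if n < 1e-12:
        raise GeometryError("neck midpoint coincides with head centre")
    return c, d / n


# ---------------------------------------------------------------------------
# Alpha angle
# ---------------------------------------------------------------------------

# Departure tolerance: at least MIN_DEPARTURE_TOL of the radius, scaled up
# with the circle-fit residual so landmark noise alone rarely triggers a
# spurious junction (three residual SDs; two is not enough when the
# superior walk crosses several on-circle points).
MIN_DEPARTURE_TOL = 0.02
DEPARTURE_RMS_MULT = 3.0


def _departure_tolerance(circle: HeadCircle, delta: float | None) -> float:
    if delta is not None:
        return delta
    return max(MIN_DEPARTURE_TOL, DEPARTURE_RMS_MULT * circle.rms_residual / circle.radius)


def alpha_angle(
    config: LandmarkConfiguration,
    schema: PointSchema = DEFAULT_SCHEMA,
    delta: float | None = None,
    circle: HeadCircle | None = None,
) -> tuple[float, str]:
    """Alpha angle (degrees) at the superior femoral head-neck junction.

    Walks the superior outline from the head apex toward the neck (superior
    head points, head-neck junction, superior neck border, then greater
    trochanter); the junction is the first outline point whose distance from
    the head-circle centre exceeds ``radius * (1 + delta)``.  The alpha angle
    is the angle at the circle centre between the neck axis (pointing down
    the neck) and the centre-to-junction ray.  Returns ``(nan, reason)``
    when no outline point ever leaves the circle.
    """
    circle = circle or fit_head_circle(config, schema)
    c, axis_dir = neck_axis(config, schema, circle=circle)
    tol = _departure_tolerance(circle, delta)
    threshold = circle.radius * (1.0 + tol)

    # Outline order of the walk: superior head from the apex, junction
    # points, superior neck, greater trochanter.
    walk = list(schema.superior_head_idx) + list(schema.head_neck_junction_idx) \
        + list(schema.superior_neck_idx) + list(schema.greater_troch_idx)
    seen = set()
    walk = [i for i in walk if not (i in seen or seen.add(i))]
    pts = config.get(walk)
    # Start at the apex: the walk point most nearly opposite the neck axis
    # (a frame-independent notion of "top of the head").
    rel = pts - c
    rel = rel / np.maximum(np.linalg.norm(rel, axis=1, keepdims=True), 1e-12)
    start = int(np.argmin(rel @ axis_dir))
    for p in pts[start:]:
        if np.linalg.norm(p - c) > threshold:
            return _angle_between(p - c, axis_dir), ""
    return float("nan"), (
        f"no outline point leaves the head circle (threshold {threshold:.3f} mm)"
    )


# ---------------------------------------------------------------------------
# LCEA
# ---------------------------------------------------------------------------

def lcea(
    config: LandmarkConfiguration,
    schema: PointSchema = DEFAULT_SCHEMA,
    circle: HeadCircle | None = None,
) -> tuple[float, str]:
    """Lateral centre-edge angle (degrees), lateral-positive.

    Angle between the vertical through the femoral-head centre and the ray
    from the centre to the lateral acetabular edge (default point 78).
    Positive when the edge lies lateral (x-negative side for a left hip) of
    the vertical; negative values (dysplasia) are reported, not clipped.
    Returns ``(nan, reason)`` if the edge point lies below the head centre.
    """
    circle = circle or fit_head_circle(config, schema)
    c = np.asarray(circle.center)
    edge = config.get(schema.lateral_acetabular_edge_idx)[0]
    ray = edge - c
    if ray[1] <= 0:
        return float("nan"), "lateral acetabular edge lies below the head centre"
    ang = _angle_between(ray, np.array([0.0, 1.0]))
    sign = 1.0 if ray[0] < 0 else -1.0  # lateral = medial-negative x
    return sign * ang, ""


# ---------------------------------------------------------------------------
# Neck-shaft angle
# ---------------------------------------------------------------------------

def _shaft_axis(config: LandmarkConfiguration, schema: PointSchema) -> np.ndarray:
    """Unit direction of the femoral shaft axis.

    Each medial shaft point is paired with the lateral shaft point nearest
    in y; the axis is the principal direction of the midpoints.
    """
    med = config.get(schema.shaft_medial_idx)
    lat = config.get(schema.shaft_lateral_idx)
    pairs = np.abs(med[:, 1][:, None] - lat[:, 1][None, :])
    mids = (med + lat[np.argmin(pairs, axis=1)]) / 2.0
    mids = np.unique(mids, axis=0)
    if len(mids) < 2:
        raise GeometryError("need >= 2 distinct shaft midpoints for a shaft axis")
    centred = mids - mids.mean(axis=0)
    _, _, vt = np.linalg.svd(centred)
    return vt[0]


def neck_shaft_angle(
    config: LandmarkConfiguration,
    schema: PointSchema = DEFAULT_SCHEMA,
    circle: HeadCircle | None = None,
) -> float:
    """Obtuse anatomical angle between neck axis and shaft axis, degrees."""
    circle = circle or fit_head_circle(config, schema)
    _, neck_dir = neck_axis(config, schema, circle=circle)
    shaft_dir = _shaft_axis(config, schema)
    ang = _angle_between(neck_dir, shaft_dir)
    return max(ang, 180.0 - ang)


# ---------------------------------------------------------------------------
# Minimum joint-space width
# ---------------------------------------------------------------------------

def mjsw(
    config: LandmarkConfiguration,
    schema: PointSchema = DEFAULT_SCHEMA,
) -> float:
    """Minimum joint-space width (mm): superior head vs acetabular polyline.

    Minimum point-to-segment distance between the superior femoral head
    polyline (default points 22-31) and the acetabular polyline (default
    78-84).  If the polylines intersect the joint space is reported as 0
    with a warning.
    """
    head = config.get(schema.superior_head_idx)
    acet = config.get(schema.acetabulum_idx)
    if _polylines_intersect(head, acet):
        warnings.warn(
            f"subject {config.subject_id}: head and acetabular outlines intersect; mJSW = 0",
            stacklevel=2,
        )
        return 0.0
    d, _, _ = polyline_min_distance(head, acet)
    return float(d)


# ---------------------------------------------------------------------------
# Cohort-level driver
# ---------------------------------------------------------------------------

def measure(
    config: LandmarkConfiguration,
    schema: PointSchema = DEFAULT_SCHEMA,
    delta: float | None = None,
) -> GeometricMeasures:
    """All geometric morphometrics for one configuration."""
    config.validate_against(schema)
    circle = fit_head_circle(config, schema)
    diagnostics: list[str] = []
    aa, aa_diag = alpha_angle(config, schema, delta=delta, circle=circle)
    if aa_diag:
        diagnostics.append(f"AA: {aa_diag}")
    ce, ce_diag = lcea(config, schema, circle=circle)
    if ce_diag:
        diagnostics.append(f"LCEA: {ce_diag}")
    nnw, _ = narrowest_neck_width(config, schema)
    return GeometricMeasures(
        subject_id=config.subject_id,
        alpha_angle=aa,
        lcea=ce,
        nsa=neck_shaft_angle(config, schema, circle=circle),
        nnw=nnw,
        mjsw=mjsw(config, schema),
        head_fit_residual=circle.rms_residual,
        diagnostics=tuple(diagnostics),
    )


def measure_cohort(
    configs,
    schema: PointSchema = DEFAULT_SCHEMA,
    delta: float | None = None,
) -> pd.DataFrame:
    """One row of AA / LCEA / NSA / NNW / mJSW per subject."""
    rows = []
    for cfg in configs:
        m = measure(cfg, schema, delta=delta)
        rows.append({
            "subject_id": m.subject_id,
            "alpha_angle": m.alpha_angle,
            "lcea": m.lcea,
            "nsa": m.nsa,
            "nnw": m.nnw,
            "mjsw": m.mjsw,
            "head_fit_residual": m.head_fit_residual,
        })
    return pd.DataFrame(rows)
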