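"""Synthetic left-hip cohort generator.

Real hip-shape cohorts of this kind are access-controlled, so every
downstream stage (shape model, morphometrics, grading, association
models, composites) is exercised on synthetic data with the same
statistical structure:

* a parametric 85-point template outline of the left proximal femur and
  superior acetabulum, built from geometric primitives (head circle,
  neck band, shaft lines, trochanter lobes, acetabular arc);
* mutually orthogonal unit-norm deformation modes with Gaussian scores,
  including a *cam_bump* mode (radial outward bump at the superior
  head-neck junction, which raises the alpha angle), an
  *acetabular_coverage* mode (rotation of the acetabular arc about the
  head centre, which moves the LCEA), a *neck_width* mode and a
  *troch_size* mode;
* isotropic Gaussian landmark variation (plus extra variability of the
  lateral acetabular edge, the least reproducible landmark);
* covariates drawn from documented margins (age ~ N(63.7, 7.6) years,
  sex ~ 47.8% male, sex-specific height/weight, 96.8% white ethnicity);
* logistic outcome models for a latent rHOA severity class (none /
  moderate / severe) and hospital-diagnosed HOA, and an exponential
  proportional-hazards model for time to total hip replacement with
  administrative censoring — with effects per 1 SD of mode score and,
  for the severe-type outcomes, per 1 SD of the realized outline's
  alpha angle and LCEA (the morphology the measurement stage reads);
* osteophyte areas drawn from gamma distributions conditional on the
  latent severity class, and a joint-space reduction applied to the
  acetabular arc of affected subjects, so that the grading stage can
  re-derive radiographic OA from the generated data.

Everything is driven by one seeded generator: identical seeds give
byte-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import LandmarkConfiguration, DEFAULT_SCHEMA, CohortTable

__all__ = [
    "TemplateGeometry",
    "GenerativeShapeSpec",
    "CovariateSpec",
    "OutcomeSpec",
    "OutcomeModelSpec",
    "make_template",
    "sample_cohort",
    "MODE_NAMES",
]

MODE_NAMES = ("cam_bump", "acetabular_coverage", "neck_width", "troch_size")

OUTCOME_NAMES = ("moderate", "severe", "hospital", "thr")


# ---------------------------------------------------------------------------
# Template geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TemplateGeometry:
    """Lengths in mm, angles in degrees, of the parametric template."""

    r_head: float = 25.0            # femoral head radius
    neck_half_width: float = 15.8   # half of the narrowest neck width (NNW 31.6)
    neck_length: float = 40.0       # head centre -> neck/shaft junction
    nsa_deg: float = 135.0          # neck-shaft angle
    shaft_half_width: float = 15.0
    shaft_bottom_y: float = -95.0
    joint_space: float = 4.0        # radial head-acetabulum gap (mJSW scale)
    lcea_deg: float = 36.0          # lateral acetabular edge above vertical
    acetab_medial_deg: float = 60.0  # polar angle of the medial arc end

    def validate(self) -> None:
        if self.r_head <= 0:
            raise ValueError("r_head must be positive")
        if not 0 < 2 * self.neck_half_width < 2 * self.r_head:
            raise ValueError("neck width must be positive and below the head diameter")
        if self.neck_length <= self.r_head * 0.5:
            raise ValueError("degenerate geometry: neck too short")
        if self.joint_space <= 0:
            raise ValueError("joint_space must be positive")


# Waist profile of the superior head-neck junction (points 29-34): polar
# angles relative to the head-ward neck-axis angle, and radii as fractions
# of the head radius.  The waist dips below the circle toward the apex and
# exits it on the neck side, so a growing cam bump moves the
# circle-departure point progressively apex-ward (alpha angle up).
_JUNCTION_REL_DEG = np.array([67.0, 83.0, 99.0, 113.0, 125.0, 135.0])
_JUNCTION_R_FRAC = np.array([0.996, 0.963, 0.930, 0.959, 1.015, 1.048])

# Greater-trochanter lobe at default scale, absolute mm for r_head=25.
_GT_LOBE = np.array([
    (-40.0, -11.0), (-42.0, -6.0), (-44.5, -1.5), (-47.5, 1.5),
    (-50.5, 2.5), (-52.5, 1.5), (-53.5, -2.0), (-53.5, -6.0),
    (-52.5, -10.0), (-51.0, -14.0), (-49.5, -18.0), (-48.0, -21.5),
    (-46.5, -24.5), (-45.3, -27.0), (-44.2, -28.7), (-43.4, -29.8),
])


def make_template(geometry: TemplateGeometry | None = None) -> LandmarkConfiguration:
    """Build the 85-point left-hip template outline.

    Head centre at the origin, x medial-positive, y superior-positive.
    Femoral head points (15-28) lie exactly on the head circle; the
    acetabular arc (78-85) is concentric at ``r_head + joint_space``.
    """
    g = geometry or TemplateGeometry()
    g.validate()
    s = g.r_head / 25.0  # global scale for the hand-tuned lobes
    phi = np.radians(g.nsa_deg - 90.0)  # head-ward neck-axis angle
    u_head = np.array([np.cos(phi), np.sin(phi)])
    n_sup = np.array([-np.sin(phi), np.cos(phi)])
    n_inf = -n_sup
    w = g.neck_half_width

    def sup_border(t):
        return -t * u_head + w * n_sup

    def inf_border(t):
        return -t * u_head + w * n_inf

    x_shaft = -g.neck_length * np.cos(phi)
    x_med = x_shaft + g.shaft_half_width
    x_lat = x_shaft - g.shaft_half_width

    t_cross = np.sqrt(g.r_head**2 - w**2)  # neck border meets head circle
    theta_inf = np.degrees(np.arctan2(*inf_border(t_cross)[::-1]))
    arc_start = theta_inf + 2.8
    arc_end = np.degrees(phi) + 55.0

    pts: list[np.ndarray] = []

    # 1-6 medial shaft border, distal -> proximal
    for y in np.linspace(g.shaft_bottom_y, -55.0 * s, 6):
        pts.append(np.array([x_med, y]))
    # 7-10 lesser trochanter bump on the medial border
    for dx, y in zip((3.0, 6.0, 6.0, 3.0), (-51.0, -47.0, -43.0, -39.0)):
        pts.append(np.array([x_med + dx * s, y * s]))
    # 11-14 inferior neck (calcar), shaft -> head
    t_i1 = (w * np.sin(phi) - x_med) / np.cos(phi)
    for t in np.linspace(t_i1, 1.035 * t_cross, 4):
        pts.append(inf_border(t))
    # 15-28 femoral head circle
    for th in np.radians(np.linspace(arc_start, arc_end, 14)):
        pts.append(g.r_head * np.array([np.cos(th), np.sin(th)]))
    # 29-34 superior head-neck junction waist
    for rel, frac in zip(_JUNCTION_REL_DEG, _JUNCTION_R_FRAC):
        th = np.radians(np.degrees(phi) + rel)
        pts.append(frac * g.r_head * np.array([np.cos(th), np.sin(th)]))
    # 35-42 superior neck border, head -> trochanter
    for t in np.linspace(1.058 * t_cross, 0.95 * g.neck_length, 8):
        pts.append(sup_border(t))
    # 43-58 greater trochanter lobe
    for p in _GT_LOBE:
        pts.append(p * s)
    # 59-70 lateral shaft border, proximal -> distal
    for y in np.linspace(-33.0 * s, g.shaft_bottom_y, 12):
        pts.append(np.array([x_lat, y]))
    # 71-77 distal shaft bottom, lateral -> medial
    for x in np.linspace(x_lat + 3.8 * s, x_med - 3.8 * s, 7):
        pts.append(np.array([x, g.shaft_bottom_y]))
    # 78-85 acetabular arc, lateral edge -> medial
    r_ac = g.r_head + g.joint_space
    for th in np.radians(np.linspace(90.0 + g.lcea_deg, g.acetab_medial_deg, 8)):
        pts.append(r_ac * np.array([np.cos(th), np.sin(th)]))

    return LandmarkConfiguration(subject_id="template", points=np.asarray(pts))


# ---------------------------------------------------------------------------
# Deformation modes
# ---------------------------------------------------------------------------

def _gram_schmidt(fields: np.ndarray) -> np.ndarray:
    """Orthonormalize (K, 2p) row vectors in order; earlier rows stay pure."""
    out = fields.astype(float).copy()
    for i in range(out.shape[0]):
        for j in range(i):
            out[i] -= np.dot(out[i], out[j]) * out[j]
        nrm = np.linalg.norm(out[i])
        if nrm < 1e-10:
            raise ValueError(f"deformation field {i} is linearly dependent")
        out[i] /= nrm
    return out


def _default_mode_fields(template: LandmarkConfiguration,
                         geometry: TemplateGeometry) -> np.ndarray:
    """Hand-designed deformation fields, then Gram-Schmidt orthonormalized."""
    p = template.points
    n = template.n_points
    phi_deg = geometry.nsa_deg - 90.0
    theta = np.degrees(np.arctan2(p[:, 1], p[:, 0]))  # polar angle about head centre
    radial = p / np.maximum(np.linalg.norm(p, axis=1, keepdims=True), 1e-9)

    fields = np.zeros((4, n, 2))

    # cam_bump: radial outward Gaussian bump centred on the superior
    # head-neck junction (polar angle ~ neck axis + 110 deg).
    centre = phi_deg + 110.0
    for i in range(26, 36):  # 0-based: points 27-36
        wgt = np.exp(-0.5 * ((theta[i] - centre) / 22.0) ** 2)
        fields[0, i] = wgt * radial[i]

    # acetabular_coverage: tangential rotation of the acetabular arc about
    # the head centre, largest at the lateral edge (point 78).
    acet = np.arange(77, 85)  # 0-based points 78-85
    tang = np.column_stack([-np.sin(np.radians(theta[acet])),
                            np.cos(np.radians(theta[acet]))])
    wgt = np.linspace(1.0, 0.0, len(acet))
    fields[1, acet] = wgt[:, None] * tang

    # neck_width: superior neck border displaced along its outward normal.
    phi = np.radians(phi_deg)
    n_sup = np.array([-np.sin(phi), np.cos(phi)])
    neck = np.arange(34, 42)  # 0-based points 35-42
    wgt = np.array([0.5, 0.8, 1.0, 1.0, 1.0, 1.0, 0.8, 0.5])
    fields[2, neck] = wgt[:, None] * n_sup

    # troch_size: greater and lesser trochanter lobes inflated radially
    # from their own centroids.
    for block, amp in ((np.arange(42, 58), 1.0), (np.arange(6, 10), 0.7)):
        ctr = p[block].mean(axis=0)
        d = p[block] - ctr
        d = d / np.maximum(np.linalg.norm(d, axis=1, keepdims=True), 1e-9)
        fields[3, block] = amp * d

    # Project out the similarity-group directions (translations, rotation,
    # scaling about the template centroid) so the fields live in the shape
    # tangent space: Procrustes alignment then leaves them intact to first
    # order and a PCA of aligned cohorts can recover them cleanly.
    ctr = p - p.mean(axis=0)
    sim_dirs = np.stack([
        np.tile([1.0, 0.0], n),                     # translate x
        np.tile([0.0, 1.0], n),                     # translate y
        np.column_stack([-ctr[:, 1], ctr[:, 0]]).reshape(-1),  # rotation
        ctr.reshape(-1),                            # scaling
    ])
    sim_dirs = _gram_schmidt(sim_dirs)
    flat = fields.reshape(4, -1)
    flat = flat - (flat @ sim_dirs.T) @ sim_dirs
    return _gram_schmidt(flat).reshape(4, n, 2)




@dataclass
class GenerativeShapeSpec:
    """Template + orthonormal deformation modes + score model + landmark noise.

    Scores are Gaussian with per-mode SDs and an optional correlation
    matrix (``None`` = independent).
    """

    template: LandmarkConfiguration
    modes: np.ndarray                 # (K, p, 2), unit-norm, mutually orthogonal
    score_sd: np.ndarray              # (K,) SDs of the Gaussian mode scores, mm units
    mode_names: tuple[str, ...]
    point_noise_sd: float = 0.35     # isotropic per-landmark noise, mm
    # Extra isotropic variability of the lateral acetabular edge point: the
    # edge is the least reproducible landmark (sourcil definition, os
    # acetabuli), so its position varies well beyond the global coverage
    # mode — which is also why a directly measured LCEA carries information
    # no single global mode score does.
    edge_noise_sd: float = 0.9
    score_corr: np.ndarray | None = None  # (K, K) score correlation matrix

    def __post_init__(self) -> None:
        flat = np.asarray(self.modes, float).reshape(len(self.mode_names), -1)
        G = flat @ flat.T
        if not np.allclose(G, np.eye(len(flat)), atol=1e-8):
            raise ValueError("deformation fields must be orthonormal (off-diagonals < 1e-8)")
        if np.any(np.asarray(self.score_sd) <= 0):
            raise ValueError("score SDs must be positive")
        if self.point_noise_sd < 0:
            raise ValueError("point_noise_sd must be >= 0")
        if self.score_corr is not None:
            C = np.asarray(self.score_corr, float)
            if C.shape != (self.n_modes, self.n_modes):
                raise ValueError("score_corr must be K x K")
            if not np.allclose(C, C.T, atol=1e-10) or not np.allclose(np.diag(C), 1.0):
                raise ValueError("score_corr must be symmetric with unit diagonal")
            try:
                self._chol = np.linalg.cholesky(C)
            except np.linalg.LinAlgError as exc:
                raise ValueError("score_corr must be positive definite") from exc
        else:
            self._chol = None

    @property
    def n_modes(self) -> int:
        return len(self.mode_names)

    def draw_landmark_noise(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """(n, p, 2) landmark perturbations: isotropic base + extra edge term."""
        noise = rng.normal(0.0, self.point_noise_sd,
                           size=(n,) + self.template.points.shape)
        if self.edge_noise_sd > 0:
            e0 = DEFAULT_SCHEMA.lateral_acetabular_edge_idx - 1
            noise[:, e0, :] += rng.normal(0.0, self.edge_noise_sd, size=(n, 2))
        return noise

    def sample_scores(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Raw mode scores (n, K): marginal SDs ``score_sd``, correlation
        ``score_corr`` (independent when None)."""
        f = rng.standard_normal((n, self.n_modes))
        if self._chol is not None:
            f = f @ self._chol.T
        return f * np.asarray(self.score_sd)

    @classmethod
    def default(cls, geometry: TemplateGeometry | None = None,
                score_sd=(3.0, 2.5, 2.0, 1.5),
                point_noise_sd: float = 0.35,
                edge_noise_sd: float = 0.9,
                score_corr: np.ndarray | None = None,
                ) -> "GenerativeShapeSpec":
        geometry = geometry or TemplateGeometry()
        template = make_template(geometry)
        return cls(
            template=template,
            modes=_default_mode_fields(template, geometry),
            score_sd=np.asarray(score_sd, float),
            mode_names=MODE_NAMES,
            point_noise_sd=point_noise_sd,
            edge_noise_sd=edge_noise_sd,
            score_corr=score_corr,
        )


# ---------------------------------------------------------------------------
# Covariates and outcomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateSpec:
    """Marginal covariate distributions (documented defaults, not targets)."""

    age_mean: float = 63.7
    age_sd: float = 7.6
    p_male: float = 0.478
    height_mean_m: float = 177.2
    height_sd_m: float = 6.6
    height_mean_f: float = 163.6
    height_sd_f: float = 6.4
    weight_mean_m: float = 83.2
    weight_sd_m: float = 13.4
    weight_mean_f: float = 68.2
    weight_sd_f: float = 12.9
    p_white: float = 0.968


@dataclass
class OutcomeSpec:
    """One binary outcome: intercept, per-SD mode effects, geometry effects.

    ``gamma`` holds direct per-SD effects of latent mode scores;
    ``gamma_aa``/``gamma_lcea`` act per SD of the *morphology* — the alpha
    angle and lateral centre-edge angle of the subject's noiseless anatomy.
    Routing cam/coverage effects through the measured geometry (rather than
    the latent score) is what makes angle adjustment attenuate the
    corresponding shape-mode associations downstream, the way it does when
    the angle is the disease-relevant feature.
    """

    intercept: float
    gamma: dict[str, float] = field(default_factory=dict)   # per-SD log odds (log hazard)
    gamma_aa: float = 0.0       # per SD of true alpha angle
    gamma_lcea: float = 0.0     # per SD of true LCEA
    beta_age: float = 0.0       # per year, centred at the cohort mean age
    beta_male: float = 0.0
    beta_weight: float = 0.0    # per kg, centred


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _batch_point_segment(V: np.ndarray, A: np.ndarray, B: np.ndarray):
    """Batched vertex-to-segment distances: V (n,a,2) vs segments A->B (n,b,2)."""
    ab = B - A                                    # (n, b, 2)
    ap = V[:, :, None, :] - A[:, None, :, :]      # (n, a, b, 2)
    denom = np.einsum("nbd,nbd->nb", ab, ab)
    denom = np.where(denom > 0, denom, 1.0)
    t = np.clip(np.einsum("nabd,nbd->nab", ap, ab) / denom[:, None, :], 0.0, 1.0)
    foot = A[:, None, :, :] + t[..., None] * ab[:, None, :, :]
    dist = np.linalg.norm(V[:, :, None, :] - foot, axis=3)
    return dist, foot


def anatomy_angles(shape_spec: GenerativeShapeSpec, points: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Alpha angle and LCEA of realized outlines, vectorised over subjects.

    *points* is (n, 85, 2) — the subjects' outlines including any local
    landmark variation.  This replicates the per-subject measurement in
    :mod:`hipshape.geometry` (algebraic head-circle fit, narrowest-neck
    midpoint for the neck axis, apex-to-neck departure walk) in batched
    numpy, so outcome models can be driven by the same morphology the
    measurement stage reads, at cohort scale.
    """
    sch = DEFAULT_SCHEMA
    pts = np.asarray(points, float)
    n = pts.shape[0]

    # head circle: Kasa fit via per-subject 3x3 normal equations
    H = pts[:, sch.to0(sch.head_circle_idx), :]
    x, y = H[..., 0], H[..., 1]
    Amat = np.stack([2 * x, 2 * y, np.ones_like(x)], axis=2)   # (n, 14, 3)
    b = x * x + y * y
    AtA = np.einsum("nij,nik->njk", Amat, Amat)
    Atb = np.einsum("nij,ni->nj", Amat, b)
    sol = np.linalg.solve(AtA, Atb[..., None])[..., 0]
    c = sol[:, :2]
    r = np.sqrt(sol[:, 2] + np.einsum("ni,ni->n", c, c))
    d_head = np.linalg.norm(H - c[:, None, :], axis=2)
    rms = np.sqrt(np.mean((d_head - r[:, None]) ** 2, axis=1))

    # neck axis through the narrowest-neck midpoint
    sup = pts[:, sch.to0(sch.superior_neck_idx), :]
    inf = pts[:, sch.to0(sch.inferior_neck_idx), :]
    d1, f1 = _batch_point_segment(sup, inf[:, :-1], inf[:, 1:])
    d2, f2 = _batch_point_segment(inf, sup[:, :-1], sup[:, 1:])
    m1 = d1.reshape(n, -1)
    m2 = d2.reshape(n, -1)
    i1 = np.argmin(m1, axis=1)
    i2 = np.argmin(m2, axis=1)
    use1 = m1[np.arange(n), i1] <= m2[np.arange(n), i2]
    a1, b1 = np.unravel_index(i1, d1.shape[1:])
    a2, b2 = np.unravel_index(i2, d2.shape[1:])
    mid1 = (sup[np.arange(n), a1] + f1[np.arange(n), a1, b1]) / 2.0
    mid2 = (inf[np.arange(n), a2] + f2[np.arange(n), a2, b2]) / 2.0
    mid = np.where(use1[:, None], mid1, mid2)
    axis = mid - c
    axis = axis / np.maximum(np.linalg.norm(axis, axis=1, keepdims=True), 1e-12)

    # departure walk from the apex (most axis-opposite walk point)
    walk = list(sch.superior_head_idx) + list(sch.head_neck_junction_idx) \
        + list(sch.superior_neck_idx) + list(sch.greater_troch_idx)
    seen: set[int] = set()
    walk = [i for i in walk if not (i in seen or seen.add(i))]
    P = pts[:, [i - 1 for i in walk], :]
    rel = P - c[:, None, :]
    dist = np.linalg.norm(rel, axis=2)
    rel_u = rel / np.maximum(dist[..., None], 1e-12)
    start = np.argmin(np.einsum("nwd,nd->nw", rel_u, axis), axis=1)
    from .geometry import DEPARTURE_RMS_MULT, MIN_DEPARTURE_TOL
    tol = np.maximum(MIN_DEPARTURE_TOL, DEPARTURE_RMS_MULT * rms / r)
    exceed = dist > (r * (1 + tol))[:, None]
    idx = np.arange(len(walk))
    valid = exceed & (idx[None, :] >= start[:, None])
    has = valid.any(axis=1)
    j = np.argmax(valid, axis=1)
    pj = rel[np.arange(n), j]
    cosang = np.einsum("nd,nd->n", pj, axis) / np.maximum(np.linalg.norm(pj, axis=1), 1e-12)
    aa = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    aa = np.where(has, aa, np.nan)

    # LCEA: lateral edge vs the vertical through the head centre
    ray = pts[:, sch.lateral_acetabular_edge_idx - 1, :] - c
    ang = np.degrees(np.arccos(np.clip(
        ray[:, 1] / np.maximum(np.linalg.norm(ray, axis=1), 1e-12), -1.0, 1.0)))
    lcea = np.where(ray[:, 0] < 0, ang, -ang)
    lcea = np.where(ray[:, 1] > 0, lcea, np.nan)
    return aa, lcea


def _build_outlines(shape_spec: GenerativeShapeSpec, z_raw: np.ndarray,
                    noise: np.ndarray) -> np.ndarray:
    """(n, 85, 2) outlines: template + mode deformations + landmark variation."""
    tmpl = shape_spec.template.points
    fields = np.asarray(shape_spec.modes, float)
    return tmpl[None, :, :] + np.einsum("nk,kij->nij", np.atleast_2d(z_raw), fields) + noise


@dataclass
class OutcomeModelSpec:
    """Latent severity, hospital-HOA and THR outcome models + OA phenotypes.

    ``severe``/``moderate`` define a latent three-level radiographic
    severity class (severe sampled first, moderate among the rest);
    osteophyte areas and a joint-space reduction are drawn conditional on
    that class so the grading stage can re-derive rHOA.  ``hospital`` is a
    plain logistic outcome and ``thr`` an exponential proportional-hazards
    time-to-event with administrative censoring.
    """

    moderate: OutcomeSpec
    severe: OutcomeSpec
    hospital: OutcomeSpec
    thr: OutcomeSpec
    thr_baseline_hazard: float = 1e-3      # events / year at covariate means
    censor_horizon: float = 6.0            # years of administrative follow-up
    # Gamma(shape, scale) osteophyte-area distributions (mm^2) per site,
    # conditional on the latent severity class.
    osteophyte_gamma: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "control": (0.5, 1.0),
        "moderate": (1.5, 2.0),
        "severe": (6.0, 4.0),
    })
    # Radial inward shift of the acetabular arc (mm): joint-space narrowing.
    jsw_reduction: dict[str, float] = field(default_factory=lambda: {
        "control": 0.0, "moderate": 0.8, "severe": 1.8,
    })
    # Reference (mean, SD) of the true morphology angles, frozen during
    # calibration so per-SD geometry effects are fixed population constants.
    aa_ref: tuple[float, float] | None = None
    lcea_ref: tuple[float, float] | None = None

    def validate(self) -> None:
        if self.thr_baseline_hazard <= 0:
            raise ValueError("THR baseline hazard must be positive")
        if self.censor_horizon <= 0:
            raise ValueError("censoring horizon must be positive")

    @classmethod
    def default(cls, shape_spec: GenerativeShapeSpec | None = None) -> "OutcomeModelSpec":
        """Default study conditions.

        Moderate disease relates to femoral-neck widening, trochanter size
        and *greater* acetabular coverage (positive LCEA effect); the
        severe outcomes (rHOA >= 3, hospital HOA, THR) are driven by cam
        morphology (higher alpha angle) and *reduced* coverage (negative
        LCEA effect), routed through the true morphology angles.
        """
        spec = cls(
            moderate=OutcomeSpec(
                intercept=0.0,
                gamma={"neck_width": np.log(1.25), "troch_size": np.log(1.15)},
                gamma_lcea=np.log(1.2),
                beta_age=0.04, beta_male=0.45, beta_weight=0.01,
            ),
            severe=OutcomeSpec(
                intercept=0.0,
                gamma_aa=np.log(1.6), gamma_lcea=-np.log(1.3),
                beta_age=0.05, beta_male=0.55, beta_weight=0.01,
            ),
            hospital=OutcomeSpec(
                intercept=0.0,
                gamma_aa=np.log(1.7), gamma_lcea=-np.log(1.5),
                beta_age=0.05, beta_male=-0.2, beta_weight=0.01,
            ),
            thr=OutcomeSpec(
                intercept=0.0,
                gamma_aa=0.35, gamma_lcea=-0.25,
                beta_age=0.05, beta_male=0.0, beta_weight=0.01,
            ),
        )
        # Marginal prevalence targets mirroring the cohort the generator
        # emulates: 5.7% moderate, 1.7% severe, 1.3% hospital HOA, 0.6% THR.
        spec.calibrate({"moderate": 0.057, "severe": 0.017,
                        "hospital": 0.013, "thr": 0.006},
                       shape_spec=shape_spec)
        return spec

    # -- intercept calibration --------------------------------------------

    def _linear_predictor(self, out: OutcomeSpec, z_std: np.ndarray,
                          mode_names, cov: pd.DataFrame,
                          covspec: CovariateSpec,
                          aa_std: np.ndarray | None = None,
                          lcea_std: np.ndarray | None = None) -> np.ndarray:
        eta = np.zeros(len(cov)) + out.intercept
        for k, name in enumerate(mode_names):
            g = out.gamma.get(name, 0.0)
            if g:
                eta = eta + g * z_std[:, k]
        if out.gamma_aa and aa_std is not None:
            eta = eta + out.gamma_aa * aa_std
        if out.gamma_lcea and lcea_std is not None:
            eta = eta + out.gamma_lcea * lcea_std
        eta = eta + out.beta_age * (cov["age"].to_numpy() - covspec.age_mean)
        eta = eta + out.beta_male * (cov["sex"] == "M").to_numpy()
        mean_w = covspec.p_male * covspec.weight_mean_m + (1 - covspec.p_male) * covspec.weight_mean_f
        eta = eta + out.beta_weight * (cov["weight"].to_numpy() - mean_w)
        return eta

    def _standardize_angles(self, aa: np.ndarray, lcea: np.ndarray
                            ) -> tuple[np.ndarray, np.ndarray]:
        """Per-SD units for the geometry effects; refs frozen on first use."""
        aa = np.nan_to_num(np.asarray(aa, float), nan=float(np.nanmean(aa)))
        lcea = np.nan_to_num(np.asarray(lcea, float), nan=float(np.nanmean(lcea)))
        if self.aa_ref is None or self.lcea_ref is None:
            self.aa_ref = (float(aa.mean()), float(aa.std() or 1.0))
            self.lcea_ref = (float(lcea.mean()), float(lcea.std() or 1.0))
        return ((aa - self.aa_ref[0]) / self.aa_ref[1],
                (lcea - self.lcea_ref[0]) / self.lcea_ref[1])

    def calibrate(self, targets: dict[str, float],
                  covariate_spec: CovariateSpec | None = None,
                  shape_spec: GenerativeShapeSpec | None = None,
                  n_mc: int = 200_000,
                  seed: int = 20_220_807) -> "OutcomeModelSpec":
        """Tune intercepts (and THR baseline hazard) to marginal prevalences.

        Monte-Carlo bisection on a fixed internal sample of standardized
        scores, morphology angles and covariates; the moderate target is
        interpreted among subjects not already severe.  The geometry
        reference mean/SD used to express per-SD angle effects are frozen
        here, so sampled subjects stay mutually independent.
        """
        covspec = covariate_spec or CovariateSpec()
        shape_spec = shape_spec or GenerativeShapeSpec.default()
        mode_names = shape_spec.mode_names
        rng = np.random.default_rng(seed)
        z_raw = shape_spec.sample_scores(rng, n_mc)
        z_std = z_raw / np.asarray(shape_spec.score_sd)
        aa = np.empty(n_mc)
        lcea = np.empty(n_mc)
        chunk = 50_000
        for lo in range(0, n_mc, chunk):  # chunked: outlines are large
            hi = min(lo + chunk, n_mc)
            noise = shape_spec.draw_landmark_noise(rng, hi - lo)
            pts = _build_outlines(shape_spec, z_raw[lo:hi], noise)
            aa[lo:hi], lcea[lo:hi] = anatomy_angles(shape_spec, pts)
        self.aa_ref = None
        self.lcea_ref = None
        aa_std, lcea_std = self._standardize_angles(aa, lcea)
        cov = _sample_covariates(rng, n_mc, covspec)

        def solve(out: OutcomeSpec, marginal_fn, target):
            lo, hi = -20.0, 10.0
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                out.intercept = mid
                if marginal_fn(out) < target:
                    lo = mid
                else:
                    hi = mid
            out.intercept = 0.5 * (lo + hi)

        def eta_of(out):
            return self._linear_predictor(out, z_std, mode_names, cov, covspec,
                                          aa_std=aa_std, lcea_std=lcea_std)

        def logistic_marginal(out):
            return _expit(eta_of(out)).mean()

        for name in ("severe", "hospital"):
            if name in targets:
                solve(getattr(self, name), logistic_marginal, targets[name])
        if "moderate" in targets:
            # among the non-severe remainder
            p_sev = _expit(eta_of(self.severe))
            def moderate_marginal(out):
                return ((1 - p_sev) * _expit(eta_of(out))).mean()
            solve(self.moderate, moderate_marginal, targets["moderate"])
        if "thr" in targets:
            eta = eta_of(self.thr)
            eta = eta - self.thr.intercept
            lo, hi = -14.0, 2.0
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                p = (1 - np.exp(-np.exp(mid + eta) * self.censor_horizon)).mean()
                if p < targets["thr"]:
                    lo = mid
                else:
                    hi = mid
            self.thr_baseline_hazard = float(np.exp(0.5 * (lo + hi)))
            self.thr.intercept = 0.0
        return self

    def to_json(self, path: str | Path) -> None:
        def enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return float(o)
            raise TypeError(type(o))
        Path(path).write_text(json.dumps(asdict(self), default=enc, indent=1))


def _sample_covariates(rng: np.random.Generator, n: int,
                       spec: CovariateSpec) -> pd.DataFrame:
    male = rng.random(n) < spec.p_male
    age = rng.normal(spec.age_mean, spec.age_sd, n)
    height = np.where(male,
                      rng.normal(spec.height_mean_m, spec.height_sd_m, n),
                      rng.normal(spec.height_mean_f, spec.height_sd_f, n))
    weight = np.where(male,
                      rng.normal(spec.weight_mean_m, spec.weight_sd_m, n),
                      rng.normal(spec.weight_mean_f, spec.weight_sd_f, n))
    weight = np.maximum(weight, 30.0)
    height = np.maximum(height, 120.0)
    white = (rng.random(n) < spec.p_white).astype(int)
    return pd.DataFrame({
        "age": age, "sex": np.where(male, "M", "F"),
        "height": height, "weight": weight, "ethnicity_white": white,
    })


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------

def sample_cohort(
    shape_spec: GenerativeShapeSpec | None = None,
    outcome_spec: OutcomeModelSpec | None = None,
    n: int = 2000,
    seed: int = 0,
    covariate_spec: CovariateSpec | None = None,
) -> tuple[list[LandmarkConfiguration], CohortTable, pd.DataFrame]:
    """Draw a full synthetic cohort.

    Returns ``(configs, cohort, true_scores)``: landmark configurations
    (template + mode deformations + severity-dependent joint-space
    narrowing + landmark noise), the covariate/outcome table, and the true
    per-subject mode scores (raw and standardized).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    shape_spec = shape_spec or GenerativeShapeSpec.default()
    outcome_spec = outcome_spec or OutcomeModelSpec.default()
    outcome_spec.validate()
    covspec = covariate_spec or CovariateSpec()
    rng = np.random.default_rng(seed)

    names = shape_spec.mode_names
    z_raw = shape_spec.sample_scores(rng, n)
    z_std = z_raw / np.asarray(shape_spec.score_sd)
    cov = _sample_covariates(rng, n, covspec)
    # The subject's outline (modes + local landmark variation) IS the
    # anatomy; its alpha angle / LCEA drive the geometry-channel outcomes.
    template = shape_spec.template.points
    noise = shape_spec.draw_landmark_noise(rng, n)
    outlines = _build_outlines(shape_spec, z_raw, noise)
    aa_anat, lcea_anat = anatomy_angles(shape_spec, outlines)
    aa_std, lcea_std = outcome_spec._standardize_angles(aa_anat, lcea_anat)

    def eta_of(out):
        return outcome_spec._linear_predictor(out, z_std, names, cov, covspec,
                                              aa_std=aa_std, lcea_std=lcea_std)

    # Latent radiographic severity class: severe first, moderate among rest.
    severe = rng.random(n) < _expit(eta_of(outcome_spec.severe))
    moderate = (~severe) & (rng.random(n) < _expit(eta_of(outcome_spec.moderate)))
    latent = np.where(severe, "severe", np.where(moderate, "moderate", "control"))

    # Hospital-diagnosed HOA and time-to-THR.
    hosp = (rng.random(n) < _expit(eta_of(outcome_spec.hospital))).astype(int)
    eta_thr = eta_of(outcome_spec.thr)
    lam = outcome_spec.thr_baseline_hazard * np.exp(eta_thr - outcome_spec.thr.intercept)
    t_event = rng.exponential(1.0 / lam)
    thr_event = (t_event < outcome_spec.censor_horizon).astype(int)
    thr_time = np.minimum(t_event, outcome_spec.censor_horizon)

    # Osteophyte areas per site, conditional on severity class.
    areas = np.empty((n, 3))
    for cls, (shape_g, scale_g) in outcome_spec.osteophyte_gamma.items():
        m = latent == cls
        if m.any():
            areas[m] = rng.gamma(shape_g, scale_g, size=(int(m.sum()), 3))

    # Landmark configurations: joint-space narrowing pulls the acetabular
    # arc radially toward the template head centre in affected subjects.
    acet = np.arange(77, template.shape[0])
    radial_ac = template[acet] / np.linalg.norm(template[acet], axis=1, keepdims=True)
    jsw_shift = np.array([outcome_spec.jsw_reduction.get(c, 0.0) for c in latent])
    outlines[:, acet, :] -= jsw_shift[:, None, None] * radial_ac[None, :, :]

    configs: list[LandmarkConfiguration] = []
    width = len(str(n))
    for i in range(n):
        configs.append(LandmarkConfiguration(subject_id=f"S{i:0{width}d}",
                                             points=outlines[i]))

    df = cov.copy()
    df.insert(0, "subject_id", [c.subject_id for c in configs])
    df["osteo_area_lat_acetabulum"] = areas[:, 0]
    df["osteo_area_sup_lat_head"] = areas[:, 1]
    df["osteo_area_inf_med_head"] = areas[:, 2]
    df["hoa_hospital"] = hosp
    df["thr_event"] = thr_event
    df["thr_time"] = thr_time
    df["latent_class"] = latent

    scores = pd.DataFrame(z_raw, columns=[f"{m}_raw" for m in names])
    for k, m in enumerate(names):
        scores[f"{m}_std"] = z_std[:, k]
    scores.insert(0, "subject_id", df["subject_id"])

    return configs, CohortTable(df), scores
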