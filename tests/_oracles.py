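"""Independent brute-force geometric oracles used to cross-check the package.

Everything here deliberately re-derives the measurements through different
algorithms (dense sampling, grid search, scalar loops over complex
arithmetic) so that the vectorised implementations in ``hipshape.geometry``
are checked against an independent path, not against themselves.
"""

from __future__ import annotations

import cmath
import math

import numpy as np
from scipy.spatial import cKDTree


def _densify(V, samples_per_segment: int):
    V = np.atleast_2d(np.asarray(V, float))
    if len(V) == 1:
        return V
    out = [V[[0]]]
    for a, b in zip(V[:-1], V[1:]):
        t = np.linspace(0.0, 1.0, samples_per_segment + 1)[1:]
        out.append(a[None, :] + t[:, None] * (b - a)[None, :])
    return np.vstack(out)


def brute_polyline_min_distance(P, Q, samples_per_segment: int = 2000) -> float:
    """Min distance between two polylines by dense sampling of both chains."""
    A = _densify(P, samples_per_segment)
    B = _densify(Q, samples_per_segment)
    d, _ = cKDTree(B).query(A)
    return float(d.min())


def grid_circle_fit(pts, span: float = 40.0, levels: int = 8):
    """Geometric least-squares circle by refined grid search over the centre.

    For a fixed centre the optimal radius is the mean point distance, so the
    search is 2-D: coarse-to-fine 41x41 grids shrinking by 4x per level
    (initial span wide enough that the centre need not be near the arc's
    centroid; final resolution ~1e-4 mm).
    """
    pts = np.asarray(pts, float)
    cx, cy = pts.mean(axis=0)
    step = span / 40.0
    for _ in range(levels):
        gx = cx + step * np.arange(-20, 21)
        gy = cy + step * np.arange(-20, 21)
        best = (np.inf, cx, cy)
        for x in gx:
            for y in gy:
                d = np.hypot(pts[:, 0] - x, pts[:, 1] - y)
                r = d.mean()
                sse = float(np.sum((d - r) ** 2))
                if sse < best[0]:
                    best = (sse, x, y)
        _, cx, cy = best
        step /= 4.0
    d = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
    return float(cx), float(cy), float(d.mean())


def angle_between_deg(u, v) -> float:
    """Unsigned angle via complex arguments, degrees in [0, 180]."""
    a = cmath.phase(complex(*u))
    b = cmath.phase(complex(*v))
    d = abs(math.degrees(a - b)) % 360.0
    return 360.0 - d if d > 180.0 else d


def oracle_measures(config, schema, delta=None):
    """All five morphometrics re-derived with scalar/brute-force algorithms."""
    pts = config.points

    def grab(idx):
        return pts[[i - 1 for i in idx]]

    # --- head circle (grid search) ---
    cx, cy, r = grid_circle_fit(grab(schema.head_circle_idx))
    centre = np.array([cx, cy])
    rms = float(np.sqrt(np.mean(
        (np.hypot(*(grab(schema.head_circle_idx) - centre).T) - r) ** 2)))

    # --- NNW + neck axis ---
    sup = grab(schema.superior_neck_idx)
    inf = grab(schema.inferior_neck_idx)
    # minimising pair and its midpoint, by dense sampling + KD-tree query
    A = _densify(sup, 800)
    B = _densify(inf, 800)
    d, j = cKDTree(B).query(A)
    i = int(np.argmin(d))
    nnw = float(d[i])
    mid = (A[i] + B[j[i]]) / 2.0
    axis = mid - centre
    axis = axis / math.hypot(*axis)

    # --- alpha angle: scalar walk ---
    tol = delta if delta is not None else max(0.02, 3.0 * rms / r)
    walk_idx = (list(schema.superior_head_idx) + list(schema.head_neck_junction_idx)
                + list(schema.superior_neck_idx) + list(schema.greater_troch_idx))
    seen, walk = set(), []
    for i1 in walk_idx:
        if i1 not in seen:
            seen.add(i1)
            walk.append(i1)
    opp = []
    for i1 in walk:
        v = pts[i1 - 1] - centre
        opp.append(angle_between_deg(v, axis))
    start = int(np.argmax(opp))
    aa = float("nan")
    for i1 in walk[start:]:
        p = pts[i1 - 1]
        if math.hypot(p[0] - cx, p[1] - cy) > r * (1.0 + tol):
            aa = angle_between_deg(p - centre, axis)
            break

    # --- LCEA ---
    edge = pts[schema.lateral_acetabular_edge_idx - 1]
    ray = edge - centre
    if ray[1] <= 0:
        ce = float("nan")
    else:
        ce = angle_between_deg(ray, (0.0, 1.0))
        if ray[0] > 0:
            ce = -ce

    # --- NSA: nearest-y pairing, total-least-squares line on midpoints ---
    med = grab(schema.shaft_medial_idx)
    lat = grab(schema.shaft_lateral_idx)
    mids = []
    for m in med:
        k = int(np.argmin(np.abs(lat[:, 1] - m[1])))
        mids.append((m + lat[k]) / 2.0)
    mids = np.unique(np.asarray(mids), axis=0)
    c = mids - mids.mean(axis=0)
    cov = c.T @ c
    w, V = np.linalg.eigh(cov)
    shaft_dir = V[:, int(np.argmax(w))]
    nsa = angle_between_deg(axis, shaft_dir)
    nsa = max(nsa, 180.0 - nsa)

    # --- mJSW ---
    mj = brute_polyline_min_distance(grab(schema.superior_head_idx),
                                     grab(schema.acetabulum_idx))

    return {"alpha_angle": aa, "lcea": ce, "nsa": nsa, "nnw": float(nnw), "mjsw": float(mj)}
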