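"""Statistical shape model: generalized Procrustes alignment + landmark PCA.

A point-distribution model in the classical sense: configurations are
aligned by generalized Procrustes analysis (translation, rotation and by
default scale removal), and the covariance of the aligned coordinates is
eigen-decomposed into orthogonal hip shape modes (HSMs).  Mode scores are
standardized over the training cohort to mean 0 / SD 1; the per-mode raw
(non-standardized) score SDs are kept because composite shape figures
scale regression coefficients by them.

Absolute mm measures (neck width, joint-space width) are never computed
in the aligned frame — scale removal makes it unitless — but on the
original coordinates via :mod:`hipshape.geometry`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .schema import LandmarkConfiguration

__all__ = [
    "ShapeModel",
    "ShapeModelError",
    "generalized_procrustes",
    "fit_pca",
    "fit_shape_model",
    "standardize",
]


class ShapeModelError(ValueError):
    pass


def _centroid_size(pts: np.ndarray) -> float:
    c = pts.mean(axis=0)
    return float(np.sqrt(np.sum((pts - c) ** 2)))


def _optimal_rotation(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Rotation matrix (no reflection) minimising ||src @ R.T - dst||."""
    H = src.T @ dst
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, d])
    return Vt.T @ D @ U.T


def _align_one(pts: np.ndarray, ref: np.ndarray, allow_scaling: bool) -> np.ndarray:
    """Superimpose one centred configuration onto a centred reference."""
    p = pts - pts.mean(axis=0)
    if allow_scaling:
        s = _centroid_size(p)
        if s < 1e-12:
            raise ShapeModelError("degenerate configuration: zero centroid size")
        p = p / s
    R = _optimal_rotation(p, ref)
    return p @ R.T


def generalized_procrustes(
    configs: Sequence[LandmarkConfiguration],
    allow_scaling: bool = True,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively align configurations to their evolving mean shape.

    Returns ``(aligned, mean_shape)`` where ``aligned`` is (n, p, 2) and
    ``mean_shape`` is (p, 2), centred at the origin (and of unit centroid
    size when ``allow_scaling``).  Convergence: mean-shape change below
    *tol* (RMS per coordinate) or *max_iter* iterations.
    """
    if len(configs) < 2:
        raise ShapeModelError("generalized Procrustes needs >= 2 configurations")
    X = np.stack([np.asarray(c.points, float) for c in configs])
    n, p, _ = X.shape
    sizes = np.array([_centroid_size(x) for x in X])
    if np.any(sizes < 1e-12):
        raise ShapeModelError("degenerate configuration: all points coincident")

    mean = X[0] - X[0].mean(axis=0)
    if allow_scaling:
        mean = mean / _centroid_size(mean)
    aligned = np.empty_like(X)
    for _ in range(max_iter):
        for i in range(n):
            aligned[i] = _align_one(X[i], mean, allow_scaling)
        new_mean = aligned.mean(axis=0)
        new_mean = new_mean - new_mean.mean(axis=0)
        if allow_scaling:
            s = _centroid_size(new_mean)
            if s < 1e-12:
                raise ShapeModelError("mean shape collapsed during alignment")
            new_mean = new_mean / s
        change = np.sqrt(np.mean((new_mean - mean) ** 2))
        mean = new_mean
        if change < tol:
            break
    # Canonical orientation: principal axis of the mean along y, with the
    # farthest-from-centroid point inferior.  Makes the fitted model (mean,
    # modes) invariant to rigid motion of the whole input set, not just
    # invariant up to a global rotation.
    Rc = _canonical_rotation(mean)
    mean = mean @ Rc.T
    for i in range(n):  # final pass against the converged, canonical mean
        aligned[i] = _align_one(X[i], mean, allow_scaling)
    return aligned, mean


def _canonical_rotation(mean: np.ndarray) -> np.ndarray:
    C = mean.T @ mean
    w, V = np.linalg.eigh(C)
    v = V[:, int(np.argmax(w))]
    R = np.array([[v[1], -v[0]], [v[0], v[1]]])  # rotates v onto +y
    far = mean[int(np.argmax(np.linalg.norm(mean, axis=1)))]
    if (R @ far)[1] > 0:
        R = -R  # extra half turn: det stays +1
    return R


@dataclass
class ShapeModel:
    """Procrustes mean, orthonormal deformation modes and score statistics.

    ``modes`` has one column per mode over the flattened (x1, y1, ...)
    coordinates; ``raw_sd`` holds the non-standardized per-mode score SDs
    and ``var_frac`` the variance fractions (``raw_sd**2`` normalised).
    """

    mean_shape: np.ndarray          # (p, 2)
    modes: np.ndarray               # (2p, K) orthonormal columns
    raw_sd: np.ndarray              # (K,)
    var_frac: np.ndarray            # (K,)
    allow_scaling: bool = True
    n_train: int = 0
    score_mean: np.ndarray = field(default=None)  # training raw-score means

    def __post_init__(self) -> None:
        G = self.modes.T @ self.modes
        if not np.allclose(G, np.eye(self.n_modes), atol=1e-8):
            raise ShapeModelError("mode matrix is not orthonormal")
        if np.any(np.diff(self.var_frac) > 1e-12):
            raise ShapeModelError("variance fractions must be non-increasing")
        if self.score_mean is None:
            self.score_mean = np.zeros(self.n_modes)

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    @property
    def n_points(self) -> int:
        return self.mean_shape.shape[0]

    # -- scoring -----------------------------------------------------------

    def align(self, config: LandmarkConfiguration) -> np.ndarray:
        """Superimpose a new configuration onto the model mean, (p, 2)."""
        if config.n_points != self.n_points:
            raise ShapeModelError(
                f"configuration has {config.n_points} points, model expects {self.n_points}"
            )
        return _align_one(np.asarray(config.points, float), self.mean_shape,
                          self.allow_scaling)

    def score_raw(self, config: LandmarkConfiguration,
                  assume_aligned: bool = False) -> np.ndarray:
        """Raw (non-standardized) mode scores of one configuration.

        With ``assume_aligned`` the configuration is taken to live in the
        model frame already (e.g. a :meth:`reconstruct` output) and is
        projected directly, making score->reconstruct->score exact.
        """
        x = (np.asarray(config.points, float) if assume_aligned
             else self.align(config)).reshape(-1)
        return self.modes.T @ (x - self.mean_shape.reshape(-1))

    def score(self, config: LandmarkConfiguration,
              assume_aligned: bool = False) -> np.ndarray:
        """Standardized mode scores (training mean 0 / SD 1 units)."""
        return (self.score_raw(config, assume_aligned) - self.score_mean) / self.raw_sd

    def transform(self, configs: Sequence[LandmarkConfiguration],
                  standardized: bool = True) -> pd.DataFrame:
        """Score a set of configurations; one ``hsm{i}`` column per mode."""
        rows = [self.score(c) if standardized else self.score_raw(c) for c in configs]
        df = pd.DataFrame(np.asarray(rows),
                          columns=[f"hsm{i + 1}" for i in range(self.n_modes)])
        df.insert(0, "subject_id", [c.subject_id for c in configs])
        return df

    # -- reconstruction ----------------------------------------------------

    def reconstruct(self, z_raw: np.ndarray, n_modes: int | None = None,
                    subject_id: str = "reconstruction") -> LandmarkConfiguration:
        """Mean shape plus a raw-score mode combination, in the aligned frame."""
        z_raw = np.atleast_1d(np.asarray(z_raw, float))
        if n_modes is None:
            n_modes = len(z_raw)
        if n_modes > self.n_modes:
            raise ShapeModelError(
                f"requested {n_modes} modes but model has {self.n_modes}"
            )
        if len(z_raw) > n_modes:
            raise ShapeModelError("more scores than requested modes")
        x = self.mean_shape.reshape(-1) + self.modes[:, : len(z_raw)] @ z_raw
        return LandmarkConfiguration(subject_id=subject_id, points=x.reshape(-1, 2))

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mean_shape": self.mean_shape.tolist(),
            "modes": self.modes.tolist(),
            "raw_sd": self.raw_sd.tolist(),
            "var_frac": self.var_frac.tolist(),
            "allow_scaling": self.allow_scaling,
            "n_train": self.n_train,
            "score_mean": self.score_mean.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ShapeModel":
        d = json.loads(Path(path).read_text())
        return cls(
            mean_shape=np.asarray(d["mean_shape"], float),
            modes=np.asarray(d["modes"], float),
            raw_sd=np.asarray(d["raw_sd"], float),
            var_frac=np.asarray(d["var_frac"], float),
            allow_scaling=bool(d["allow_scaling"]),
            n_train=int(d["n_train"]),
            score_mean=np.asarray(d["score_mean"], float),
        )

    def cumulative_variance(self, k: int) -> float:
        """Fraction of total shape variance explained by the top *k* modes."""
        return float(np.sum(self.var_frac[:k]))


def _pin_mode_signs(modes: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|element| entry made positive."""
    out = modes.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def fit_pca(
    aligned: np.ndarray,
    allow_scaling: bool = True,
) -> ShapeModel:
    """PCA of aligned landmark coordinates into an ordered mode basis.

    *aligned* is the (n, p, 2) output of :func:`generalized_procrustes`.
    Eigen-decomposition is of the coordinate covariance (SVD of the centred
    data matrix); modes are ordered by explained variance with a pinned
    sign convention, and trailing numerically-null directions are dropped.
    """
    aligned = np.asarray(aligned, float)
    n = aligned.shape[0]
    if n < 2:
        raise ShapeModelError("PCA needs >= 2 aligned configurations")
    X = aligned.reshape(n, -1)
    col_mean = X.mean(axis=0)
    Xc = X - col_mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    sd = s / np.sqrt(n - 1)
    keep = sd > max(1e-12, 1e-9 * sd[0]) if sd[0] > 0 else sd > -1
    k = int(np.sum(keep))
    modes = _pin_mode_signs(Vt[:k].T)
    raw_scores = Xc @ modes
    raw_sd = raw_scores.std(axis=0, ddof=1)
    var_frac = raw_sd**2 / np.sum(raw_sd**2)
    return ShapeModel(
        mean_shape=col_mean.reshape(-1, 2),
        modes=modes,
        raw_sd=raw_sd,
        var_frac=var_frac,
        allow_scaling=allow_scaling,
        n_train=n,
        score_mean=raw_scores.mean(axis=0),
    )


def fit_shape_model(
    configs: Sequence[LandmarkConfiguration],
    allow_scaling: bool = True,
) -> ShapeModel:
    """GPA + PCA in one step: the full shape-model build."""
    aligned, _ = generalized_procrustes(configs, allow_scaling=allow_scaling)
    return fit_pca(aligned, allow_scaling=allow_scaling)


def standardize(raw_scores: np.ndarray) -> np.ndarray:
    """Standardize raw score columns over a cohort to mean 0 / SD 1."""
    raw_scores = np.asarray(raw_scores, float)
    mu = raw_scores.mean(axis=0)
    sd = raw_scores.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ShapeModelError("cannot standardize a zero-variance score column")
    return (raw_scores - mu) / sd
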