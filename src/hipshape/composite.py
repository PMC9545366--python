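"""Composite "OA risk shape" outlines from per-mode regression coefficients.

For one outcome, every mode significant at the Bonferroni threshold
contributes the term ``beta * raw_sd * factor * mode`` to a single shape
offset vector: *beta* is the log-odds (log-hazard) coefficient per SD,
*raw_sd* the mode's non-standardized score SD (so each mode contributes
in proportion to its share of shape variance), and *factor* an arbitrary
visual multiplier (default 5) that exaggerates the offset for display —
it is metadata, never physical mm.  The composite outline is the mean
shape plus the offset, in the aligned model frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import LandmarkConfiguration, PointSchema, DEFAULT_SCHEMA
from .ssm import ShapeModel

__all__ = ["CompositeShape", "build_composite", "render_outlines", "composite_to_frame"]


@dataclass
class CompositeShape:
    """One outcome's combined significant-mode shape offset."""

    outcome: str
    included_hsms: tuple[str, ...]
    coefficients: tuple[float, ...]     # log-odds / log-hazard per SD
    factor: float
    offset: np.ndarray                  # flattened (2p,) shape offset
    composite_points: LandmarkConfiguration
    mean_points: LandmarkConfiguration


def build_composite(
    model: ShapeModel,
    results: pd.DataFrame,
    outcome: str,
    factor: float = 5.0,
    p_threshold: float = 0.005,
) -> CompositeShape:
    """Combine all modes significant for *outcome* into one composite shape.

    *results* is a results table from :mod:`hipshape.association` with
    ``hsm``, ``outcome``, ``beta``, ``p_value`` and ``estimable`` columns
    (one adjustment model; filter before calling if several are present).
    With no significant mode the composite equals the mean shape and the
    inclusion list is empty — a finding, not an error.
    """
    sub = results[(results["outcome"] == outcome)]
    if "estimable" in sub.columns:
        sub = sub[sub["estimable"].astype(bool)]
    sub = sub[sub["p_value"] < p_threshold]
    offset = np.zeros(model.modes.shape[0])
    included: list[str] = []
    betas: list[float] = []
    for _, row in sub.iterrows():
        k = int(str(row["hsm"]).replace("hsm", "")) - 1
        if k >= model.n_modes:
            raise ValueError(f"{row['hsm']} not present in the shape model")
        beta = float(row["beta"])
        offset = offset + beta * model.raw_sd[k] * factor * model.modes[:, k]
        included.append(str(row["hsm"]))
        betas.append(beta)
    mean_cfg = LandmarkConfiguration("mean_shape", model.mean_shape.copy())
    comp_pts = model.mean_shape.reshape(-1) + offset
    comp_cfg = LandmarkConfiguration(f"composite_{outcome}", comp_pts.reshape(-1, 2))
    return CompositeShape(
        outcome=outcome,
        included_hsms=tuple(included),
        coefficients=tuple(betas),
        factor=factor,
        offset=offset,
        composite_points=comp_cfg,
        mean_points=mean_cfg,
    )


def composite_to_frame(comp: CompositeShape) -> pd.DataFrame:
    """Offsets as a tidy per-point table (for CSV dumps alongside figures)."""
    off = comp.offset.reshape(-1, 2)
    return pd.DataFrame({
        "point": np.arange(1, len(off) + 1),
        "dx": off[:, 0],
        "dy": off[:, 1],
        "x_mean": comp.mean_points.points[:, 0],
        "y_mean": comp.mean_points.points[:, 1],
        "x_composite": comp.composite_points.points[:, 0],
        "y_composite": comp.composite_points.points[:, 1],
    })


def _outline_parts(schema: PointSchema) -> tuple[np.ndarray, np.ndarray]:
    """Split the point order into the femur loop and the acetabular arc."""
    ac_start = min(schema.acetabulum_idx)
    femur = np.arange(0, ac_start - 1)
    acet = np.arange(ac_start - 1, schema.n_points)
    return femur, acet


def render_outlines(
    mean: LandmarkConfiguration,
    composites: dict[str, LandmarkConfiguration],
    path: str | Path,
    schema: PointSchema = DEFAULT_SCHEMA,
    title: str | None = None,
) -> Path:
    """Plot mean vs composite outlines (femur closed, acetabular arc open).

    The mean outline is black; composites are coloured and labelled by
    group.  Output format follows the file suffix (svg/png/pdf).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    femur, acet = _outline_parts(schema)
    fig, ax = plt.subplots(figsize=(5, 6))

    def draw(cfg: LandmarkConfiguration, color: str, label: str | None):
        P = cfg.points
        loop = np.append(femur, femur[0])
        ax.plot(P[loop, 0], P[loop, 1], color=color, lw=1.4, label=label)
        ax.plot(P[acet, 0], P[acet, 1], color=color, lw=1.4)

    draw(mean, "black", "mean shape")
    palette = ["tab:green", "tab:blue", "tab:red", "tab:orange", "tab:purple"]
    for (name, cfg), color in zip(composites.items(), palette):
        draw(cfg, color, name)
    ax.set_aspect("equal")
    ax.invert_xaxis()  # radiographic convention: medial on the reader's right
    ax.set_xlabel("x (aligned frame)")
    ax.set_ylabel("y (aligned frame)")
    if title:
        ax.set_title(title)
    ax.legend(loc="lower left", fontsize=8)
    path = Path(path)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return path
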