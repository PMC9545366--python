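"""Composite OA-shape outlines per outcome.

For each outcome, the modes significant at p < 0.005 are combined into a
single shape offset (beta x non-standardized mode SD x visual factor 5)
added to the mean shape; the mean and composite outlines are rendered
together and the per-point offsets written as CSV.
"""

import sys
from pathlib import Path

import pandas as pd

from hipshape.composite import build_composite, composite_to_frame, render_outlines
from hipshape.pipeline import OUTCOMES
from hipshape.ssm import ShapeModel

ROOT = Path(__file__).resolve().parent.parent / "results"
FACTOR = 5.0


def main() -> None:
    model = ShapeModel.from_json(ROOT / "model.json")
    results = pd.read_csv(ROOT / "results.csv")
    model2 = results[results["model"] == "model2"]

    composites = {}
    for outcome in OUTCOMES:
        comp = build_composite(model, model2, outcome, factor=FACTOR)
        composite_to_frame(comp).to_csv(ROOT / f"composite_{outcome}.csv", index=False)
        composites[outcome] = comp.composite_points
        disp = float(abs(comp.offset).max())
        print(f"  {outcome}: {len(comp.included_hsms)} modes "
              f"({', '.join(comp.included_hsms) or 'none'}), "
              f"max |offset| {disp:.4f} (aligned units, x{FACTOR:g} exaggeration)")
    mean = build_composite(model, model2, OUTCOMES[0], factor=FACTOR).mean_points
    out = render_outlines(mean, composites, ROOT / "composites.svg",
                          title="mean vs composite OA shapes")
    print(f"rendered outlines -> {out}")


if __name__ == "__main__":
    sys.exit(main())
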