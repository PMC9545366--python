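"""Build the statistical shape model and score the cohort.

Generalized Procrustes alignment (with scale removal) followed by PCA of
the aligned coordinates yields the hip shape modes; scores are
standardized to mean 0 / SD 1 over the cohort and the first ten modes are
carried forward into the association stage.
"""

import sys
from pathlib import Path

from hipshape.schema import read_points_dir
from hipshape.ssm import fit_shape_model

K = 10
ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    configs = read_points_dir(ROOT / "cohort" / "points")
    model = fit_shape_model(configs)
    model.to_json(ROOT / "model.json")
    scores = model.transform(configs)
    scores = scores[["subject_id"] + [f"hsm{i + 1}" for i in range(K)]]
    scores.to_csv(ROOT / "scores.csv", index=False)

    print(f"shape model from {len(configs)} outlines: {model.n_modes} modes")
    for i in range(6):
        print(f"  hsm{i + 1}: variance fraction {model.var_frac[i]:.3f}")
    print(f"  top-{K} cumulative variance: {model.cumulative_variance(K):.3f}")
    print(f"wrote {ROOT / 'model.json'} and scores for {len(scores)} subjects")


if __name__ == "__main__":
    sys.exit(main())
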