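"""Geometric morphometrics per subject, with a sex-stratified summary.

Alpha angle, lateral centre-edge angle, neck-shaft angle, narrowest neck
width and minimum joint-space width are measured on the raw (mm)
coordinates of each outline and summarised overall and by sex.
"""

import sys
from pathlib import Path

import pandas as pd

from hipshape.geometry import measure_cohort
from hipshape.schema import read_cohort, read_points_dir

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    configs = read_points_dir(ROOT / "cohort" / "points")
    measures = measure_cohort(configs)
    measures.to_csv(ROOT / "measures.csv", index=False)

    cohort = read_cohort(ROOT / "cohort" / "cohort.csv").df
    df = measures.merge(cohort[["subject_id", "sex"]], on="subject_id")
    print(f"measured {len(df)} subjects -> {ROOT / 'measures.csv'}")
    for name, col in (("AA (deg)", "alpha_angle"), ("LCEA (deg)", "lcea"),
                      ("NSA (deg)", "nsa"), ("NNW (mm)", "nnw"),
                      ("mJSW (mm)", "mjsw")):
        overall = df[col]
        males = df.loc[df.sex == "M", col]
        females = df.loc[df.sex == "F", col]
        print(f"  {name:10s} combined {overall.mean():6.1f} ({overall.std():.1f})"
              f"  M {males.mean():6.1f} ({males.std():.1f})"
              f"  F {females.mean():6.1f} ({females.std():.1f})")
    n_undef = int((~pd.notna(df.alpha_angle)).sum())
    print(f"  alpha angle undefined for {n_undef} subjects")


if __name__ == "__main__":
    sys.exit(main())
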