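# hipshape

Statistical shape analysis of the proximal femur on 2-D landmark
outlines, for musculoskeletal epidemiologists studying how hip shape
relates to hip osteoarthritis (HOA) of different severities. The package
covers the full analysis chain:

1. **Shape model** — generalized Procrustes alignment (GPA) of 85-point
   left-hip outlines and PCA into orthogonal *hip shape modes* (HSMs),
   with scores standardized to mean 0 / SD 1;
2. **Geometric morphometrics** — alpha angle (AA, cam morphology),
   lateral centre-edge angle (LCEA, acetabular coverage), neck-shaft
   angle (NSA), narrowest neck width (NNW) and minimum joint-space width
   (mJSW), measured automatically from the landmarks;
3. **rHOA grading** — osteophyte areas graded 0–3 at three sites plus a
   joint-space-narrowing grade from height-adjusted mJSW, summed (0–12)
   into four overall radiographic HOA grades;
4. **Association models** — per-mode logistic (moderate/severe rHOA,
   hospital-diagnosed HOA) and Cox (time to total hip replacement)
   models, OR/HR per 1 SD of mode score with Wald CIs, a Bonferroni
   threshold p < 0.05/10, and further adjustment for AA or LCEA with
   excess-odds attenuation `100·(OR_base − OR_adj)/(OR_base − 1)`;
5. **Composite shapes** — significant modes combined into one outline
   offset `Σ β_i · sd_i · 5 · mode_i` (β = log-odds per SD, sd = the
   mode's non-standardized score SD, 5 = visual factor).

Real cohorts of this kind are access-controlled, so the package includes
a first-class synthetic cohort generator (`hipshape.simulate`) with a
parametric femur template, orthonormal deformation modes (including a
cam-type head–neck bump and an acetabular-coverage rotation), Gaussian
scores, landmark noise, covariate margins and calibrated logistic /
proportional-hazards outcome models. Every stage is tested against it.

## Worked example

The numbered scripts under `analysis/` run the whole study on a
synthetic cohort and write their tables under `results/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_build_shape_model.py
python analysis/03_measure_geometry.py
python analysis/04_grade_rhoa.py
python analysis/05_fit_associations.py
python analysis/06_composite_shapes.py
```

With the default seed (1) and n = 4000 this prints, among other lines:

```
simulated n=4000 subjects (seed 1) -> results/cohort
  latent moderate: 0.054, severe: 0.018
  hospital HOA: 0.013, THR events: 0.006
shape model from 4000 outlines: 167 modes
  top-10 cumulative variance: 0.566
  AA (deg)   combined   49.1 (16.7)
graded 4000 subjects -> results/grades.csv
  rHOA grade 2 only          162 (4.0%)
  rHOA grade >= 3             96 (2.4%)
  hospital-diagnosed HOA      53 (1.3%)
  THR                         25 (0.6%)
  cam-aligned mode hsm1 vs hospital HOA: OR 0.59 -> 1.04 after angle
  adjustment (110% excess-odds attenuation)
```

Reading: the generator hits its calibrated prevalences (which decrease
with severity); the first ten fitted modes carry 57% of shape variance
in this four-mode-plus-noise cohort; the mode aligned with the injected
cam factor is associated with hospital-diagnosed HOA, and that
association is removed by adjusting for the alpha angle — the
morphology-adjustment logic the pipeline exists to test. (Mode signs are
arbitrary but pinned; here hsm1 is anti-aligned with the cam score, so
its protective OR corresponds to a harmful cam effect.)

The same stages are available as a CLI
(`hipshape simulate | build-ssm | measure | grade | associate |
composite | run`), e.g.:

```sh
hipshape run --n 2000 --seed 1 --out run1/
```

## Layout

```
src/hipshape/      library: schema, simulate, ssm, geometry, grading,
                   association, composite, pipeline, cli
analysis/          numbered narrative drivers over the library
tests/             pytest suite (unit, property and acceptance tests)
scripts/           acceptance script
docs/methods.md    model, defaults and design decisions
```
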