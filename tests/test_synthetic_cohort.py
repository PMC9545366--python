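"""The synthetic cohort generator: template, modes, outcomes, determinism."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from hipshape.geometry import alpha_angle, lcea, measure_cohort
from hipshape.schema import DEFAULT_SCHEMA
from hipshape.simulate import (CovariateSpec, GenerativeShapeSpec, MODE_NAMES,
                               OutcomeModelSpec, TemplateGeometry,
                               make_template, sample_cohort)

from conftest import deformed_configs


class TestTemplate:
    def test_head_points_exactly_on_circle(self, template, schema):
        pts = template.get(schema.head_circle_idx)
        r = np.linalg.norm(pts, axis=1)
        np.testing.assert_allclose(r, 25.0, atol=1e-9)

    def test_85_points_default(self, template):
        assert template.n_points == 85

    @pytest.mark.parametrize("bad", [
        dict(r_head=-1.0),
        dict(neck_half_width=30.0),       # neck wider than head diameter
        dict(neck_length=5.0),            # degenerate, zero-length neck scale
        dict(joint_space=0.0),
    ])
    def test_degenerate_geometry_rejected(self, bad):
        with pytest.raises(ValueError):
            make_template(TemplateGeometry(**bad))

    def test_doubling_all_lengths_doubles_pairwise_distances(self, template):
        g2 = TemplateGeometry(r_head=50.0, neck_half_width=31.6, neck_length=80.0,
                              shaft_half_width=30.0, shaft_bottom_y=-190.0,
                              joint_space=8.0)
        t2 = make_template(g2)
        d1 = np.linalg.norm(template.points[:, None] - template.points[None, :], axis=2)
        d2 = np.linalg.norm(t2.points[:, None] - t2.points[None, :], axis=2)
        np.testing.assert_allclose(d2, 2.0 * d1, atol=1e-9)

    def test_zero_cam_weight_gives_baseline_junction_angle(self, template):
        aa, diag = alpha_angle(template)
        assert diag == ""
        # template junction point sits at 45 deg from the neck axis by design
        assert aa == pytest.approx(45.0, abs=1e-9)


class TestModes:
    def test_fields_orthonormal(self, shape_spec):
        flat = np.asarray(shape_spec.modes).reshape(len(MODE_NAMES), -1)
        G = flat @ flat.T
        assert np.max(np.abs(G - np.eye(len(flat)))) < 1e-8

    def test_non_orthogonal_modes_rejected_before_sampling(self, shape_spec):
        bad = np.asarray(shape_spec.modes).copy()
        bad[1] = bad[0]
        with pytest.raises(ValueError, match="orthonormal"):
            GenerativeShapeSpec(template=shape_spec.template, modes=bad,
                                score_sd=np.ones(4), mode_names=MODE_NAMES)

    def test_cam_sweep_monotone_in_alpha_angle(self, noise_free_spec):
        """AA is non-decreasing along a cam sweep.

        Monotone up to a few millidegrees of wiggle: the orthogonalized cam
        field has tiny weights on the head-circle points themselves, so the
        fitted circle centre (the angle vertex) drifts minutely with the
        score.
        """
        sweep = np.linspace(0.0, 9.0, 25)
        scores = np.zeros((len(sweep), 4))
        scores[:, 0] = sweep
        configs = deformed_configs(noise_free_spec, scores)
        aa = np.array([alpha_angle(c)[0] for c in configs])
        assert np.all(np.diff(aa) >= -0.05)
        assert aa[-1] > aa[0] + 20.0  # strongly increasing overall

    def test_coverage_sweep_monotone_in_lcea(self, noise_free_spec):
        sweep = np.linspace(-6.0, 6.0, 25)
        scores = np.zeros((len(sweep), 4))
        scores[:, 1] = sweep
        configs = deformed_configs(noise_free_spec, scores)
        ce = [lcea(c)[0] for c in configs]
        assert np.all(np.diff(ce) > 0)


class TestSampling:
    def test_identical_seed_identical_output(self, shape_spec, outcome_spec):
        a = sample_cohort(shape_spec, outcome_spec, n=50, seed=123)
        b = sample_cohort(shape_spec, outcome_spec, n=50, seed=123)
        for ca, cb in zip(a[0], b[0]):
            np.testing.assert_array_equal(ca.points, cb.points)
        assert a[1].df.equals(b[1].df)
        assert a[2].equals(b[2])

    def test_distinct_seeds_differ(self, shape_spec, outcome_spec):
        a = sample_cohort(shape_spec, outcome_spec, n=10, seed=1)
        b = sample_cohort(shape_spec, outcome_spec, n=10, seed=2)
        assert not np.array_equal(a[0][0].points, b[0][0].points)

    def test_score_sds_recovered(self, shape_spec, outcome_spec):
        _, _, scores = sample_cohort(shape_spec, outcome_spec, n=10000, seed=3)
        for k, name in enumerate(MODE_NAMES):
            s = shape_spec.score_sd[k]
            emp = scores[f"{name}_raw"].std(ddof=1)
            se = s / np.sqrt(2 * (10000 - 1))
            assert abs(emp - s) < 3 * se

    def test_marginal_prevalences_near_calibrated_targets(self, shape_spec, outcome_spec):
        _, cohort, _ = sample_cohort(shape_spec, outcome_spec, n=50000, seed=4)
        df = cohort.df
        for col, target in (("moderate", 0.057), ("severe", 0.017)):
            p = (df["latent_class"] == col).mean()
            se = np.sqrt(target * (1 - target) / len(df))
            assert abs(p - target) < 3 * se, (col, p)
        for col, target in (("hoa_hospital", 0.013), ("thr_event", 0.006)):
            p = df[col].mean()
            se = np.sqrt(target * (1 - target) / len(df))
            assert abs(p - target) < 3 * se, (col, p)

    def test_covariate_margins(self, shape_spec, outcome_spec):
        _, cohort, _ = sample_cohort(shape_spec, outcome_spec, n=20000, seed=5)
        df = cohort.df
        spec = CovariateSpec()
        assert df["age"].mean() == pytest.approx(spec.age_mean, abs=0.2)
        assert (df["sex"] == "M").mean() == pytest.approx(spec.p_male, abs=0.02)
        assert df["ethnicity_white"].mean() == pytest.approx(spec.p_white, abs=0.01)

    def test_n_below_one_rejected(self, shape_spec, outcome_spec):
        with pytest.raises(ValueError):
            sample_cohort(shape_spec, outcome_spec, n=0, seed=1)


class TestNullEffects:
    def test_null_mode_or_cis_cover_one(self, shape_spec):
        """With all shape effects zeroed, per-mode OR CIs should cover 1."""
        from hipshape.association import fit_logistic_per_hsm
        null = OutcomeModelSpec.default()
        for out in (null.moderate, null.severe, null.hospital, null.thr):
            out.gamma = {}
            out.gamma_aa = 0.0
            out.gamma_lcea = 0.0
        _, cohort, scores = sample_cohort(shape_spec, null, n=20000, seed=6)
        import pandas as pd
        z = pd.DataFrame({name: scores[f"{name}_std"] for name in MODE_NAMES})
        res = fit_logistic_per_hsm(z, cohort.df["hoa_hospital"])
        covered = sum(r.ci_low <= 1.0 <= r.ci_high for r in res)
        assert covered >= 3  # >= 3 of 4 modes at the 95% level


class TestMeasurementHinge:
    """Injected geometry-mode scores must drive the measured angles."""

    def test_cam_score_correlates_with_alpha_angle(self, shape_spec, outcome_spec):
        configs, _, scores = sample_cohort(shape_spec, outcome_spec, n=1500, seed=7)
        meas = measure_cohort(configs)
        rho = spearmanr(scores["cam_bump_std"], meas["alpha_angle"],
                        nan_policy="omit").statistic
        assert rho > 0.5

    def test_coverage_score_correlates_with_lcea(self, shape_spec, outcome_spec):
        configs, _, scores = sample_cohort(shape_spec, outcome_spec, n=1500, seed=7)
        meas = measure_cohort(configs)
        rho = spearmanr(scores["acetabular_coverage_std"], meas["lcea"]).statistic
        assert rho > 0.5

    def test_larger_cam_sd_raises_mean_alpha_angle(self, outcome_spec):
        """Cohorts generated with a larger cam-score SD show a higher mean AA
        (the male/female AA contrast the generator can emulate)."""
        lo = GenerativeShapeSpec.default(score_sd=(1.5, 2.5, 2.0, 1.5))
        hi = GenerativeShapeSpec.default(score_sd=(4.5, 2.5, 2.0, 1.5))
        aa = {}
        for name, spec in (("lo", lo), ("hi", hi)):
            configs, _, _ = sample_cohort(spec, outcome_spec, n=800, seed=8)
            aa[name] = np.nanmean(measure_cohort(configs)["alpha_angle"])
        assert aa["hi"] > aa["lo"]
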