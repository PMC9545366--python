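"""Generalized Procrustes alignment and the PCA shape model."""

import numpy as np
import pytest

from hipshape.schema import LandmarkConfiguration
from hipshape.simulate import GenerativeShapeSpec, OutcomeModelSpec, sample_cohort
from hipshape.ssm import (ShapeModel, ShapeModelError, fit_pca, fit_shape_model,
                          generalized_procrustes, standardize)

from conftest import deformed_configs


def _rigid(points, angle, shift, scale=1.0):
    R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
    return scale * points @ R.T + np.asarray(shift)


def _two_shape_procrustes_mean(A, B):
    """Closed-form full-Procrustes mean of two shapes (complex formulation)."""
    def norm(P):
        z = (P[:, 0] + 1j * P[:, 1])
        z = z - z.mean()
        return z / np.sqrt((np.abs(z) ** 2).sum())
    za, zb = norm(A), norm(B)
    w = np.vdot(za, zb)  # optimal rotation+scale of zb onto za
    zb_al = zb * np.conj(w) / abs(w)
    m = (za + zb_al) / 2
    m = m - m.mean()
    m = m / np.sqrt((np.abs(m) ** 2).sum())
    return np.column_stack([m.real, m.imag])


def _full_procrustes_distance(A, B):
    """Residual after optimally aligning B to A (both unit-size, centred)."""
    za = (A[:, 0] + 1j * A[:, 1])
    zb = (B[:, 0] + 1j * B[:, 1])
    za, zb = za - za.mean(), zb - zb.mean()
    za = za / np.sqrt((np.abs(za) ** 2).sum())
    zb = zb / np.sqrt((np.abs(zb) ** 2).sum())
    w = np.vdot(zb, za)
    return float(np.sqrt(np.sum(np.abs(za - w / abs(w) * zb) ** 2)))


class TestGPA:
    def test_rigid_copies_align_exactly(self, template):
        rng = np.random.default_rng(0)
        configs = [LandmarkConfiguration(
            f"r{i}", _rigid(template.points, rng.uniform(0, 2 * np.pi),
                            rng.uniform(-50, 50, 2), rng.uniform(0.5, 2.0)))
            for i in range(6)]
        aligned, mean = generalized_procrustes(configs, allow_scaling=True)
        for a in aligned:
            np.testing.assert_allclose(a, mean, atol=1e-9)
        model = fit_pca(aligned)
        assert model.n_modes == 0  # no effective shape variation

    def test_mean_centred_and_unit_size(self, small_cohort):
        configs = small_cohort[0][:50]
        _, mean = generalized_procrustes(configs)
        np.testing.assert_allclose(mean.mean(axis=0), 0.0, atol=1e-12)
        assert np.sqrt((mean ** 2).sum()) == pytest.approx(1.0, abs=1e-12)

    def test_model_invariant_to_rigid_motion_of_inputs(self, small_cohort):
        configs = small_cohort[0][:80]
        rng = np.random.default_rng(1)
        moved = [LandmarkConfiguration(
            c.subject_id, _rigid(c.points, rng.uniform(0, 2 * np.pi),
                                 rng.uniform(-30, 30, 2)))
            for c in configs]
        m1 = fit_shape_model(configs)
        m2 = fit_shape_model(moved)
        k = 4
        # principal angles between the top-k mode subspaces
        sv = np.linalg.svd(m1.modes[:, :k].T @ m2.modes[:, :k], compute_uv=False)
        assert np.max(np.arccos(np.clip(sv, 0, 1))) < 1e-6

    def test_model_invariant_to_input_ordering(self, small_cohort):
        configs = small_cohort[0][:60]
        m1 = fit_shape_model(configs)
        m2 = fit_shape_model(configs[::-1])
        np.testing.assert_allclose(m1.mean_shape, m2.mean_shape, atol=1e-9)
        np.testing.assert_allclose(np.abs(m1.modes[:, :4]), np.abs(m2.modes[:, :4]),
                                   atol=1e-6)

    def test_two_triangles_match_closed_form_mean(self):
        A = np.array([[0.0, 0.0], [4.0, 0.0], [1.0, 3.0]])
        B = np.array([[0.0, 0.0], [5.0, 1.0], [0.5, 2.0]])
        configs = [LandmarkConfiguration("a", A), LandmarkConfiguration("b", B)]
        _, mean = generalized_procrustes(configs, allow_scaling=True)
        oracle = _two_shape_procrustes_mean(A, B)
        assert _full_procrustes_distance(oracle, mean) < 1e-8

    def test_fewer_than_two_configs_rejected(self, template):
        with pytest.raises(ShapeModelError):
            generalized_procrustes([template])


class TestPCA:
    def test_subspace_and_sd_recovery(self, noise_free_spec):
        """PCA on a noise-free 3-mode cohort recovers the generating fields."""
        spec3 = GenerativeShapeSpec(
            template=noise_free_spec.template,
            modes=np.asarray(noise_free_spec.modes)[:3],
            score_sd=np.asarray(noise_free_spec.score_sd)[:3],
            mode_names=noise_free_spec.mode_names[:3],
            point_noise_sd=0.0,
        )
        rng = np.random.default_rng(2)
        z = rng.standard_normal((2000, 3)) * spec3.score_sd
        configs = deformed_configs(spec3, z)
        model = fit_shape_model(configs)
        # generating fields mapped into the aligned frame
        from hipshape.ssm import _align_one
        tmpl = spec3.template.points
        tc = tmpl - tmpl.mean(axis=0)
        size = np.sqrt((tc ** 2).sum())
        A = _align_one(tmpl, model.mean_shape, True)
        R, *_ = np.linalg.lstsq(tc / size, A, rcond=None)
        F = np.stack([f @ R for f in np.asarray(spec3.modes)]).reshape(3, -1).T
        Q1, _ = np.linalg.qr(F)
        sv = np.linalg.svd(Q1.T @ model.modes[:, :3], compute_uv=False)
        assert np.max(np.arccos(np.clip(sv, 0, 1))) < 0.05
        # raw score SDs scale with 1/centroid-size of the template
        expected = np.sort(spec3.score_sd / size)[::-1]
        np.testing.assert_allclose(np.sort(model.raw_sd[:3])[::-1], expected,
                                   rtol=0.05)

    def test_var_frac_sums_to_one_and_matches_raw_sd(self, small_cohort):
        model = fit_shape_model(small_cohort[0][:100])
        assert model.var_frac.sum() == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(model.var_frac,
                                   model.raw_sd ** 2 / (model.raw_sd ** 2).sum(),
                                   atol=1e-12)
        assert np.all(np.diff(model.var_frac) <= 1e-12)

    def test_cumulative_top10_variance_reported(self, small_cohort):
        model = fit_shape_model(small_cohort[0][:100])
        v10 = model.cumulative_variance(10)
        assert 0.0 < v10 <= 1.0
        assert v10 >= model.cumulative_variance(5)

    def test_single_config_rejected(self, template):
        with pytest.raises(ShapeModelError):
            fit_pca(template.points[None])


class TestScoring:
    @pytest.fixture(scope="class")
    def model_and_configs(self, small_cohort):
        configs = small_cohort[0][:150]
        return fit_shape_model(configs), configs

    def test_score_of_mean_shape_is_zero(self, model_and_configs):
        model, _ = model_and_configs
        mean_cfg = LandmarkConfiguration("mean", model.mean_shape)
        np.testing.assert_allclose(model.score_raw(mean_cfg, assume_aligned=True),
                                   0.0, atol=1e-12)
        # re-aligning the mean to itself perturbs scores only marginally
        # (the coordinate mean is of unit centroid size only to ~1e-4, so
        # re-scaling leaks a fraction of a percent of one mode SD)
        np.testing.assert_allclose(model.score_raw(mean_cfg), 0.0, atol=1e-4)

    def test_training_scores_standardized(self, model_and_configs):
        model, configs = model_and_configs
        z = model.transform(configs).drop(columns="subject_id").to_numpy()
        assert np.max(np.abs(z.mean(axis=0))) < 1e-8
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-8)

    def test_full_reconstruction_lossless(self, model_and_configs):
        model, configs = model_and_configs
        for cfg in configs[:5]:
            aligned = model.align(cfg)
            rec = model.reconstruct(model.score_raw(cfg))
            np.testing.assert_allclose(rec.points, aligned, atol=1e-8)

    def test_score_reconstruct_round_trip(self, model_and_configs):
        model, _ = model_and_configs
        rng = np.random.default_rng(3)
        z = rng.standard_normal(model.n_modes) * model.raw_sd
        rec = model.reconstruct(z)
        np.testing.assert_allclose(model.score_raw(rec, assume_aligned=True), z,
                                   atol=1e-12)

    def test_truncated_reconstruction_error_monotone(self, model_and_configs):
        model, configs = model_and_configs
        cfg = configs[7]
        aligned = model.align(cfg)
        z = model.score_raw(cfg)
        errs = []
        for k in range(0, model.n_modes + 1, 10):
            rec = (model.reconstruct(z[:k]) if k
                   else LandmarkConfiguration("m", model.mean_shape))
            errs.append(np.linalg.norm(rec.points - aligned))
        assert np.all(np.diff(errs) <= 1e-12)

    def test_zero_scores_give_mean_shape(self, model_and_configs):
        model, _ = model_and_configs
        rec = model.reconstruct(np.zeros(model.n_modes))
        np.testing.assert_allclose(rec.points, model.mean_shape, atol=1e-15)

    def test_too_many_modes_rejected(self, model_and_configs):
        model, _ = model_and_configs
        with pytest.raises(ShapeModelError):
            model.reconstruct(np.zeros(model.n_modes), n_modes=model.n_modes + 1)

    def test_json_round_trip(self, model_and_configs, tmp_path):
        model, configs = model_and_configs
        p = tmp_path / "model.json"
        model.to_json(p)
        back = ShapeModel.from_json(p)
        np.testing.assert_allclose(back.modes, model.modes)
        np.testing.assert_allclose(back.score(configs[0]), model.score(configs[0]))

    def test_standardize_helper(self):
        rng = np.random.default_rng(4)
        raw = rng.normal(5.0, 2.0, size=(500, 3))
        z = standardize(raw)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-12)
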