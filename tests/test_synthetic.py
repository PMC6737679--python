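"""Phantom generator and cohort sampler."""

import numpy as np
import pandas as pd
import pytest

from breastdeform import CohortConfig, PhantomSpec, generate_phantom, nearest_psd, sample_cohort
from breastdeform.stats import COHORT_COLUMNS, _parse_repeats
from breastdeform.synthetic import LATENT_VARS


class TestPhantom:
    def test_zero_density_gives_pure_fat(self):
        spec = PhantomSpec(grid_shape=(40, 32, 40), voxel_size_mm=2.5,
                           breast_semiaxes_mm=(35, 40, 35), chest_slab_mm=10,
                           target_percent_density=0.0, bias_amplitude=0.0,
                           noise_sd=0.0)
        ph = generate_phantom(spec)
        assert not ph.fgt_mask.any()
        assert np.allclose(ph.image.data[ph.breast_mask], spec.fat_intensity)

    @pytest.mark.parametrize("target", [13.1, 30.0, 50.0])
    def test_density_within_one_point_of_target(self, target):
        spec = PhantomSpec(grid_shape=(48, 40, 48), voxel_size_mm=2.5,
                           breast_semiaxes_mm=(45, 50, 45), chest_slab_mm=15,
                           target_percent_density=target, noise_sd=0.0,
                           bias_amplitude=0.0)
        ph = generate_phantom(spec)
        got = 100.0 * ph.fgt_mask.sum() / ph.breast_mask.sum()
        assert abs(got - target) <= 1.0

    def test_seeded_determinism(self, phantom_spec):
        a = generate_phantom(phantom_spec)
        b = generate_phantom(phantom_spec)
        assert np.array_equal(a.image.data, b.image.data)
        assert np.array_equal(a.fgt_mask, b.fgt_mask)
        c = generate_phantom(PhantomSpec(**{**phantom_spec.__dict__, "seed": 99}))
        assert not np.array_equal(a.image.data, c.image.data)

    def test_breast_volume_matches_analytic_hemiellipsoid(self):
        # >= 64^3-equivalent resolution: 1.5 mm voxels on a 45/50/45 breast
        spec = PhantomSpec(grid_shape=(80, 64, 80), voxel_size_mm=1.5,
                           breast_semiaxes_mm=(45, 50, 45), chest_slab_mm=12)
        ph = generate_phantom(spec)
        a, b, c = spec.breast_semiaxes_mm
        analytic = (2.0 / 3.0) * np.pi * a * b * c
        measured = ph.breast_mask.sum() * ph.image.voxel_volume_mm3
        assert abs(measured - analytic) / analytic < 0.02

    def test_unreachable_density_names_achievable_range(self):
        spec = PhantomSpec(grid_shape=(40, 32, 40), voxel_size_mm=2.5,
                           breast_semiaxes_mm=(35, 40, 35), chest_slab_mm=10,
                           target_percent_density=99.0)
        with pytest.raises(ValueError, match="achievable"):
            generate_phantom(spec)

    def test_nipple_is_anterior_surface_point(self, phantom):
        nip = phantom.nipple_location_mm
        # anterior-most breast voxel overall is on the nipple line
        ys = phantom.image.index_to_world(np.argwhere(phantom.breast_mask))[:, 1]
        assert nip[1] == pytest.approx(ys.max(), abs=phantom.image.spacing[1])

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(target_percent_density=120.0)
        with pytest.raises(ValueError):
            PhantomSpec(noise_sd=-1.0)
        with pytest.raises(ValueError):
            PhantomSpec(breast_semiaxes_mm=(0.0, 10.0, 10.0))


class TestNearestPsd:
    def test_identity_and_psd_inputs_unchanged(self):
        assert np.allclose(nearest_psd(np.eye(3)), np.eye(3))
        m = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert np.allclose(nearest_psd(m), m)

    def test_indefinite_matrix_projected(self):
        m = np.array([[1.0, 0.9, 0.9],
                      [0.9, 1.0, -0.9],
                      [0.9, -0.9, 1.0]])
        out = nearest_psd(m)
        w = np.linalg.eigvalsh(out)
        assert w.min() >= -1e-12
        assert np.allclose(np.diag(out), 1.0)
        # eigen-decomposition oracle: clipping the negative eigenvalue and
        # rescaling reproduces the projection
        w0, v0 = np.linalg.eigh(m)
        clipped = (v0 * np.clip(w0, 1e-8, None)) @ v0.T
        d = np.sqrt(np.diag(clipped))
        expected = clipped / np.outer(d, d)
        np.fill_diagonal(expected, 1.0)
        assert np.allclose(out, expected)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            nearest_psd(np.array([[1.0, 0.2], [0.3, 1.0]]))


class TestCohort:
    def test_empty_cohort_has_full_schema(self):
        df = sample_cohort(CohortConfig(n_subjects=0))
        assert list(df.columns) == COHORT_COLUMNS
        assert len(df) == 0

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_subjects=-1)
        with pytest.raises(ValueError):
            CohortConfig(stiffness_sd=-0.1)
        with pytest.raises(ValueError):
            CohortConfig(n_repeats_range=(1, 5))

    def test_default_correlation_matrix_is_pd(self):
        R = CohortConfig().correlation_matrix()
        assert np.linalg.eigvalsh(R).min() > 0
        assert np.allclose(R, R.T)
        idx = {v: i for i, v in enumerate(LATENT_VARS)}
        assert R[idx["age"], idx["whole_percent_density"]] == pytest.approx(-0.56)
        assert R[idx["age"], idx["stiffness"]] == pytest.approx(0.29)

    def test_record_invariants(self, default_cohort):
        df = default_cohort
        assert (df["fgt_volume"] <= df["breast_volume"] + 1e-9).all()
        implied = 100.0 * df["fgt_volume"] / df["breast_volume"]
        assert np.allclose(implied, df["whole_percent_density"], atol=1e-9)
        assert (df["stiffness"] > 0).all()
        for reps in df["stiffness_repeats"].head(200):
            r = _parse_repeats(reps)
            assert 3 <= len(r) <= 5 and (r > 0).all()

    def test_moment_recovery_at_large_n(self, default_cohort):
        """Sample means land within 3 standard errors of the configuration.

        Pooled over three seeds (n = 15000) so a single unlucky draw on
        one marginal cannot trip a sound generator.
        """
        cfg = CohortConfig()
        pooled = pd.concat([default_cohort] + [
            sample_cohort(CohortConfig(n_subjects=5000, seed=s)) for s in (2, 3)
        ], ignore_index=True)
        n = len(pooled)
        checks = [
            ("stiffness", cfg.stiffness_mean, cfg.stiffness_sd),
            ("breast_volume", cfg.breast_volume_mean, cfg.breast_volume_sd),
            ("whole_percent_density", cfg.whole_density_mean, cfg.whole_density_sd),
            ("age", cfg.age_mean, cfg.age_sd),
            ("roi_depth", cfg.roi_depth_mean, cfg.roi_depth_sd),
        ]
        for col, mean, sd in checks:
            assert abs(pooled[col].mean() - mean) < 3.0 * sd / np.sqrt(n), col
        assert abs(default_cohort["stiffness"].mean() - cfg.stiffness_mean) < 0.05

    def test_sample_correlations_match_configuration(self, default_cohort):
        cfg = CohortConfig()
        R = cfg.correlation_matrix()
        cols = ["age", "breast_volume", "whole_percent_density",
                "local_percent_density", "stiffness"]
        sample = np.corrcoef(default_cohort[cols].to_numpy().T)
        assert np.abs(sample - R).max() < 0.04

    def test_identity_correlations_yield_null_sample(self):
        corr = {(a, b): 0.0 for i, a in enumerate(LATENT_VARS)
                for b in LATENT_VARS[i + 1:]}
        df = sample_cohort(CohortConfig(n_subjects=5000, seed=7, correlations=corr))
        cols = ["age", "breast_volume", "whole_percent_density",
                "local_percent_density", "stiffness"]
        sample = np.corrcoef(df[cols].to_numpy().T)
        off = sample[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_seeded_determinism(self):
        a = sample_cohort(CohortConfig(n_subjects=50, seed=11))
        b = sample_cohort(CohortConfig(n_subjects=50, seed=11))
        c = sample_cohort(CohortConfig(n_subjects=50, seed=12))
        pd.testing.assert_frame_equal(a, b)
        assert not a["stiffness"].equals(c["stiffness"])
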