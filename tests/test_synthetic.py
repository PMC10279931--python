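"""Synthetic generator: spatial covariance, temporal decorrelation, rendering, cohorts."""

import numpy as np
import pytest

from tmflow import synthetic as syn
from tmflow.pipeline import analyse_eye, analyse_profile
from tmflow.synthetic import _circulant_eigenvalues, _sample_many


class TestSampleField:
    def test_same_seed_is_bit_identical(self):
        m = syn.FieldModel()
        a = syn.sample_segmental_field(9540.0, m, 42)
        b = syn.sample_segmental_field(9540.0, m, 42)
        assert np.array_equal(a.values, b.values)
        c = syn.sample_segmental_field(9540.0, m, 43)
        assert not np.array_equal(a.values, c.values)

    def test_zero_marginal_sd_gives_zero_field(self):
        m = syn.FieldModel(marginal_sd=0.0)
        f = syn.sample_segmental_field(9540.0, m, 0)
        assert np.all(f.values == 0.0)

    def test_rejects_correlation_length_over_half_circumference(self):
        m = syn.FieldModel(correlation_length_um=5000.0)
        with pytest.raises(ValueError, match="near-constant"):
            syn.sample_segmental_field(9540.0, m, 0)

    def test_rejects_too_coarse_grid(self):
        m = syn.FieldModel(correlation_length_um=300.0)
        with pytest.raises(ValueError, match="spacing"):
            syn.sample_segmental_field(9540.0, m, 0, n_samples=20)

    def test_lag_covariance_matches_squared_exponential(self, rng):
        """Monte-Carlo lag covariance at d = l vs the closed form sd^2*exp(-1/2).

        10,000 fields at l = 500 um on a 9.5 mm circumference; grid spacing
        100 um puts d = 500 um exactly at lag 5.
        """
        n, circ, ell = 95, 9500.0, 500.0
        lam = _circulant_eigenvalues(n, circ, ell, 1.0)
        X = _sample_many(rng, lam, 10_000)
        prods = X * np.roll(X, 5, axis=1)  # per-draw, all positions
        per_draw = prods.mean(axis=1)
        est, sem = per_draw.mean(), per_draw.std(ddof=1) / np.sqrt(per_draw.size)
        assert abs(est - np.exp(-0.5)) < 3 * sem

    def test_marginal_variance_is_unit(self, rng):
        lam = _circulant_eigenvalues(96, 9540.0, 300.0, 1.0)
        X = _sample_many(rng, lam, 20_000)
        assert abs(X.var() - 1.0) < 0.03


class TestEvolveField:
    def test_dt_zero_returns_identical_field(self):
        m = syn.FieldModel()
        f = syn.sample_segmental_field(9540.0, m, 1)
        f2 = syn.evolve_field(f, 0.0, 5.0, 99, model=m)
        assert np.array_equal(f.values, f2.values)

    def test_half_life_definition(self):
        assert syn.decorrelation_rho(5.0, 5.0) == pytest.approx(0.5, abs=1e-15)
        assert syn.decorrelation_rho(14.0, 5.0) == pytest.approx(
            np.exp(-14 * np.log(2) / 5), abs=1e-15
        )

    def test_negative_dt_rejected(self):
        m = syn.FieldModel()
        f = syn.sample_segmental_field(9540.0, m, 1)
        with pytest.raises(ValueError):
            syn.evolve_field(f, -1.0, 5.0, 0, model=m)

    def test_empirical_correlation_at_ten_thousand_points(self):
        """corr(f1, f2) -> exp(-ln2*dt/tau) on a dense, short-range grid.

        A 5 um correlation length on the full circumference gives ~1000
        effectively independent patches per field; averaging the per-pair
        correlation over 20 pairs brings the Monte-Carlo error well inside
        the +/-0.03 band around the closed form.
        """
        m = syn.FieldModel(correlation_length_um=5.0)
        target = np.exp(-14 * np.log(2) / 5.0)  # ~0.1437
        rs = []
        for k in range(20):
            f1 = syn.sample_segmental_field(9540.0, m, 500 + k, n_samples=10_000)
            f2 = syn.evolve_field(f1, 14.0, 5.0, 900 + k, model=m)
            rs.append(np.corrcoef(f1.values, f2.values)[0, 1])
        assert abs(np.mean(rs) - target) < 0.03

    def test_stationarity_variance_preserved(self):
        """The sqrt(1-rho^2) innovation weight keeps the marginal variance."""
        m = syn.FieldModel()
        v1, v2 = [], []
        for k in range(400):
            f1 = syn.sample_segmental_field(9540.0, m, 2_000 + k)
            f2 = syn.evolve_field(f1, 3.0, 5.0, 7_000 + k, model=m)
            v1.append(f1.values.var())
            v2.append(f2.values.var())
        assert np.mean(v2) == pytest.approx(np.mean(v1), rel=0.05)


class TestRender:
    def test_constant_field_noiseless_band_levels(self, small_geometry):
        m = syn.FieldModel(marginal_sd=0.0, noise_sd=0.0, channel_gain_ratio=0.6)
        f = syn.sample_segmental_field(small_geometry, m, 0)
        img = syn.render_flat_mount(f, f, small_geometry, m, 0)
        from tmflow.synthetic import _band_and_angle

        band, _ = _band_and_angle(small_geometry)
        assert np.allclose(img.red[band], m.baseline_intensity)
        assert np.allclose(img.blue[band], m.baseline_intensity * 0.6)
        # background far from band and puncture marker
        assert img.red[10, 10] == small_geometry.background_level

    def test_band_outside_image_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            syn.FlatMountGeometry(image_size_px=(500, 500), band_mean_radius_px=260.0)

    def test_gain_ratio_two_gives_scaling_factor_half(self, small_geometry):
        """With blue exactly twice red, the least-squares factor is 1/2."""
        geo = syn.FlatMountGeometry(
            image_size_px=small_geometry.image_size_px,
            band_mean_radius_px=small_geometry.band_mean_radius_px,
            background_level=0.0,
        )
        m = syn.FieldModel(noise_sd=0.0, channel_gain_ratio=2.0)
        f = syn.sample_segmental_field(geo, m, 5)
        img = syn.render_flat_mount(f, f, geo, m, 5)
        polys, lines, bg = syn.annotate_geometry(geo)
        res = analyse_eye(img, polys, lines, bg)
        assert res.profile.scaling_factor_applied == pytest.approx(0.5, abs=1e-9)
        assert res.correlation.r == pytest.approx(1.0, abs=1e-9)


class TestCohort:
    def _design(self, groups, seed=0, **model_kw):
        return syn.CohortDesign(
            groups=groups, seed=seed, model=syn.FieldModel(**model_kw), geometry=None
        )

    def test_three_eyes_distinct_subseeds(self):
        d = self._design((syn.CohortGroup("g", 2.0, 3),))
        records, table = syn.generate_cohort(d)
        assert len(records) == 3
        assert table["eye_id"].nunique() == 3
        assert table["seed"].nunique() == 3

    def test_determinism(self):
        d = self._design((syn.CohortGroup("g", 7.0, 2),), seed=11)
        r1, t1 = syn.generate_cohort(d)
        r2, t2 = syn.generate_cohort(d)
        assert t1.equals(t2)
        assert np.array_equal(r1[0].profile.red_mean, r2[0].profile.red_mean)

    def test_dt_zero_noiseless_gives_unit_correlation(self):
        d = self._design((syn.CohortGroup("dt0", 0.0, 2),), noise_sd=0.0)
        records, _ = syn.generate_cohort(d)
        for rec in records:
            res = analyse_profile(rec.profile, side=rec.side, delta_t_days=0.0)
            assert res.correlation.r == pytest.approx(1.0, abs=1e-12)

    def test_group_mean_correlation_tracks_decay_law(self):
        """tau = 5 d at dt = 14 d: mean per-eye r near exp(-14 ln2/5) = 0.144.

        Short-range fields (l = 50 um) binned at 50 um give ~100 effective
        samples per eye, so the 20-eye mean has a standard error of ~0.02;
        the +/-0.05 check is then a comfortable 2.4-sigma band.
        """
        d = syn.CohortDesign(
            groups=(syn.CohortGroup("dt14", 14.0, 20),),
            seed=0,
            model=syn.FieldModel(correlation_length_um=50.0, half_life_days=5.0),
            geometry=None,
            target_bin_width_um=50.0,
        )
        records, _ = syn.generate_cohort(d)
        rs = [
            analyse_profile(rec.profile, delta_t_days=14.0).correlation.r
            for rec in records
        ]
        assert np.mean(rs) == pytest.approx(np.exp(-14 * np.log(2) / 5), abs=0.05)

    def test_duplicate_group_labels_rejected(self):
        d = self._design((syn.CohortGroup("g", 0.0, 2), syn.CohortGroup("g", 2.0, 2)))
        with pytest.raises(ValueError, match="duplicate"):
            syn.generate_cohort(d)
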