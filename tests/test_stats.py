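"""Per-eye correlations, decay fitting, t-tests and difference images."""

import numpy as np
import pytest

from tmflow import stats as ts
from tmflow import synthetic as syn
from tmflow.profile import TracerProfile
from tmflow.straighten import StraightenedTM

LN2 = np.log(2.0)


def _profile(red, blue):
    n = len(red)
    return TracerProfile(
        red_mean=np.asarray(red, float),
        blue_mean=np.asarray(blue, float),
        centre_um=np.arange(n) + 0.5,
        valid_fraction=np.ones(n),
        circumference_um=float(n),
    )


class TestPearson:
    def test_identical_channels(self):
        c = ts.pearson_r(_profile([1, 2, 3, 4], [1, 2, 3, 4]))
        assert c.r == pytest.approx(1.0)
        assert c.slope == pytest.approx(1.0)
        assert c.intercept == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_channels(self):
        c = ts.pearson_r(_profile([1, 2, 3, 4], [9, 8, 7, 6]))
        assert c.r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # r = cov/(sx*sy) = 1.0/1.25 = 0.8 for these four bins
        c = ts.pearson_r(_profile([1, 2, 3, 4], [1, 3, 2, 4]))
        assert c.r == pytest.approx(0.8, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            ts.pearson_r(_profile([1, 2, 3], [5, 5, 5]))

    def test_too_few_valid_bins_rejected(self):
        p = _profile([1, 2, np.nan, np.nan], [1, 2, 3, 4])
        with pytest.raises(ValueError, match="valid bins"):
            ts.pearson_r(p)


class TestPooled:
    def test_single_eye_equals_per_eye(self):
        p = _profile([1, 2, 3, 5], [2, 3, 5, 6])
        assert ts.pooled_r([p]).r == pytest.approx(ts.pearson_r(p).r)

    def test_identical_eyes_preserve_r(self):
        p = _profile([1, 2, 3, 5], [2, 3, 5, 6])
        assert ts.pooled_r([p, p]).r == pytest.approx(ts.pearson_r(p).r)

    def test_pooling_mixes_between_eye_means(self):
        """Two eyes with per-eye r = 1 but opposite channel offsets: the
        pooled r over concatenated bins differs from 1 (direct oracle)."""
        a = _profile([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        b = _profile([11.0, 12.0, 13.0], [1.0, 2.0, 3.0])
        expect = np.corrcoef(
            np.concatenate([a.blue_mean, b.blue_mean]),
            np.concatenate([a.red_mean, b.red_mean]),
        )[0, 1]
        pooled = ts.pooled_r([a, b]).r
        assert pooled == pytest.approx(expect, abs=1e-12)
        assert pooled < 0.99


class TestDecayFit:
    def test_exact_recovery_from_noiseless_points(self):
        dt = np.array([0.0, 2.0, 7.0, 14.0])
        r = np.exp(-LN2 * dt / 5.0)
        res = ts.ExponentialDecayModel(dt, r).fit(n_boot=0)
        assert res.half_life_days == pytest.approx(5.0, rel=1e-6)
        assert res.rate_per_day * res.half_life_days == pytest.approx(LN2, rel=1e-12)

    def test_group_means_within_published_interval(self):
        """Fitting the four per-interval mean correlations lands inside the
        95% CI of the cohort-level half-life, [3.5, 7.4] days."""
        res = ts.ExponentialDecayModel([0, 2, 7, 14], [0.95, 0.66, 0.55, 0.05]).fit(n_boot=0)
        assert 3.5 <= res.half_life_days <= 7.4

    def test_free_amplitude_form(self):
        dt = np.array([0.0, 2.0, 7.0, 14.0])
        r = 0.9 * np.exp(-LN2 * dt / 5.0)
        res = ts.ExponentialDecayModel(dt, r, model_form="free").fit(n_boot=0)
        assert res.half_life_days == pytest.approx(5.0, rel=1e-6)
        assert res.amplitude == pytest.approx(0.9, rel=1e-6)

    def test_identical_dt_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            ts.ExponentialDecayModel([7, 7, 7, 7], [0.5, 0.6, 0.4, 0.5])

    def test_bootstrap_is_seeded_and_point_estimate_stable(self):
        rng = np.random.default_rng(3)
        dt = np.repeat([0, 2, 7, 14], 5).astype(float)
        r = np.exp(-LN2 * dt / 5.0) + rng.normal(0, 0.1, dt.size)
        m = ts.ExponentialDecayModel(dt, r)
        a = m.fit(n_boot=200, seed=7)
        b = m.fit(n_boot=200, seed=7)
        c = m.fit(n_boot=200, seed=8)
        assert a.conf_int_days == b.conf_int_days
        assert a.conf_int_days != c.conf_int_days
        assert a.half_life_days == c.half_life_days  # seed only moves the CI
        assert a.conf_int_days[0] <= a.half_life_days <= a.conf_int_days[1]

    def test_wrapper_requires_four_eyes(self):
        eyes = [
            ts.EyeCorrelation("e", 0.8, 1, 0, (0, 2), (-1, 1), 10, delta_t_days=d)
            for d in (0.0, 2.0)
        ]
        with pytest.raises(ValueError, match="4 eyes"):
            ts.fit_exponential_decay(eyes)

    def test_summary_mentions_half_life(self):
        res = ts.ExponentialDecayModel([0, 2, 7, 14], [0.95, 0.66, 0.55, 0.05]).fit(
            n_boot=50, seed=0
        )
        s = res.summary()
        assert "half-life" in s and "95% CI" in s


class TestTTests:
    def test_one_sample_all_zero(self):
        res = ts.one_sample_t([0.0, 0.0, 0.0])
        assert res.t == 0.0 and res.p == 1.0 and res.zero_variance

    def test_one_sample_constant_nonzero(self):
        res = ts.one_sample_t([1.0, 1.0, 1.0])
        assert np.isinf(res.t) and res.p == 0.0 and res.zero_variance

    def test_one_sample_textbook_formula(self):
        x = np.array([0.2, -0.1, 0.05, 0.1, -0.05, 0.1])
        res = ts.one_sample_t(x)
        t_manual = x.mean() / (x.std(ddof=1) / np.sqrt(x.size))
        from scipy.stats import t as tdist

        p_manual = 2 * tdist.sf(abs(t_manual), x.size - 1)
        assert res.t == pytest.approx(t_manual, rel=1e-12)
        assert res.p == pytest.approx(p_manual, rel=1e-12)
        assert res.df == 5

    def test_two_sample_identical_groups(self):
        res = ts.two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0) and res.p == pytest.approx(1.0)

    def test_two_sample_zero_variance_distinct(self):
        res = ts.two_sample_t([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        assert np.isinf(res.t) and res.p == 0.0 and res.zero_variance

    def test_age_comparison_power(self):
        """Young (tau = 5 d) vs old (tau ~ 21.7 d) cohorts at dt = 14 d,
        6 eyes each: the two-sample test rejects in > 80% of replicates."""
        tau_old = ts.half_life_from_single_r(0.64, 14.0)
        model = syn.FieldModel()
        lam = syn._circulant_eigenvalues(159, 9540.0, 300.0, 1.0)
        rng = np.random.default_rng(12)
        n_rep, n_eyes = 200, 6
        rejections = 0
        rho_y = syn.decorrelation_rho(14.0, 5.0)
        rho_o = syn.decorrelation_rho(14.0, tau_old)
        for _ in range(n_rep):
            rs = {}
            for label, rho in (("young", rho_y), ("old", rho_o)):
                f1 = syn._sample_many(rng, lam, n_eyes)
                eps = syn._sample_many(rng, lam, n_eyes)
                f2 = rho * f1 + np.sqrt(1 - rho**2) * eps
                f1c = f1 - f1.mean(axis=1, keepdims=True)
                f2c = f2 - f2.mean(axis=1, keepdims=True)
                rs[label] = np.einsum("ij,ij->i", f1c, f2c) / np.sqrt(
                    np.einsum("ij,ij->i", f1c, f1c) * np.einsum("ij,ij->i", f2c, f2c)
                )
            if ts.two_sample_t(rs["young"], rs["old"]).p < 0.05:
                rejections += 1
        assert rejections / n_rep > 0.8

    def test_fisher_z_switch_changes_statistic_not_sign(self):
        rs = [0.8, 0.7, 0.9, 0.75]
        raw = ts.one_sample_t(rs)
        fz = ts.one_sample_t(rs, fisher_z=True)
        assert raw.t > 0 and fz.t > 0 and raw.t != fz.t


class TestHalfLifeInversion:
    def test_definition(self):
        assert ts.half_life_from_single_r(0.5, 5.0) == pytest.approx(5.0)

    def test_published_old_mouse_value(self):
        # r = 0.64 at dt = 14 d implies tau ~ 21.7 d
        assert ts.half_life_from_single_r(0.64, 14.0) == pytest.approx(21.74, abs=0.01)

    def test_r_near_one_capped(self):
        with pytest.raises(ValueError, match="cap"):
            ts.half_life_from_single_r(0.9999, 1.0, cap_days=100.0)

    def test_invalid_r_rejected(self):
        for bad in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                ts.half_life_from_single_r(bad, 5.0)


class TestDifferenceImage:
    def _tm(self, red, blue):
        return StraightenedTM(
            channels={"red": red, "blue": blue},
            region_boundaries=[],
            pixel_size_um=1.3,
            region_labels=["r0"],
        )

    def test_identical_channels_zero(self):
        a = np.random.default_rng(0).normal(10, 1, (4, 20))
        d = ts.difference_image(self._tm(a, a.copy()))
        assert np.allclose(d, 0.0, atol=1e-12)

    def test_constant_offset_uniform(self):
        a = np.random.default_rng(1).normal(10, 1, (4, 20))
        d = ts.difference_image(self._tm(a, a + 3.0), scale_blue=False)
        assert np.allclose(d, 3.0)
        d2 = ts.difference_image(self._tm(a, a + 3.0), order="red_minus_blue", scale_blue=False)
        assert np.allclose(d2, -3.0)

    def test_redistribution_increases_difference_magnitude(self):
        """A dt = 14 d pair shows a larger mean |difference| than dt = 0."""
        m = syn.FieldModel(noise_sd=0.0)
        f1 = syn.sample_segmental_field(9540.0, m, 21)
        f14 = syn.evolve_field(f1, 14.0, 5.0, 22, model=m)

        def tm_for(fa, fb):
            red = np.tile(100 + 20 * fa.values, (4, 1))
            blue = np.tile(100 + 20 * fb.values, (4, 1))
            return self._tm(red, blue)

        d0 = ts.difference_image(tm_for(f1, f1))
        d14 = ts.difference_image(tm_for(f1, f14))
        assert np.mean(np.abs(d14)) > np.mean(np.abs(d0))

    def test_render_maps_sign_to_colour(self):
        d = np.array([[1.0, -2.0, np.nan]])
        rgb = ts.render_difference(d)
        assert rgb[0, 0, 1] > 0 and rgb[0, 0, 0] == 0  # positive -> green
        assert rgb[0, 1, 0] > 0 and rgb[0, 1, 1] == 0  # negative -> red
        assert np.all(rgb[0, 2] == 0)  # NaN -> black
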