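"""Statistical contracts of the seeded fixture generators."""

import numpy as np
import pytest
from scipy import stats

import promyelin as pm


class TestEisSpectrum:
    def test_zero_noise_equals_forward_model(self):
        f = np.logspace(-1, 4, 30)
        spec = pm.gen_eis_spectrum(pm.REFERENCE_CIRCUIT, f, rel_noise=0.0)
        np.testing.assert_allclose(
            spec.z, pm.z_total(pm.REFERENCE_CIRCUIT, 2 * np.pi * f)
        )

    def test_seed_determinism(self):
        f = np.logspace(-1, 4, 30)
        s1 = pm.gen_eis_spectrum(pm.REFERENCE_CIRCUIT, f, 0.02, seed=9)
        s2 = pm.gen_eis_spectrum(pm.REFERENCE_CIRCUIT, f, 0.02, seed=9)
        np.testing.assert_array_equal(s1.z, s2.z)

    def test_noise_scaling(self):
        """Doubling rel_noise doubles the mean absolute relative residual."""
        f = np.logspace(-1, 4, 200)
        model = pm.z_total(pm.REFERENCE_CIRCUIT, 2 * np.pi * f)

        def mean_resid(noise):
            r = []
            for seed in range(10):
                s = pm.gen_eis_spectrum(pm.REFERENCE_CIRCUIT, f, noise, seed=seed)
                r.append(np.mean(np.abs(s.z - model) / np.abs(model)))
            return np.mean(r)

        ratio = mean_resid(0.02) / mean_resid(0.01)
        assert ratio == pytest.approx(2.0, rel=0.2)

    def test_nonpositive_freq_rejected(self):
        with pytest.raises(ValueError):
            pm.gen_eis_spectrum(pm.REFERENCE_CIRCUIT, [0.0, 1.0])


class TestCorrelatedBinary:
    def test_perfect_correlation_identical_sequences(self):
        a, b = pm.gen_correlated_binary(0.5, 0.5, 1.0, 2000, seed=0)
        np.testing.assert_array_equal(a.states, b.states)

    def test_empirical_and_frequency(self):
        a, b = pm.gen_correlated_binary(0.49, 0.49, -0.27, 10 ** 6, seed=1)
        p11 = np.mean(a.states * b.states)
        assert p11 == pytest.approx(0.172627, abs=3 * np.sqrt(0.1726 * 0.8274 / 1e6))

    def test_empirical_phi_within_3_se(self):
        n = 200000
        a, b = pm.gen_correlated_binary(0.49, 0.49, -0.27, n, seed=2)
        phi = pm.phi_correlation(a, b)
        # sampling error of a correlation coefficient ~ 1/sqrt(n)
        assert abs(phi - (-0.27)) < 3.0 / np.sqrt(n)

    def test_joint_law_chi_square(self):
        """Cell frequencies match the specified 2x2 law (chi-square GOF)."""
        pa, pb, phi, n = 0.49, 0.49, -0.27, 10 ** 6
        a, b = pm.gen_correlated_binary(pa, pb, phi, n, seed=3)
        p11 = pm.expected_joint_and(pa, pb, phi)
        expected = np.array(
            [1 - pa - pb + p11, pb - p11, pa - p11, p11]
        ) * n
        cells = 2 * a.states.astype(int) + b.states.astype(int)
        observed = np.bincount(cells, minlength=4)
        chi2 = float(((observed - expected) ** 2 / expected).sum())
        assert stats.chi2.sf(chi2, df=3) > 0.01

    def test_infeasible_phi_rejected(self):
        with pytest.raises(ValueError):
            pm.gen_correlated_binary(0.9, 0.8, -0.9, 100)


class TestPoissonTrain:
    def test_expected_count(self):
        rate, dur = 0.5, 20000.0
        train = pm.gen_poisson_train(rate, dur, seed=4)
        assert abs(len(train) - rate * dur) < 3 * np.sqrt(rate * dur)

    def test_cv_near_one(self):
        train = pm.gen_poisson_train(1.0, 20000.0, seed=5)
        st = pm.isi_stats(train)
        assert st.cv == pytest.approx(1.0, abs=0.05)

    def test_zero_duration_empty(self):
        assert len(pm.gen_poisson_train(1.0, 0.0, seed=0)) == 0

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            pm.gen_poisson_train(0.0, 10.0)


class TestRegularTrain:
    def test_zero_jitter_zero_cv(self):
        train = pm.gen_regular_train(10.0, 1000.0, jitter_sd=0.0, seed=0)
        assert pm.isi_stats(train).cv == 0.0

    def test_jitter_sets_cv(self):
        """Interval jitter sd of 2.3% of the period gives CV ~= 0.023 —
        the metronomic low-CV regime."""
        period = 50.0
        train = pm.gen_regular_train(period, 200000.0, jitter_sd=0.023 * period,
                                     seed=6)
        assert pm.isi_stats(train).cv == pytest.approx(0.023, rel=0.15)

    def test_events_within_duration(self):
        train = pm.gen_regular_train(7.0, 100.0, jitter_sd=1.0, seed=7)
        assert np.all((train.peak_times >= 0) & (train.peak_times <= 100.0))


class TestDiameters:
    def test_positive_and_deterministic(self):
        d1 = pm.gen_diameters(1000, seed=8)
        d2 = pm.gen_diameters(1000, seed=8)
        assert (d1.diameters > 0).all()
        np.testing.assert_array_equal(d1.diameters, d2.diameters)

    def test_default_moments(self):
        d = pm.gen_diameters(10 ** 4, seed=9)
        assert d.diameters.mean() == pytest.approx(1204.43, rel=0.05)
        assert d.diameters.std() == pytest.approx(1071.74, rel=0.10)

    def test_bimodal_band_masses(self):
        d = pm.gen_diameters(10 ** 5, seed=10).diameters
        assert np.mean((d > 200) & (d < 800)) >= 0.20
        assert np.mean((d > 1500) & (d < 2500)) >= 0.20


class TestTestImage:
    def test_round_trip_exact_fractions(self):
        img = pm.gen_test_image((80, 80), (0.40, 0.45, 0.15), seed=11)
        seg = pm.segment_by_hue(img)
        assert seg.fractions["microsphere"] == pytest.approx(0.40, abs=1e-9)
        assert seg.fractions["interface"] == pytest.approx(0.45, abs=1e-9)
        assert seg.fractions["matrix"] == pytest.approx(0.15, abs=1e-9)

    def test_single_region_image(self):
        img = pm.gen_test_image((32, 32), (1.0, 0.0, 0.0), seed=12)
        seg = pm.segment_by_hue(img)
        assert seg.fractions["microsphere"] == 1.0

    def test_seed_determinism(self):
        i1 = pm.gen_test_image((48, 48), (0.3, 0.3, 0.2), seed=13)
        i2 = pm.gen_test_image((48, 48), (0.3, 0.3, 0.2), seed=13)
        np.testing.assert_array_equal(i1, i2)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            pm.gen_test_image((10, 10), (0.6, 0.6, 0.1))
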