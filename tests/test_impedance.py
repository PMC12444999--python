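"""Circuit-element formulas, CNLS fitting and series-equivalent conversions."""

import numpy as np
import pytest

import promyelin as pm
from promyelin.impedance import _auto_init


OMEGAS = np.logspace(-2, 5, 40)


class TestElements:
    def test_cpe_ideal_capacitor_at_n_1(self):
        q = 2e-6
        z = pm.z_cpe(q, 1.0, OMEGAS)
        np.testing.assert_allclose(z, 1.0 / (1j * OMEGAS * q))

    def test_cpe_resistor_at_n_0(self):
        z = pm.z_cpe(4.0, 0.0, OMEGAS)
        np.testing.assert_allclose(z, 0.25)

    def test_cpe_modulus_scaling(self):
        n = 0.7
        ratio = np.abs(pm.z_cpe(1e-6, n, 10.0)) / np.abs(pm.z_cpe(1e-6, n, 1.0))
        assert ratio == pytest.approx(10 ** (-n))

    def test_warburg_phase_minus_45_everywhere(self):
        z = pm.z_warburg(6332.0, OMEGAS)
        np.testing.assert_allclose(np.degrees(np.angle(z)), -45.0)

    def test_warburg_modulus(self):
        sigma, w = 100.0, 7.3
        assert np.abs(pm.z_warburg(sigma, w)) == pytest.approx(
            sigma * np.sqrt(2.0 / w)
        )
        assert np.abs(pm.z_warburg(sigma, 1e9)) < 0.01

    def test_total_impedance_limits(self):
        p = pm.CircuitParams(r1=100.0, r2=1000.0, q=1e-6, n=0.9, sigma=0.0)
        assert pm.z_total(p, 1e9).real == pytest.approx(100.0, rel=1e-3)
        assert pm.z_total(p, 1e-9).real == pytest.approx(1100.0, rel=1e-3)

    def test_total_matches_elementwise_oracle(self):
        # independent element-by-element complex arithmetic at f = 1 Hz
        p = pm.REFERENCE_CIRCUIT
        w = 2 * np.pi * 1.0
        z_cpe = 1.0 / (p.q * (1j * w) ** p.n)
        z_arc = 1.0 / (1.0 / p.r2 + 1.0 / z_cpe)  # parallel combination
        z_w = p.sigma / np.sqrt(w) * (1 - 1j)
        expected = p.r1 + z_arc + z_w
        assert pm.z_total(p, w) == pytest.approx(expected, rel=1e-12)

    def test_multi_rc_ladder(self):
        r, c = [100.0, 300.0], [1e-6, 1e-7]
        assert pm.z_multi_rc([100.0], [1e-6], 0.0) == pytest.approx(100.0)
        assert np.abs(pm.z_multi_rc(r, c, 1e12)) < 1e-3
        w = 50.0
        direct = sum(ri / (1 + 1j * w * ri * ci) for ri, ci in zip(r, c))
        assert pm.z_multi_rc(r, c, w) == pytest.approx(direct)

    def test_capacitive_branch_sign(self):
        # -Im(Z) >= 0 across a log grid for valid parameters
        z = pm.z_total(pm.REFERENCE_CIRCUIT, OMEGAS)
        assert np.all(-z.imag >= 0)

    def test_modulus_monotone_without_warburg(self):
        p = pm.CircuitParams(r1=50.0, r2=5000.0, q=1e-5, n=0.85, sigma=0.0)
        mag = np.abs(pm.z_total(p, OMEGAS))
        assert np.all(np.diff(mag) <= 1e-9)


FREQS = np.logspace(-2, 5, 50)


class TestFitCircuit:
    def test_noiseless_parameter_recovery(self):
        spec = pm.gen_eis_spectrum(pm.REFERENCE_CIRCUIT, FREQS, rel_noise=0.0)
        fit = pm.fit_circuit(spec)
        assert fit.success and not fit.degenerate
        assert fit.chi2 < 1e-10
        for name in ("r1", "r2", "q", "n", "sigma"):
            got = getattr(fit.params, name)
            want = getattr(pm.REFERENCE_CIRCUIT, name)
            assert got == pytest.approx(want, rel=1e-3), name

    def test_noisy_recovery_within_5_percent(self):
        for seed in range(10):
            spec = pm.gen_eis_spectrum(
                pm.REFERENCE_CIRCUIT, FREQS, rel_noise=0.01, seed=seed
            )
            fit = pm.fit_circuit(spec)
            assert fit.success
            for name in ("r1", "r2", "q", "n", "sigma"):
                got = getattr(fit.params, name)
                want = getattr(pm.REFERENCE_CIRCUIT, name)
                assert abs(got - want) / want < 0.05, (name, seed)

    def test_fit_idempotence(self):
        spec = pm.gen_eis_spectrum(pm.REFERENCE_CIRCUIT, FREQS, rel_noise=0.01,
                                   seed=3)
        fit1 = pm.fit_circuit(spec)
        fit2 = pm.fit_circuit(spec, init=fit1.params)
        for name in ("r1", "r2", "q", "n", "sigma"):
            a, b = getattr(fit1.params, name), getattr(fit2.params, name)
            assert b == pytest.approx(a, rel=1e-6)

    def test_pure_resistor_flagged_degenerate(self):
        f = FREQS
        spec = pm.ImpedanceSpectrum(freq=f, z=np.full(f.size, 500.0 + 0.0j))
        fit = pm.fit_circuit(spec)
        assert fit.degenerate

    def test_too_few_points_rejected(self):
        f = np.logspace(0, 2, 5)
        spec = pm.gen_eis_spectrum(pm.REFERENCE_CIRCUIT, f)
        with pytest.raises(ValueError):
            pm.fit_circuit(spec)

    def test_auto_init_is_sane(self):
        spec = pm.gen_eis_spectrum(pm.REFERENCE_CIRCUIT, FREQS)
        init = _auto_init(spec)
        assert init.r1 > 0 and init.r2 > 0 and init.q > 0 and init.sigma > 0


class TestSeriesEquivalents:
    def test_three_four_five(self):
        out = pm.series_equivalents(3.0, -4.0, 1000.0)
        assert out["z_mag"] == pytest.approx(5.0)

    def test_phase_angle(self):
        out = pm.series_equivalents(1.0, -1.0, 300e3)
        assert out["theta"] == pytest.approx(-45.0)

    def test_capacitance_from_negative_reactance(self):
        f, x = 300e3, -2243.0
        out = pm.series_equivalents(5790.0, x, f)
        assert out["cs"] == pytest.approx(-1.0 / (2 * np.pi * f * x))
        assert out["cs_defined"]
        # standard formulas give |Z| ~= 6209 ohm for the pure-proteinoid
        # readout (instrument prints 6043; the conversions are exact algebra)
        assert out["z_mag"] == pytest.approx(6209.3, abs=0.5)

    def test_inductive_reactance_flagged(self):
        out = pm.series_equivalents(10.0, 5.0, 1000.0)
        assert not out["cs_defined"]
        assert np.isnan(out["cs"])

    def test_capacitance_increase_arithmetic(self):
        assert pm.capacitance_increase_percent(159.3, 72.89) == pytest.approx(
            118.55, abs=0.01
        )
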