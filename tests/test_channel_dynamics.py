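"""Channel model tests: printed defaults, skeleton levels, noise calibration."""

import dataclasses

import numpy as np
import pytest

import promyelin as pm
from promyelin.channel_dynamics import channel_seed

from conftest import noiseless


class TestDefaults:
    @pytest.mark.parametrize(
        "channel,field,expected",
        [
            ("C", "drift_rate", -2.0),
            ("D", "drift_rate", 0.2),
            ("F", "drift_rate", 0.6),
            ("H", "drift_rate", 0.15),
            ("F", "t_c", 80000.0),
            ("F", "post_level", 35.0),
            ("E", "v_peak", 70.0),
        ],
    )
    def test_printed_default_values(self, channel, field, expected):
        assert getattr(pm.default_params(channel), field) == expected

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError):
            pm.default_params("Z")
        with pytest.raises(ValueError):
            pm.simulate_channel("Z", duration_s=10, dt_s=1, seed=0)


class TestSkeletons:
    """Noise-free traces must follow each channel's characteristic form."""

    def test_channel_e_initial_peak(self):
        tr = noiseless("E", duration_s=1000, dt_s=0.4)
        assert tr.v[0] == pytest.approx(70.0)

    def test_channel_e_steady_state(self):
        tr = noiseless("E")
        late = tr.v[tr.t > 100000]
        assert np.all(np.abs(late - (-5.0)) <= 3.0)

    def test_channel_f_bistable_levels(self):
        tr = noiseless("F")
        # baseline outside the hyperpolarization dip
        assert tr.v[tr.t == 5000] == pytest.approx(-60.0)
        assert np.all(tr.v[tr.t >= 80000] == 35.0)

    def test_channel_f_dip_reaches_minus_90(self):
        tr = noiseless("F")
        window = tr.v[(tr.t >= 20000) & (tr.t <= 30000)]
        assert window.min() == pytest.approx(-90.0)

    def test_channel_c_linear_drift_value(self):
        # v0 = 0, beta = -2 mV/ks: at t = 10,000 s the potential is -20 mV
        tr = noiseless("C", duration_s=20000, dt_s=0.4)
        assert tr.v[tr.t == 10000] == pytest.approx(-20.0)

    def test_channel_c_steady_level(self):
        tr = noiseless("C")
        late = tr.v[tr.t > 80000]
        assert np.all(np.abs(late - (-75.0)) <= 5.0)

    def test_channel_b_plateau(self):
        tr = noiseless("B")
        plateau = tr.v[(tr.t >= 40000) & (tr.t <= 160000)]
        assert np.all(np.abs(plateau - 25.0) <= 5.0 + 1e-9)

    def test_channel_d_initial_floor(self):
        tr = noiseless("D")
        assert tr.v[tr.t == 1000] == pytest.approx(-55.0, abs=0.5)

    def test_channel_g_endpoint_near_zero(self):
        tr = noiseless("G")
        assert abs(tr.v[-1]) < 1.0

    def test_channel_h_steady_level(self):
        tr = noiseless("H")
        assert tr.v[-1] == pytest.approx(35.0, abs=2.0)


class TestStochastics:
    def test_noise_off_equals_skeleton_exactly(self):
        a = noiseless("B", duration_s=10000, dt_s=2.0)
        b = noiseless("B", duration_s=10000, dt_s=2.0)
        np.testing.assert_array_equal(a.v, b.v)

    def test_same_seed_identical_trace(self):
        t1 = pm.simulate_channel("A", duration_s=5000, dt_s=0.4, seed=11)
        t2 = pm.simulate_channel("A", duration_s=5000, dt_s=0.4, seed=11)
        np.testing.assert_array_equal(t1.v, t2.v)

    def test_different_seed_differs(self):
        t1 = pm.simulate_channel("A", duration_s=5000, dt_s=0.4, seed=1)
        t2 = pm.simulate_channel("A", duration_s=5000, dt_s=0.4, seed=2)
        assert not np.array_equal(t1.v, t2.v)

    def test_noise_sd_calibration(self):
        # flat skeleton, default correlation time: RMS about the skeleton
        # averaged over 10 seeds recovers the configured sd within 10%
        p = dataclasses.replace(
            pm.default_params("C"), drift_rate=0.0, v_steady=0.0, v0=0.0,
            noise_sd=3.0,
        )
        rms = []
        for seed in range(10):
            tr = pm.simulate_channel("C", p, duration_s=360000, dt_s=4.0, seed=seed)
            rms.append(np.sqrt(np.mean(tr.v ** 2)))
        assert np.mean(rms) == pytest.approx(3.0, rel=0.10)

    def test_noise_bounded_by_envelope(self):
        # fluctuations saturate at ~2 sd: the printed +/- envelope
        p = dataclasses.replace(
            pm.default_params("C"), drift_rate=0.0, v_steady=0.0, v0=0.0,
            noise_sd=3.0,
        )
        tr = pm.simulate_channel("C", p, duration_s=360000, dt_s=4.0, seed=0)
        assert np.abs(tr.v).max() <= 2.0 * 3.0 / 0.9594461556733254 + 1e-9

    def test_channel_a_spikes_are_positive_excursions(self):
        p = dataclasses.replace(pm.default_params("A"), noise_sd=0.0)
        tr = pm.simulate_channel("A", p, duration_s=20000, dt_s=0.4, seed=3)
        skel = noiseless("A", duration_s=20000, dt_s=0.4)
        resid = tr.v - skel.v
        assert resid.min() >= -1e-9  # spike kernel only adds depolarization
        assert resid.max() > 5.0  # and events do occur at the default rate


class TestEdgeCases:
    def test_zero_duration_empty_trace(self):
        tr = pm.simulate_channel("A", duration_s=0.0, dt_s=0.4, seed=0)
        assert len(tr) == 0

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            pm.simulate_channel("A", duration_s=-1.0, dt_s=0.4, seed=0)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            pm.simulate_channel("A", duration_s=10.0, dt_s=0.0, seed=0)


class TestEnsemble:
    def test_shared_time_grid_and_determinism(self):
        e1 = pm.simulate_ensemble(duration_s=2000, dt_s=0.4, seed=5)
        e2 = pm.simulate_ensemble(duration_s=2000, dt_s=0.4, seed=5)
        assert set(e1) == set(pm.CHANNELS)
        t0 = e1["A"].t
        for ch in pm.CHANNELS:
            np.testing.assert_array_equal(e1[ch].t, t0)
            np.testing.assert_array_equal(e1[ch].v, e2[ch].v)

    def test_subset_ensemble(self):
        e = pm.simulate_ensemble(
            {"B": pm.default_params("B")}, duration_s=1000, dt_s=0.4, seed=0
        )
        assert list(e) == ["B"]

    def test_subseeding_matches_single_channel_runs(self):
        e = pm.simulate_ensemble(duration_s=1000, dt_s=0.4, seed=9)
        solo = pm.simulate_channel(
            "D", duration_s=1000, dt_s=0.4, seed=channel_seed(9, "D")
        )
        np.testing.assert_array_equal(e["D"].v, solo.v)

    def test_ensemble_extrema_span_printed_range(self):
        # channel F dip -> minimum near -90 mV; channel E start -> max near +70
        mins, maxs = [], []
        for seed in (1, 2, 3):
            ens = pm.simulate_ensemble(duration_s=180000, dt_s=8.0, seed=seed)
            mins.append(min(tr.v.min() for tr in ens.values()))
            maxs.append(max(tr.v.max() for tr in ens.values()))
        f_sd = pm.default_params("F").noise_sd
        assert abs(np.mean(mins) - (-90.0)) <= 2.0 * f_sd
        assert abs(np.mean(maxs) - 70.0) <= 2.0 * pm.default_params("E").noise_sd
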