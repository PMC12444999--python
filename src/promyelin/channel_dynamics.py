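"""Phenomenological membrane-potential models for the eight recording channels.

A proteinoid-myelin hybrid network recorded through eight extracellular
microelectrodes (labelled A-H) exhibits channel-specific long-term dynamics:
random-walk spiking (A), linear depolarizing drift with oscillations (B),
anionic hyperpolarizing drift (C), biphasic RC-like recovery (D), sharp
capacitive discharge (E), bistable switching with a deep hyperpolarization
dip (F), envelope-modulated oscillation (G) and saturating monotone rise (H).

Each channel is simulated as a deterministic skeleton (the channel's
characteristic functional form) plus stochastic components: a slow
band-limited Gaussian fluctuation process and, for channel A, superimposed
Poisson spike events.  With the stochastic amplitudes set to zero the trace
equals the skeleton exactly, which is what the skeleton-level unit tests
exercise.

Units: time in seconds, potential in mV, drift rates in mV/ks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "CHANNELS",
    "PotentialTrace",
    "ChannelParams",
    "default_params",
    "simulate_channel",
    "simulate_ensemble",
]

CHANNELS = ("A", "B", "C", "D", "E", "F", "G", "H")

_KS = 1000.0  # seconds per "ks" drift-rate unit


@dataclass(frozen=True)
class PotentialTrace:
    """Uniformly sampled membrane-potential time series for one channel."""

    channel_id: str
    t: np.ndarray  # seconds, monotonically increasing
    v: np.ndarray  # mV
    dt: float  # sampling interval, seconds

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.v, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "v", v)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("t and v must be 1-D arrays of equal length")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if t.size and not (np.isfinite(t).all() and np.isfinite(v).all()):
            raise ValueError("trace contains non-finite values")
        if t.size > 1:
            steps = np.diff(t)
            if not np.allclose(steps, self.dt, rtol=1e-9, atol=1e-9 * self.dt):
                raise ValueError("time grid is not uniform at the stated dt")

    def __len__(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class ChannelParams:
    """Per-channel model parameters.

    Only the fields used by a given channel's functional form matter for that
    channel; the rest are ignored.  The stochastic terms of all channels are
    realized as one band-limited Gaussian fluctuation process configured by
    ``noise_sd`` (mV, stationary standard deviation) and ``noise_tau`` (s,
    correlation time), plus optional Poisson spike events (channel A).
    """

    v0: float = 0.0  # initial potential, mV
    drift_rate: float = 0.0  # mV/ks, sign-carrying
    tau1: Optional[float] = None  # s
    tau2: Optional[float] = None  # s
    t_c: Optional[float] = None  # critical transition time, s
    pre_level: float = 0.0  # mV (channel F)
    post_level: float = 0.0  # mV (channel F)
    v_min: Optional[float] = None  # mV
    v_max: Optional[float] = None  # mV
    v_peak: Optional[float] = None  # mV
    v_base: Optional[float] = None  # mV
    v_steady: Optional[float] = None  # mV
    osc_amplitude: float = 0.0  # mV, peak of the oscillatory component
    osc_period_range: Tuple[float, float] = (2000.0, 3000.0)  # s
    phase: float = 0.0  # rad
    noise_sd: float = 0.0  # mV
    noise_tau: float = 3000.0  # s, fluctuation correlation time
    spike_amplitude_range: Tuple[float, float] = (10.0, 15.0)  # mV
    spike_rate: float = 0.0  # events/s
    spike_half_life: float = 20.0  # s, decay of the spike kernel
    amp_const: Optional[float] = None  # mV, saturation amplitude (channel H)

    def __post_init__(self):
        for name in ("tau1", "tau2"):
            val = getattr(self, name)
            if val is not None and val <= 0:
                raise ValueError(f"{name} must be positive when set")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.noise_tau <= 0:
            raise ValueError("noise_tau must be positive")
        if self.osc_period_range[0] <= 0:
            raise ValueError("oscillation periods must be positive")
        if self.spike_rate < 0:
            raise ValueError("spike_rate must be non-negative")


# ---------------------------------------------------------------------------
# Default parameterization.  Printed values (drift rates, levels, transition
# time, noise envelopes) come straight from the channel characterizations;
# a +/-x mV noise envelope is read as a ~2-sd band, so noise_sd = x/2.
# ---------------------------------------------------------------------------

_DEFAULTS: Dict[str, ChannelParams] = {
    # Random walk around a decaying baseline (+25 mV -> -40 mV by 40 ks) with
    # Poisson spike events of 10-15 mV; fluctuation time scale 5000 s.
    "A": ChannelParams(
        v0=25.0, v_min=-40.0, tau1=8000.0, noise_sd=5.0, noise_tau=5000.0,
        spike_rate=0.02, spike_amplitude_range=(10.0, 15.0), spike_half_life=20.0,
    ),
    # Linear depolarization -25 -> +25 mV over 40 ks (alpha = +1.25 mV/ks),
    # plateau with 2000-3000 s oscillations, final step to +40 mV at 160 ks.
    "B": ChannelParams(
        v0=-25.0, drift_rate=1.25, v_max=40.0, v_steady=25.0,
        osc_amplitude=5.0, osc_period_range=(2000.0, 3000.0),
        noise_sd=2.5,
    ),
    # Anion-selective drift: beta = -2 mV/ks down to -75 mV, slow settle to -80.
    "C": ChannelParams(
        v0=0.0, drift_rate=-2.0, v_steady=-80.0, noise_sd=2.5,
    ),
    # Biphasic: fast hyperpolarization to -55 mV (tau1 = 200 s) then gradual
    # recovery at gamma = +0.2 mV/ks.
    "D": ChannelParams(
        v0=0.0, drift_rate=0.2, tau1=200.0, v_min=-55.0, noise_sd=2.5,
    ),
    # Capacitive discharge from +70 mV toward -5 mV, tau2 = 20 ks.
    "E": ChannelParams(
        v0=70.0, v_peak=70.0, v_steady=-5.0, tau2=20000.0, noise_sd=2.5,
    ),
    # Bistable: -60 mV baseline, deterministic dip to -90 mV (minimum in
    # 20-30 ks), recovery at alpha = +0.6 mV/ks back to -60 mV by t_c = 80 ks,
    # then switch to +35 mV.
    "F": ChannelParams(
        v0=-60.0, drift_rate=0.6, t_c=80000.0, pre_level=-60.0,
        post_level=35.0, v_min=-90.0, noise_sd=7.5,
    ),
    # Oscillatory: -70 mV start, depolarization to +20 mV by 10 ks, baseline
    # ~+10 mV with a 15 mV envelope burst at 23-36 ks, hyperpolarizing pulse
    # to -30 mV at 150 ks, endpoint 0 mV.
    "G": ChannelParams(
        v0=-70.0, v_base=10.0, v_min=-30.0, osc_amplitude=15.0,
        osc_period_range=(2000.0, 2000.0), noise_sd=5.0,
    ),
    # Saturating rise -50 mV -> ~22.5 mV by 100 ks (tau = 20 ks), then slow
    # linear approach at beta = +0.15 mV/ks to ~+35 mV.
    "H": ChannelParams(
        v0=-50.0, drift_rate=0.15, tau1=20000.0, v_min=-50.0,
        amp_const=73.0, v_steady=35.0, noise_sd=2.5,
    ),
}


def default_params(channel_id: str) -> ChannelParams:
    """Return the default model parameters for one channel.

    Raises
    ------
    ValueError
        If ``channel_id`` is not one of ``A``..``H``.
    """
    try:
        return _DEFAULTS[channel_id]
    except KeyError:
        raise ValueError(
            f"unknown channel {channel_id!r}; expected one of {CHANNELS}"
        ) from None


# ---------------------------------------------------------------------------
# Deterministic skeletons
# ---------------------------------------------------------------------------

def _smoothstep(t, t0, t1):
    """Cosine ramp from 0 at t0 to 1 at t1, clipped outside."""
    x = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * x))


def _skeleton_A(t, p: ChannelParams):
    return p.v_min + (p.v0 - p.v_min) * np.exp(-t / p.tau1)


def _skeleton_B(t, p: ChannelParams):
    ramp_end = 40000.0
    jump_t = 160000.0
    v = p.v0 + p.drift_rate * np.minimum(t, ramp_end) / _KS
    v = v + (p.v_max - p.v_steady) * _smoothstep(t, jump_t, jump_t + 1000.0)
    # deterministic oscillation on the plateau, period sweeping across the
    # printed 2000-3000 s band
    lo, hi = p.osc_period_range
    if p.osc_amplitude and hi > 0:
        w = (t > ramp_end) & (t < jump_t)
        tt = t[w] - ramp_end
        span = jump_t - ramp_end
        if hi > lo:
            # phase = integral of 2*pi/T(u) du with T linear in u
            rate = (hi - lo) / span
            ph = 2.0 * np.pi * np.log1p(rate * tt / lo) / rate
        else:
            ph = 2.0 * np.pi * tt / lo
        osc = np.zeros_like(t)
        osc[w] = p.osc_amplitude * np.sin(ph + p.phase)
        v = v + osc
    return v


def _skeleton_C(t, p: ChannelParams):
    knee = 37500.0  # -2 mV/ks reaches -75 mV
    v_knee = p.v0 + p.drift_rate * knee / _KS
    tail_rate = (p.v_steady - v_knee) / (180000.0 - knee)  # slow settle to -80
    return np.where(
        t <= knee,
        p.v0 + p.drift_rate * t / _KS,
        v_knee + tail_rate * (t - knee),
    )


def _skeleton_D(t, p: ChannelParams):
    t_knee = 1000.0
    initial = p.v_min + (p.v0 - p.v_min) * np.exp(-t / p.tau1)
    v_knee = p.v_min + (p.v0 - p.v_min) * np.exp(-t_knee / p.tau1)
    recovery = v_knee + p.drift_rate * (t - t_knee) / _KS
    return np.where(t <= t_knee, initial, recovery)


def _skeleton_E(t, p: ChannelParams):
    return p.v_steady + (p.v_peak - p.v_steady) * np.exp(-t / p.tau2)


def _skeleton_F(t, p: ChannelParams):
    # -60 mV baseline; dip to -90 mV with the minimum inside 20-30 ks; linear
    # recovery at +0.6 mV/ks returns exactly to the -60 mV pre-level at 80 ks
    dip_start, dip_bottom, recover_start = 20000.0, 25000.0, 30000.0
    v = np.full_like(t, p.pre_level)
    v = v + (p.v_min - p.pre_level) * _smoothstep(t, dip_start, dip_bottom)
    rec = t > recover_start
    v = np.where(
        rec,
        np.minimum(p.v_min + p.drift_rate * (t - recover_start) / _KS, p.pre_level),
        v,
    )
    return np.where(t >= p.t_c, p.post_level, v)


def _skeleton_G(t, p: ChannelParams):
    v = np.empty_like(t)
    # depolarization -70 -> +20 over the first 10 ks (half-cosine)
    seg0 = t <= 10000.0
    v[seg0] = p.v0 + 90.0 * _smoothstep(t[seg0], 0.0, 10000.0)
    # relax +20 -> +10 over 10-20 ks
    seg1 = (t > 10000.0) & (t <= 20000.0)
    v[seg1] = 20.0 - 10.0 * (t[seg1] - 10000.0) / 10000.0
    # quasi-stable baseline
    seg2 = (t > 20000.0) & (t <= 140000.0)
    v[seg2] = p.v_base
    # late decline to 0 mV at 180 ks
    seg3 = t > 140000.0
    v[seg3] = p.v_base * (1.0 - (t[seg3] - 140000.0) / 40000.0)
    # envelope-modulated oscillation burst, 23-36 ks
    if p.osc_amplitude:
        w = (t >= 23000.0) & (t <= 36000.0)
        env = p.osc_amplitude * np.sin(np.pi * (t[w] - 23000.0) / 13000.0) ** 2
        period = p.osc_period_range[0]
        v[w] += env * np.sin(2.0 * np.pi * t[w] / period + p.phase)
    # hyperpolarizing pulse to ~-30 mV centred at 150 ks, width 5 ks
    w = (t >= 147500.0) & (t <= 152500.0)
    v[w] -= 37.5 * np.sin(np.pi * (t[w] - 147500.0) / 5000.0) ** 2
    return v


def _skeleton_H(t, p: ChannelParams):
    t_knee = 100000.0
    sat = p.v_min + p.amp_const * (1.0 - np.exp(-t / p.tau1))
    v_knee = p.v_min + p.amp_const * (1.0 - np.exp(-t_knee / p.tau1))
    late = v_knee + p.drift_rate * (t - t_knee) / _KS
    return np.where(t <= t_knee, sat, late)


_SKELETONS = {
    "A": _skeleton_A, "B": _skeleton_B, "C": _skeleton_C, "D": _skeleton_D,
    "E": _skeleton_E, "F": _skeleton_F, "G": _skeleton_G, "H": _skeleton_H,
}


# ---------------------------------------------------------------------------
# Stochastic components
# ---------------------------------------------------------------------------

# sd of a standard normal hard-clipped at +/-2: used to rescale the saturated
# fluctuation process back to its nominal standard deviation
_CLIP_SD = 0.9594461556733254


def _fluctuation_noise(n: int, dt: float, sd: float, tau: float,
                       rng: np.random.Generator):
    """Band-limited Gaussian fluctuation path with an envelope saturation.

    White Gaussian noise smoothed with a Gaussian kernel of time scale
    ``tau`` and normalized to stationary sd ``sd``.  The smooth (finite
    level-crossing rate) process keeps sampled extremes at a few sd
    regardless of the sampling interval; the path is additionally saturated
    at the 2-sd envelope and rescaled, because the printed fluctuation
    amplitudes are +/- envelopes that excursions should not leave.  The
    delivered standard deviation equals ``sd`` exactly; excursions never
    exceed ~2.08 sd.
    """
    if n == 0 or sd == 0.0:
        return np.zeros(n)
    k_sigma = max(tau / dt, 1e-6)
    half = int(np.ceil(4.0 * k_sigma)) + 1
    kernel = np.exp(-0.5 * (np.arange(-half, half + 1) / k_sigma) ** 2)
    # normalize to unit L2 norm: filtered white noise then has sd exactly `sd`
    kernel /= np.sqrt(np.sum(kernel ** 2))
    w = rng.standard_normal(n + 2 * half)
    sm = fftconvolve(w, kernel, mode="same")[half:half + n]
    out = sm * sd
    return np.clip(out, -2.0 * sd, 2.0 * sd) / _CLIP_SD


def _spike_events(t, dt, p: ChannelParams, rng: np.random.Generator):
    """Superimposed Poisson spike events with an exponential decay kernel."""
    n = t.size
    out = np.zeros(n)
    if n == 0 or p.spike_rate <= 0:
        return out
    duration = n * dt
    count = rng.poisson(p.spike_rate * duration)
    if count == 0:
        return out
    times = np.sort(rng.uniform(0.0, duration, count))
    lo, hi = p.spike_amplitude_range
    amps = rng.uniform(lo, hi, count)
    decay = np.log(2.0) / p.spike_half_life
    support = int(np.ceil(10.0 * p.spike_half_life / dt)) + 1
    kernel_t = np.arange(support) * dt
    kernel = np.exp(-decay * kernel_t)
    for ti, ai in zip(times, amps):
        i0 = int(np.ceil(ti / dt))
        if i0 >= n:
            continue
        seg = min(support, n - i0)
        # kernel evaluated from the event time, not the sample grid
        offset = i0 * dt - ti
        out[i0:i0 + seg] += ai * np.exp(-decay * offset) * kernel[:seg]
    return out


# ---------------------------------------------------------------------------
# Public simulation API
# ---------------------------------------------------------------------------

def simulate_channel(
    channel_id: str,
    params: Optional[ChannelParams] = None,
    duration_s: float = 18000.0,
    dt_s: float = 0.4,
    seed: int = 0,
) -> PotentialTrace:
    """Simulate one channel's membrane-potential trace.

    The trace is the channel's deterministic skeleton plus an OU fluctuation
    process (sd ``noise_sd``) and, if ``spike_rate > 0``, Poisson spike
    events.  With ``noise_sd = 0`` and ``spike_rate = 0`` the output equals
    the skeleton exactly, and identical ``(params, seed)`` give identical
    arrays.

    Parameters
    ----------
    channel_id : one of 'A'..'H'
    params : ChannelParams, optional
        Defaults to :func:`default_params` for the channel.
    duration_s, dt_s : float
        Simulated span and sampling interval (default 0.4 s, i.e. 2.5 Hz).
    seed : int
        Seed for the stochastic components.
    """
    if channel_id not in _SKELETONS:
        raise ValueError(
            f"unknown channel {channel_id!r}; expected one of {CHANNELS}"
        )
    if duration_s < 0:
        raise ValueError("duration_s must be non-negative")
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    if params is None:
        params = default_params(channel_id)

    n = int(round(duration_s / dt_s))
    t = np.arange(n) * dt_s
    v = _SKELETONS[channel_id](t, params).astype(float)
    rng = np.random.default_rng(seed)
    v = v + _fluctuation_noise(n, dt_s, params.noise_sd, params.noise_tau, rng)
    v = v + _spike_events(t, dt_s, params, rng)
    return PotentialTrace(channel_id=channel_id, t=t, v=v, dt=dt_s)


def channel_seed(master_seed: int, channel_id: str) -> int:
    """Deterministic per-channel sub-seed: SeedSequence([master, ord(label)])."""
    ss = np.random.SeedSequence([int(master_seed), ord(channel_id)])
    return int(ss.generate_state(1)[0])


def simulate_ensemble(
    params_by_channel: Optional[Dict[str, ChannelParams]] = None,
    duration_s: float = 18000.0,
    dt_s: float = 0.4,
    seed: int = 0,
) -> Dict[str, PotentialTrace]:
    """Simulate a set of channels on one shared time grid.

    ``params_by_channel`` defaults to all eight channels with their default
    parameters.  Per-channel seeds are derived deterministically from the
    master seed via :func:`channel_seed`, so the ensemble is reproducible and
    individual channels can be re-simulated independently.
    """
    if params_by_channel is None:
        params_by_channel = {ch: default_params(ch) for ch in CHANNELS}
    out: Dict[str, PotentialTrace] = {}
    for ch, p in params_by_channel.items():
        out[ch] = simulate_channel(
            ch, p, duration_s=duration_s, dt_s=dt_s,
            seed=channel_seed(seed, ch),
        )
    return out
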