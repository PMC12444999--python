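"""Seeded generators for every input the analysis pipeline consumes.

These produce data with the statistical structure the downstream analyses
assume — noisy spectra from a known circuit, correlated Bernoulli pairs with
prescribed marginals and phi, Poisson and jittered-lattice spike trains,
bimodal microsphere-diameter samples, and blob-painted tri-region test
images — so every stage is testable end to end without any recorded data.

All generators are pure functions of (parameters, seed), built on
``numpy.random.default_rng``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage import color

from .boolean_logic import expected_joint_and, feasible_phi_interval
from .digitization import BinaryTrace
from .impedance import CircuitParams, ImpedanceSpectrum, z_total
from .spike_statistics import SpikeTrain

__all__ = [
    "DiameterSample",
    "DEFAULT_DIAMETER_SPEC",
    "gen_eis_spectrum",
    "gen_correlated_binary",
    "gen_poisson_train",
    "gen_regular_train",
    "gen_diameters",
    "gen_test_image",
]


# ---------------------------------------------------------------------------
# Impedance spectra
# ---------------------------------------------------------------------------

def gen_eis_spectrum(
    params: CircuitParams,
    freqs: Sequence[float],
    rel_noise: float = 0.0,
    seed: int = 0,
) -> ImpedanceSpectrum:
    """Forward-model spectrum with multiplicative complex Gaussian noise.

    ``z = z_total(params, 2 pi f) * (1 + eps)`` with ``eps`` complex
    Gaussian, per-component sd ``rel_noise``; ``rel_noise = 0`` returns the
    exact forward model.
    """
    if rel_noise < 0:
        raise ValueError("rel_noise must be non-negative")
    f = np.sort(np.asarray(freqs, dtype=float))
    if f.size == 0 or (f <= 0).any():
        raise ValueError("frequencies must be positive")
    z = z_total(params, 2.0 * np.pi * f)
    if rel_noise > 0:
        rng = np.random.default_rng(seed)
        eps = rel_noise * (
            rng.standard_normal(f.size) + 1j * rng.standard_normal(f.size)
        )
        z = z * (1.0 + eps)
    return ImpedanceSpectrum(freq=f, z=z)


# ---------------------------------------------------------------------------
# Correlated binary streams
# ---------------------------------------------------------------------------

def gen_correlated_binary(
    p_a: float,
    p_b: float,
    phi: float,
    n: int,
    seed: int = 0,
    dt: float = 1.0,
) -> Tuple[BinaryTrace, BinaryTrace]:
    """I.i.d. binary pairs with exact joint law implied by (pA, pB, phi).

    The 2x2 cell probabilities are ``p11 = pA pB + phi sqrt(pA qA pB qB)``
    with the remaining cells fixed by the marginals; an infeasible phi (one
    that would make a cell negative) raises with the feasible interval in
    the message.
    """
    lo, hi = feasible_phi_interval(p_a, p_b)
    p11 = expected_joint_and(p_a, p_b, phi)  # validates feasibility
    p10 = p_a - p11
    p01 = p_b - p11
    p00 = 1.0 - p11 - p10 - p01
    probs = np.array([p00, p01, p10, p11])
    probs = np.clip(probs, 0.0, None)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    cells = rng.choice(4, size=n, p=probs)
    a = (cells >= 2).astype(np.int8)  # cells 2 (10) and 3 (11)
    b = (cells % 2).astype(np.int8)  # cells 1 (01) and 3 (11)
    ta = BinaryTrace(channel_id="A", states=a, threshold_mv=0.0, dt=dt)
    tb = BinaryTrace(channel_id="B", states=b, threshold_mv=0.0, dt=dt)
    return ta, tb


# ---------------------------------------------------------------------------
# Spike trains
# ---------------------------------------------------------------------------

def gen_poisson_train(rate: float, duration: float, seed: int = 0) -> SpikeTrain:
    """Homogeneous Poisson event times on [0, duration]; exponential ISIs."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    if duration < 0:
        raise ValueError("duration must be non-negative")
    rng = np.random.default_rng(seed)
    count = rng.poisson(rate * duration)
    times = np.sort(rng.uniform(0.0, duration, count))
    return SpikeTrain(peak_times=times, peak_amplitudes=np.ones(count))


def gen_regular_train(
    period: float, duration: float, jitter_sd: float = 0.0, seed: int = 0
) -> SpikeTrain:
    """Equally spaced events with optional Gaussian timing jitter.

    With small jitter the ISI coefficient of variation approximates
    ``sqrt(2) * jitter_sd / period`` for independent event jitter; passing
    jitter applied to the intervals directly keeps CV = jitter_sd/period.
    Here jitter perturbs the *intervals* (each interval ~ N(period,
    jitter_sd)), so CV ~= jitter_sd / period — the low-CV metronomic regime.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    rng = np.random.default_rng(seed)
    times = []
    t = period
    while t <= duration:
        times.append(t)
        step = period + (rng.standard_normal() * jitter_sd if jitter_sd else 0.0)
        t += max(step, 1e-9 * period)  # keep times strictly increasing
    times = np.array(times)
    times = times[(times >= 0) & (times <= duration)]
    return SpikeTrain(peak_times=times, peak_amplitudes=np.ones(times.size))


# ---------------------------------------------------------------------------
# Microsphere diameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiameterSample:
    """Positive microsphere diameters (nm) drawn from a two-lognormal mixture."""

    diameters: np.ndarray
    weights: Tuple[float, float]
    medians_nm: Tuple[float, float]
    sigmas: Tuple[float, float]


#: Two-lognormal mixture calibrated numerically so that at large n the sample
#: mean ~= 1204 nm and sd ~= 1072 nm, with both populations (200-800 nm and
#: 1500-2500 nm) holding substantial mass.
DEFAULT_DIAMETER_SPEC = {
    "weights": (0.60, 0.40),
    "medians_nm": (370.0, 1990.0),
    "sigmas": (1.0, 0.33),
}


def gen_diameters(n: int, seed: int = 0, spec: Optional[dict] = None) -> DiameterSample:
    """Sample a bimodal microsphere-diameter distribution (nm)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = dict(DEFAULT_DIAMETER_SPEC)
    if spec:
        cfg.update(spec)
    w1, w2 = cfg["weights"]
    if not np.isclose(w1 + w2, 1.0):
        raise ValueError("component weights must sum to 1")
    m1, m2 = cfg["medians_nm"]
    s1, s2 = cfg["sigmas"]
    rng = np.random.default_rng(seed)
    pick = rng.random(n) < w1
    d = np.where(
        pick,
        rng.lognormal(np.log(m1), s1, n),
        rng.lognormal(np.log(m2), s2, n),
    )
    return DiameterSample(
        diameters=d, weights=(w1, w2), medians_nm=(m1, m2), sigmas=(s1, s2)
    )


# ---------------------------------------------------------------------------
# Test images
# ---------------------------------------------------------------------------

#: Mid-band hues (degrees) used to paint the three default regions.
_REGION_HUES = (30.0, 120.0, 240.0)


def gen_test_image(
    shape: Tuple[int, int],
    fractions: Sequence[float],
    seed: int = 0,
    smooth_sigma: Optional[float] = None,
) -> np.ndarray:
    """Blob-painted RGB test image with exact per-region pixel fractions.

    Thresholds a smoothed random field at the requested pixel-count
    quantiles, which yields irregular, connected blobs whose areas match the
    requested fractions exactly (to whole pixels).  The three regions are
    painted at hues 30/120/240 degrees (saturation and value 1); leftover
    pixels are neutral gray, i.e. unassigned under a saturation floor.

    Returns a uint8 (H, W, 3) array.
    """
    fr = np.asarray(fractions, dtype=float)
    if fr.size != 3 or (fr < 0).any() or fr.sum() > 1.0 + 1e-12:
        raise ValueError("need 3 non-negative fractions summing to <= 1")
    h, w = shape
    n = h * w
    rng = np.random.default_rng(seed)
    field = rng.standard_normal((h, w))
    sigma = smooth_sigma if smooth_sigma is not None else max(min(h, w) / 20.0, 1.0)
    field = ndimage.gaussian_filter(field, sigma)
    order = np.argsort(field, axis=None, kind="stable")

    counts = np.floor(fr * n).astype(int)
    # distribute rounding remainder to the largest fractional parts
    rem = int(round(min(fr.sum(), 1.0) * n)) - counts.sum()
    if rem > 0:
        extra = np.argsort(-(fr * n - counts))[:rem]
        counts[extra] += 1

    labels = np.zeros(n, dtype=np.int32)  # 0 = unassigned
    pos = 0
    for k, c in enumerate(counts, start=1):
        labels[order[pos:pos + c]] = k
        pos += c
    labels = labels.reshape(h, w)

    hsv = np.zeros((h, w, 3))
    hsv[..., 2] = 0.5  # unassigned: mid-gray (saturation 0)
    for k, hue in enumerate(_REGION_HUES, start=1):
        m = labels == k
        hsv[m, 0] = hue / 360.0
        hsv[m, 1] = 1.0
        hsv[m, 2] = 1.0
    rgb = color.hsv2rgb(hsv)
    return (np.clip(rgb, 0, 1) * 255).round().astype(np.uint8)
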