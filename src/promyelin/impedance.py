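"""Equivalent-circuit impedance model and complex nonlinear least-squares fit.

The interface is modelled as a Randles-type circuit: solution resistance R1
in series with a charge-transfer resistance R2 shunted by a constant phase
element (CPE) Q, plus a semi-infinite Warburg diffusion element:

    Z(w) = R1 + R2 / (1 + R2 * Q * (jw)^n) + sigma * w^(-1/2) * (1 - j)

The CPE, 1/(Q (jw)^n), interpolates between an ideal capacitor (n = 1) and
a resistor (n = 0); the Warburg element has a fixed -45 degree phase.  A
multi-RC ladder (sum of parallel RC elements) is also provided for
interface-stack modelling.

Fitting minimizes modulus-weighted residuals over log-parameterized
(R1, R2, Q, sigma) and box-constrained n in [0, 1]; the log parameterization
enforces positivity without a constrained solver.  All element formulas take
angular frequency (rad/s); conversion from Hz happens at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import lmfit
import numpy as np

__all__ = [
    "ImpedanceSpectrum",
    "CircuitParams",
    "FitResult",
    "REFERENCE_CIRCUIT",
    "z_cpe",
    "z_warburg",
    "z_total",
    "z_multi_rc",
    "fit_circuit",
    "series_equivalents",
    "capacitance_increase_percent",
]


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Complex impedance samples Z(f) on positive, sorted frequencies (Hz)."""

    freq: np.ndarray  # Hz
    z: np.ndarray  # complex ohms

    def __post_init__(self):
        f = np.asarray(self.freq, dtype=float)
        z = np.asarray(self.z, dtype=complex)
        object.__setattr__(self, "freq", f)
        object.__setattr__(self, "z", z)
        if f.shape != z.shape or f.ndim != 1:
            raise ValueError("freq and z must be 1-D arrays of equal length")
        if f.size and ((f <= 0).any() or not np.isfinite(f).all()):
            raise ValueError("frequencies must be positive and finite")
        if f.size and not np.isfinite(z).all():
            raise ValueError("impedances must be finite")
        if f.size > 1 and not (np.diff(f) > 0).all():
            raise ValueError("frequencies must be strictly increasing")

    def __len__(self) -> int:
        return self.freq.size

    @property
    def omega(self) -> np.ndarray:
        return 2.0 * np.pi * self.freq


@dataclass(frozen=True)
class CircuitParams:
    """The five circuit parameters: R1, R2 (ohm), Q (S s^n), n, sigma (ohm s^-1/2)."""

    r1: float
    r2: float
    q: float
    n: float
    sigma: float

    def __post_init__(self):
        if min(self.r1, self.r2, self.q, self.sigma) < 0:
            raise ValueError("r1, r2, q and sigma must be non-negative")
        if not 0.0 <= self.n <= 1.0:
            raise ValueError("CPE exponent n must lie in [0, 1]")


#: Fitted parameters reported for the hybrid interface (used as the default
#: forward model for synthetic spectra).
REFERENCE_CIRCUIT = CircuitParams(r1=539.5, r2=4.356e6, q=3.904e-6, n=0.940,
                                  sigma=6332.0)


@dataclass(frozen=True)
class FitResult:
    params: CircuitParams
    chi2: float  # reduced, modulus-weighted, dof = 2N - 5
    n_iterations: int
    rel_errors_percent: Dict[str, float]  # per-parameter relative std error, %
    success: bool
    degenerate: bool  # parameter at a bound / element contributes nothing
    message: str


def _check_omega(omega):
    w = np.asarray(omega, dtype=float)
    if (w <= 0).any():
        raise ValueError("angular frequency must be positive")
    return w


def z_cpe(q: float, n: float, omega) -> np.ndarray:
    """Constant-phase-element impedance 1/(q (j w)^n), principal branch."""
    w = _check_omega(omega)
    return 1.0 / (q * (1j * w) ** n)


def z_warburg(sigma: float, omega) -> np.ndarray:
    """Semi-infinite Warburg impedance sigma * w^(-1/2) * (1 - j)."""
    w = _check_omega(omega)
    return sigma / np.sqrt(w) * (1.0 - 1.0j)


def z_total(params: CircuitParams, omega) -> np.ndarray:
    """Total impedance of the R1 + (R2 || CPE) + Warburg circuit."""
    w = _check_omega(omega)
    z2 = params.r2 / (1.0 + params.r2 * params.q * (1j * w) ** params.n)
    return params.r1 + z2 + z_warburg(params.sigma, w)


def z_multi_rc(r_list: Sequence[float], c_list: Sequence[float], omega) -> np.ndarray:
    """Ladder of parallel RC elements: sum_i R_i / (1 + j w R_i C_i)."""
    if len(r_list) != len(c_list):
        raise ValueError("r_list and c_list must have equal length")
    if any(r <= 0 for r in r_list) or any(c <= 0 for c in c_list):
        raise ValueError("resistances and capacitances must be positive")
    w = np.asarray(omega, dtype=float)
    if (w < 0).any():
        raise ValueError("angular frequency must be non-negative")
    out = np.zeros_like(w, dtype=complex)
    for r, c in zip(r_list, c_list):
        out = out + r / (1.0 + 1j * w * r * c)
    return out


def _auto_init(spectrum: ImpedanceSpectrum) -> CircuitParams:
    """Heuristic starting point from the spectrum's asymptotes."""
    w = spectrum.omega
    re = spectrum.z.real
    im = -spectrum.z.imag
    r1 = max(float(re[-1]), 1e-3)  # high-frequency real limit
    # Warburg guess from the lowest frequency (assume it carries ~half of -Im)
    sigma = max(float(im[0]) * np.sqrt(w[0]) * 0.5, 1e-6)
    # arc width estimate after removing R1 and the Warburg tail
    r2 = max(float(re[0]) - r1 - sigma / np.sqrt(w[0]), r1) * 2.0
    # CPE: place the arc's characteristic frequency near the -Im maximum
    k = int(np.argmax(im))
    n = 0.9
    q = 1.0 / max(r2 * w[k] ** n, 1e-12)
    return CircuitParams(r1=r1, r2=r2, q=q, n=n, sigma=sigma)


def fit_circuit(
    spectrum: ImpedanceSpectrum,
    init: Optional[CircuitParams] = None,
    max_nfev: int = 5000,
) -> FitResult:
    """Complex nonlinear least-squares fit of the five circuit parameters.

    Minimizes the modulus-weighted objective
    ``sum_i [(Re dZ_i)^2 + (Im dZ_i)^2] / |Z_i|^2`` with Levenberg-Marquardt
    over log10(R1), log10(R2), log10(Q), log10(sigma) and bounded n.  The
    reported ``chi2`` is that sum divided by 2N - 5 degrees of freedom (a
    convention choice; instrument software may normalize differently).

    Non-convergence is flagged in ``success`` rather than raised; clearly
    under-determined solutions (an element fitted to a vanishing
    contribution, or n pinned at a bound) set ``degenerate``.
    """
    if len(spectrum) < 10:
        raise ValueError("need at least 10 frequency points to fit 5 parameters")
    if init is None:
        init = _auto_init(spectrum)
    w = spectrum.omega
    z = spectrum.z
    scale = np.abs(z)

    pars = lmfit.Parameters()
    pars.add("log_r1", value=np.log10(max(init.r1, 1e-9)), min=-9, max=12)
    pars.add("log_r2", value=np.log10(max(init.r2, 1e-9)), min=-9, max=15)
    pars.add("log_q", value=np.log10(max(init.q, 1e-15)), min=-15, max=3)
    pars.add("log_sigma", value=np.log10(max(init.sigma, 1e-9)), min=-9, max=12)
    pars.add("n", value=float(np.clip(init.n, 1e-3, 1.0)), min=0.0, max=1.0)

    def unpack(p) -> CircuitParams:
        return CircuitParams(
            r1=10.0 ** p["log_r1"].value,
            r2=10.0 ** p["log_r2"].value,
            q=10.0 ** p["log_q"].value,
            n=p["n"].value,
            sigma=10.0 ** p["log_sigma"].value,
        )

    def residual(p):
        zm = z_total(unpack(p), w)
        return np.concatenate(
            [(z.real - zm.real) / scale, (z.imag - zm.imag) / scale]
        )

    result = lmfit.minimize(residual, pars, method="leastsq", max_nfev=max_nfev)
    fitted = unpack(result.params)
    dof = 2 * len(spectrum) - 5
    chi2 = float(np.sum(result.residual ** 2) / dof)

    rel_errors: Dict[str, float] = {}
    log_names = {"r1": "log_r1", "r2": "log_r2", "q": "log_q",
                 "sigma": "log_sigma"}
    for pname, lname in log_names.items():
        se = result.params[lname].stderr
        rel_errors[pname] = float(np.log(10.0) * se * 100.0) if se else float("nan")
    n_se = result.params["n"].stderr
    rel_errors["n"] = (
        float(n_se / max(fitted.n, 1e-12) * 100.0) if n_se else float("nan")
    )

    # degeneracy heuristics: element contributes < 0.1% of |Z| anywhere it
    # should matter, or n pinned at a box bound
    zmag_low = float(np.abs(z[0]))
    arc = float(np.abs(fitted.r2 / (1 + fitted.r2 * fitted.q * (1j * w[0]) ** fitted.n)))
    finite_errs = [v for v in rel_errors.values() if np.isfinite(v)]
    degenerate = (
        fitted.n <= 1e-3 or fitted.n >= 1.0 - 1e-9
        or arc < 1e-3 * zmag_low
        or any(np.isnan(v) for v in rel_errors.values())
        or (finite_errs and max(finite_errs) > 100.0)
    )
    return FitResult(
        params=fitted, chi2=chi2, n_iterations=int(result.nfev),
        rel_errors_percent=rel_errors, success=bool(result.success),
        degenerate=bool(degenerate), message=str(result.message),
    )


def series_equivalents(r: float, x: float, f: float) -> Dict[str, float]:
    """LCR-style series-equivalent quantities from resistance and reactance.

    Returns ``z_mag`` = sqrt(r^2 + x^2), ``theta`` = atan2(x, r) in degrees,
    ``cs`` = -1/(2 pi f x) for capacitive (x < 0) readings and ``d`` = r/|x|
    (dissipation factor).  For x >= 0 the series capacitance is undefined and
    reported as NaN with ``cs_defined`` False: negative reactance is what
    indicates capacitive behaviour.
    """
    if f <= 0:
        raise ValueError("frequency must be positive")
    z_mag = float(np.hypot(r, x))
    theta = float(np.degrees(np.arctan2(x, r)))
    if x < 0:
        cs = float(-1.0 / (2.0 * np.pi * f * x))
        cs_defined = True
    else:
        cs = float("nan")
        cs_defined = False
    d = float(r / abs(x)) if x != 0 else float("inf")
    return {"z_mag": z_mag, "theta": theta, "cs": cs, "d": d,
            "cs_defined": cs_defined}


def capacitance_increase_percent(c_hybrid: float, c_pure: float) -> float:
    """Relative capacitance increase of the hybrid over the pure system, %."""
    if c_pure <= 0:
        raise ValueError("reference capacitance must be positive")
    return float((c_hybrid - c_pure) / c_pure * 100.0)
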