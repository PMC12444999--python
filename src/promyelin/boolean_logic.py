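"""Boolean gate algebra over binarized channels, and its output statistics.

Gates are evaluated through their arithmetic identities on {0,1} (e.g.
``XOR(a,b) = a + b - 2ab``) rather than lookup tables, so the identities
themselves are under test against a truth-table oracle.  The module also
carries the probabilistic machinery used to reconcile a measured AND-output
activation frequency with the product of the input frequencies: for binary
inputs with marginals (pA, pB) and phi coefficient phi,

    P(A and B) = pA*pB + phi * sqrt(pA qA pB qB),

which reduces to the independence product at phi = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np

from .digitization import BinaryTrace, state_stats

__all__ = [
    "GateSpec",
    "GateReport",
    "GATES",
    "eval_gate",
    "eval_gate_series",
    "expected_joint_and",
    "feasible_phi_interval",
    "phi_correlation",
]

# name -> (arity, arithmetic form on {0,1} arrays)
GATES: Dict[str, Tuple[int, callable]] = {
    "AND": (2, lambda a, b: a * b),
    "OR": (2, lambda a, b: a + b - a * b),
    "XOR": (2, lambda a, b: a + b - 2 * a * b),
    "NAND": (2, lambda a, b: 1 - a * b),
    "NOR": (2, lambda a, b: 1 - a - b + a * b),
    "XNOR": (2, lambda a, b: 1 - a - b + 2 * a * b),
    "NOT": (1, lambda a: 1 - a),
    "AND3": (3, lambda a, b, c: a * b * c),
    "OR3": (3, lambda a, b, c: 1 - (1 - a) * (1 - b) * (1 - c)),
    "MAJ": (3, lambda a, b, c: a * b + b * c + a * c - 2 * a * b * c),
    "AND4": (4, lambda a, b, c, d: a * b * c * d),
}


@dataclass(frozen=True)
class GateSpec:
    name: str
    arity: int

    def __post_init__(self):
        if self.name not in GATES:
            raise ValueError(f"unknown gate {self.name!r}")
        if self.arity != GATES[self.name][0]:
            raise ValueError(
                f"gate {self.name} has arity {GATES[self.name][0]}, "
                f"got {self.arity}"
            )

    @classmethod
    def by_name(cls, name: str) -> "GateSpec":
        if name not in GATES:
            raise ValueError(f"unknown gate {name!r}")
        return cls(name=name, arity=GATES[name][0])


@dataclass(frozen=True)
class GateReport:
    """Gate output series with its activation statistics."""

    output: BinaryTrace
    output_frequency: float  # activation ratio of the output
    input_frequencies: Tuple[float, ...]
    phi_matrix: np.ndarray  # pairwise phi of the inputs, NaN where undefined


def _check_bits(values) -> np.ndarray:
    arr = np.asarray(values)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("gate inputs must be 0/1")
    return arr.astype(np.int64)


def eval_gate(spec: GateSpec, inputs: Sequence[int]) -> int:
    """Evaluate one gate on scalar bits via its arithmetic identity."""
    arity, fn = GATES[spec.name]
    if len(inputs) != arity:
        raise ValueError(f"{spec.name} expects {arity} inputs, got {len(inputs)}")
    bits = [_check_bits(b) for b in inputs]
    out = int(fn(*bits))
    assert out in (0, 1)
    return out


def eval_gate_series(spec: GateSpec, inputs: Sequence[BinaryTrace]) -> GateReport:
    """Evaluate a gate elementwise over aligned binary traces.

    All inputs must share length and sampling interval; traces on mismatched
    time grids are refused rather than resampled.
    """
    arity, fn = GATES[spec.name]
    if len(inputs) != arity:
        raise ValueError(f"{spec.name} expects {arity} inputs, got {len(inputs)}")
    n = len(inputs[0])
    dt = inputs[0].dt
    for tr in inputs[1:]:
        if len(tr) != n:
            raise ValueError("input traces differ in length")
        if not np.isclose(tr.dt, dt, rtol=1e-12):
            raise ValueError("input traces differ in sampling interval")
    arrs = [_check_bits(tr.states) for tr in inputs]
    out_states = fn(*arrs).astype(np.int8)
    name = spec.name + "(" + ",".join(tr.channel_id for tr in inputs) + ")"
    out = BinaryTrace(channel_id=name, states=out_states, threshold_mv=0.0, dt=dt)
    in_freqs = tuple(state_stats(tr).activation_ratio for tr in inputs)
    out_freq = state_stats(out).activation_ratio if n else float("nan")
    phi = np.full((arity, arity), np.nan)
    for i in range(arity):
        phi[i, i] = 1.0
        for j in range(i + 1, arity):
            try:
                phi[i, j] = phi[j, i] = phi_correlation(inputs[i], inputs[j])
            except ValueError:
                pass  # constant input: leave NaN
    return GateReport(
        output=out, output_frequency=out_freq,
        input_frequencies=in_freqs, phi_matrix=phi,
    )


def feasible_phi_interval(p_a: float, p_b: float) -> Tuple[float, float]:
    """Frechet-feasible interval for the phi coefficient given the marginals."""
    q_a, q_b = 1.0 - p_a, 1.0 - p_b
    denom = np.sqrt(p_a * q_a * p_b * q_b)
    if denom == 0.0:
        return (0.0, 0.0)  # degenerate marginal: only phi = 0 is meaningful
    lo = (max(0.0, p_a + p_b - 1.0) - p_a * p_b) / denom
    hi = (min(p_a, p_b) - p_a * p_b) / denom
    return (lo, hi)


def expected_joint_and(p_a: float, p_b: float, phi: float = 0.0) -> float:
    """Expected AND-output activation frequency for correlated binary inputs.

    Returns ``pA*pB + phi*sqrt(pA(1-pA)pB(1-pB))``, clipped to the Frechet
    bounds ``[max(0, pA+pB-1), min(pA, pB)]``.  With ``phi = 0`` this is the
    independence prediction ``pA*pB``.

    Raises
    ------
    ValueError
        If the marginals are outside [0,1] or ``phi`` is infeasible for them
        (the message names the feasible interval).
    """
    if not (0.0 <= p_a <= 1.0 and 0.0 <= p_b <= 1.0):
        raise ValueError("marginals must lie in [0, 1]")
    lo, hi = feasible_phi_interval(p_a, p_b)
    tol = 1e-12
    if not (lo - tol <= phi <= hi + tol):
        raise ValueError(
            f"phi={phi} infeasible for marginals ({p_a}, {p_b}); "
            f"feasible interval is [{lo:.6f}, {hi:.6f}]"
        )
    q_a, q_b = 1.0 - p_a, 1.0 - p_b
    p11 = p_a * p_b + phi * np.sqrt(p_a * q_a * p_b * q_b)
    return float(np.clip(p11, max(0.0, p_a + p_b - 1.0), min(p_a, p_b)))


def phi_correlation(a: BinaryTrace, b: BinaryTrace) -> float:
    """Phi coefficient: Pearson correlation of two 0/1 sequences."""
    if len(a) != len(b):
        raise ValueError("traces differ in length")
    x = a.states.astype(float)
    y = b.states.astype(float)
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("phi is undefined for a constant binary trace")
    r = float(np.corrcoef(x, y)[0, 1])
    return float(np.clip(r, -1.0, 1.0))
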