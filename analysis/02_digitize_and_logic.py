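#!/usr/bin/env python
"""Digitize the simulated ensemble and run the Boolean-logic analysis.

Binarizes every channel at its own median, tabulates the channel statistics
(threshold, activation ratio, transition frequency, mean high-state
duration), evaluates the gate set on channels A/B (and F,G,H,A for the
4-input AND), and reconciles the AND-output frequency with the
phi-corrected joint-probability prediction on an exactly-correlated
synthetic fixture (marginals 0.49/0.49, phi = -0.27).
"""

from pathlib import Path

import numpy as np

import promyelin as pm
from promyelin import io as pio

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1
GATES = ("AND(A,B)", "OR(A,B)", "XOR(A,B)", "NAND(A,B)", "NOR(A,B)",
         "XNOR(A,B)", "MAJ(A,B,C)", "AND4(F,G,H,A)")


def main():
    OUT.mkdir(exist_ok=True)
    traces_csv = OUT / "traces.csv"
    if traces_csv.exists():
        ens = pio.read_trace_csv(traces_csv)
    else:
        ens = pm.simulate_ensemble(duration_s=180000.0, dt_s=4.0, seed=SEED)

    binaries, rows = {}, {}
    for ch, tr in sorted(ens.items()):
        thr = pm.median_threshold(tr)
        b = pm.binarize(tr, thr)
        st = pm.state_stats(b)
        binaries[ch] = b
        rows[ch] = {
            "threshold_mv": round(thr, 2),
            "activation_ratio": round(st.activation_ratio, 3),
            "transition_frequency_hz": st.transition_frequency,
            "mean_high_duration_s": st.mean_high_duration,
        }
    pio.write_json_report(rows, OUT / "channel_stats.json")

    print("per-channel binary statistics (median thresholds):")
    for ch, r in rows.items():
        print(f"  ch{ch}: thr {r['threshold_mv']:8.2f} mV  "
              f"ratio {r['activation_ratio']:.3f}  "
              f"nu {r['transition_frequency_hz']:.2e} Hz  "
              f"mean high {r['mean_high_duration_s']:.1f} s")

    gate_rows = {}
    from promyelin.pipeline import parse_gate_expr
    for expr in GATES:
        spec, args = parse_gate_expr(expr)
        rep = pm.eval_gate_series(spec, [binaries[a] for a in args])
        gate_rows[expr] = {
            "output_frequency": rep.output_frequency,
            "input_frequencies": list(rep.input_frequencies),
        }
        print(f"  {expr}: output frequency {rep.output_frequency:.3f}")

    # phi reconciliation on the exactly-specified fixture
    p_indep = pm.expected_joint_and(0.49, 0.49, 0.0)
    p_corr = pm.expected_joint_and(0.49, 0.49, -0.27)
    a, b = pm.gen_correlated_binary(0.49, 0.49, -0.27, 10 ** 6, seed=SEED)
    emp = pm.eval_gate_series(pm.GateSpec.by_name("AND"), [a, b])
    gate_rows["phi_reconciliation"] = {
        "independent_prediction": round(p_indep, 4),
        "phi_corrected_prediction": round(p_corr, 4),
        "empirical_and_frequency": emp.output_frequency,
        "empirical_phi": float(emp.phi_matrix[0, 1]),
    }
    pio.write_json_report(gate_rows, OUT / "gate_stats.json")
    print(f"AND reconciliation: independent {p_indep:.4f} -> 0.24, "
          f"phi=-0.27 corrected {p_corr:.4f} -> 0.17, "
          f"empirical {emp.output_frequency:.4f}")
    print(f"wrote {OUT/'channel_stats.json'} and {OUT/'gate_stats.json'}")


if __name__ == "__main__":
    main()
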