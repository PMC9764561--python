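#!/usr/bin/env python
"""Single-compartment sweep diagrams (no electromagnetic induction).

Scans the cortico-thalamic coupling strengths k2 and k7 at k0 = 0,
classifies the settled response at every grid point, and refines the
three state-transition thresholds by bisection:

* tonic onset in k2 (low firing -> ~16 Hz tonic oscillation),
* SWD onset in k7 (saturated background -> 2-4 Hz spike-and-wave),
* collapse to steady low discharge in k8.

Writes sweep tables and a threshold summary under results/single_sweeps/.
"""

import json
from pathlib import Path

import numpy as np

from memtc import ModelParams, sweep_parameter
from memtc import reproduction as rep

OUT = Path("results/single_sweeps")
OUT.mkdir(parents=True, exist_ok=True)


def run_sweep(param, lo, hi, n=81):
    grid = np.linspace(lo, hi, n)
    res = sweep_parameter(param, grid, ModelParams())
    df = res.to_frame()
    path = OUT / f"sweep_{param}.csv"
    df.to_csv(path, index=False, float_format="%.9g")
    print(f"\n{param} in [{lo}, {hi}] ({n} points) -> {path}")
    # compact state sequence: collapse consecutive identical labels
    seq = []
    for v, lab in zip(grid, df["label"]):
        if not seq or seq[-1][0] != lab:
            seq.append([lab, v, v])
        else:
            seq[-1][2] = v
    for lab, a, b in seq:
        print(f"  {lab:>15s}  {a:6.3f} .. {b:6.3f}")
    return df


run_sweep("k2", 0.0, 2.0)
run_sweep("k7", 0.0, 5.0)

print("\nrefined transition thresholds (bisection, tol 1e-3):")
thresholds = {
    "k2_tonic_onset": rep.tonic_onset_k2(),
    "k7_swd_onset": rep.swd_onset_k7(coarse_step=0.05),
    "k8_low_discharge_onset": rep.low_discharge_onset_k8(),
    "tonic_frequency_at_k2_1.8_hz": rep.tonic_frequency(k2=1.8),
}
for k, v in thresholds.items():
    print(f"  {k}: {v:.4f}")
(OUT / "thresholds.json").write_text(json.dumps(thresholds, indent=2))
print(f"\nwrote {OUT / 'thresholds.json'}")
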