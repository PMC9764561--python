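#!/usr/bin/env python
"""Fold-of-cycles analysis around the k5 coexistence window (k0 = 0.5).

Two independent routes to the same bistable window:

1. simulation surrogate — forward vs backward inherited-IC sweeps of k5;
   where they settle on different attractors, a stable fixed point
   coexists with the SWD limit cycle;
2. Floquet route — single-shooting continuation of the SWD cycle
   downward in k5; the fold (LPC) is flagged where a non-trivial real
   multiplier reaches +1 and the branch is lost.

Outputs under results/cycle_bifurcations/.
"""

import json
from pathlib import Path

import numpy as np

from memtc import ModelParams, continue_cycles, settle_to_attractor
from memtc.bifurcation import nontrivial_multipliers
from memtc.parameter_sweep import hysteresis_scan

OUT = Path("results/cycle_bifurcations")
OUT.mkdir(parents=True, exist_ok=True)

params = ModelParams(k0=0.5)

print("hysteresis scan of k5 in [3.2, 4.0] (forward vs backward) ...")
grid = np.linspace(3.2, 4.0, 17)
windows, fwd, bwd = hysteresis_scan("k5", grid, params)
print("coexistence windows:", windows)

print("\ncycle continuation from k5 = 3.6 downward ...")
p_seed = params.replace(k5=3.6)
seed_traj = settle_to_attractor(p_seed)
branch, events = continue_cycles("k5", 3.0, p_seed, 1, seed_traj=seed_traj,
                                 start_value=3.6)
for cp in branch.points[-4:]:
    mu = np.abs(nontrivial_multipliers(cp.multipliers)).max()
    print(f"  k5={cp.param:.4f} T={cp.period:.4f}s max|mu_nontrivial|={mu:.4f}")
for ev in events:
    print(f"  {ev.kind} at k5 = {ev.param:.4f} "
          f"(multiplier {ev.diagnostic.real:+.4f}{ev.diagnostic.imag:+.4f}j)")

payload = {
    "coexistence_windows": windows,
    "forward_amplitudes": fwd.amplitudes().tolist(),
    "backward_amplitudes": bwd.amplitudes().tolist(),
    "grid": grid.tolist(),
    "cycle_branch": [{
        "param": c.param, "period_s": c.period,
        "multipliers": [[m.real, m.imag] for m in c.multipliers],
        "stable": c.stable,
    } for c in branch.points],
    "events": [{"type": e.kind, "param": e.param,
                "diagnostic": [e.diagnostic.real, e.diagnostic.imag]}
               for e in events],
}
(OUT / "k5_lpc.json").write_text(json.dumps(payload))
print(f"\nwrote {OUT / 'k5_lpc.json'}")
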