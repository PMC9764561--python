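# Methods

## Model and assumptions

The model is a deterministic neural-mass description: each variable is
the averaged activity of one population (PY, IN, TC, RE) rather than a
membrane potential of any single cell, and the two-compartment variant
couples a second copy one-way (left → right) through attenuated copies
of the intra-compartment connections.  Consequences used throughout the
code:

- the coupled Jacobian is block lower-triangular, so compartment-1
  dynamics, equilibria and eigenvalues are independent of compartment 2;
- the cortical activation `F` is bounded in (0, 1), so with `k0 = 0`
  every population equation is linear-decay-plus-bounded-input and
  trajectories stay bounded on the protocol horizon;
- the memristance `ρ(φ) = α₁ + 3β₁φ² ≥ α₁ > 0`, so the induction term is
  always a (state-dependent) leak on PY, never a source;
- the flux equations are integrated even at `k0 = 0` (they decouple and
  contribute a fixed eigenvalue `−λ₂`), keeping one state layout for all
  sweeps that toggle `k0`.

The model is written as ODEs: no delayed argument appears in any
equation.  Time is in seconds — asserted rather than given, but it is
the only unit choice under which the model's discharge rhythms land in
the empirically reported bands (2–4 Hz SWD, ~15–16 Hz tonic), and it
makes FFT output directly interpretable in Hz.

Symbol hygiene: the linear activation's slope/offset are named
`lin_a`/`lin_b` (the conventional α, β collide with the memristance
constants α₁, β₁), and the hard-coded 1/3 inter-compartment attenuation
is exposed as `coupling_scale` for testability, fixed to 1/3 by default.

## Integration protocol

Classical RK4 with fixed step `dt = 5e-5 s`, horizon 30 s, transient
discard 20 s, recording every 20th step (1 ms sampling → 500 Hz Nyquist,
ample for < 20 Hz content).  The default initial condition is 0.1 for
every neural variable and 0 for the flux; the model never prescribes
one, so it is fixed, documented and configurable — sweep diagrams are
reproducible bit-for-bit.  A step-size audit (halving dt at
representative points, tested in the suite) changes dominant frequencies
by < 0.05 Hz and extrema by < 1e-4.  The overflow-sensitive sigmoid
(`ln ε ≈ 12.43`) is computed with a sign branch so ε^(−x) never
overflows.

Divergent integrations (non-finite or |x| > 1e6) raise a divergence
error with the blow-up time; sweeps record such points as `DIVERGENT`
and continue.

## Waveform features and state taxonomy

Features are computed on the post-transient signal of one channel (PY1,
or PY2 for the coupled model): prominence-filtered local extrema
(scipy `find_peaks`), dominant frequency as the largest non-DC peak of
the Hann-windowed FFT (≥ 8 s of signal → bin ≤ 0.125 Hz; zero when AC
power < 1e-8), and spikes per period (modal count of prominent maxima
per fundamental period, minus one when a distinct slow-wave maximum is
present).

The discharge classes are qualitative in the literature; the numeric
rules here are the package's own, all configurable
(`ClassifierThresholds`):

| threshold | default | meaning |
|---|---|---|
| `delta_amp` | 1e-3 | steady vs oscillatory amplitude floor |
| `theta_sat` | 0.28 | low/high saturated split of the mean level |
| `theta_tonic` | 10 Hz | lower edge of the tonic band |
| `theta_slow` | 3.5 Hz | upper edge of the slow-wave band |
| `delta_prom` | 0.01·amp | peak prominence floor (see below) |
| `delta_pow` | 1e-8 | AC power floor for dominant frequency |
| `split_gap` | 0.1·amp | spike/wave maxima-cluster separation |

`theta_sat = 0.28` is the midpoint of the model's computed saturated
plateaus at default parameters (low ≈ 0.17, high ≈ 0.38).  `split_gap =
0.1·amplitude` was calibrated on the model's own discharge morphologies:
the classic SWD has a spike/wave maxima gap ≈ 0.23·amplitude and the
2-spike SWD ≈ 0.11·amplitude, while simple oscillations sit near 0; a
wider gap requirement would miss the poly-spike family.  The slow-wave
flag additionally requires ≥ 2 maxima per fundamental period, so a
weakly amplitude-modulated tonic oscillation is not mistaken for a
spike-and-wave pattern.  The peak prominence floor is
`max(0.01·amplitude, 5·σ̂)` where `σ̂` is the robust noise scale from
median successive differences — on smooth model output the second term
vanishes, on noisy surrogates it stops measurement ripple from counting
as spikes.

Classification cascade: amplitude below `delta_amp` → LOW/HIGH saturated
by mean level; else if a slow-wave maximum is present → SWD (1 spike) or
n-SWD (n ≥ 2); else TONIC / CLONIC / SLOW_WAVE by frequency band;
anything contradictory → UNCLASSIFIED.

## Sweeps, thresholds, hysteresis

Sweeps run the settle-and-classify protocol over a parameter grid with
one of three initial-condition policies: `fixed` (default, every point
from the default IC — the protocol behind the headline diagrams) or
`inherited-forward`/`inherited-backward` (each run seeded with the
previous point's final state).  Transition values are refined by
bisection on a label/feature predicate to 1e-3 in the parameter.
Disagreement between the two inherited scans (different label kind or
amplitude difference > `delta_amp`) marks coexisting attractors — a
simulation surrogate for LPC-bounded windows.  Inherited scans need grid
steps ≲ 0.1 in k₅ near the coexistence window: bigger jumps can kick the
state across the (thin) fixed-point basin.

## Equilibria, Hopf points, cycles

Equilibria: damped Newton with the analytic Jacobian to residual
‖f‖∞ < 1e-10; from poor guesses (the steep sigmoid defeats plain
damping) a Powell-dogleg globalization seeds a final Newton polish.  A
multi-start scan over a state box serves as a brute-force cross-check in
the tests.

Equilibrium continuation is pseudo-arclength (secant predictor, Newton
corrector on the extended system, adaptive step with halving on
failure), so equilibrium folds would be tracked rather than lost.  Hopf
detection watches the largest real part among complex eigenvalue pairs
between consecutive branch points and bisects each sign change to 1e-4
in the parameter; real-eigenvalue crossings are excluded by
construction.  With `k0 = 0` the flux rows contribute the constant
eigenvalue −λ₂ = −0.5; the full spectrum is always computed for
uniformity, and stable branch segments consequently report max Re
= −0.5.

Limit cycles: single shooting on (anchor state, period) with a pyramidal
phase anchor (dPY/dt = 0 at the section), monodromy matrix from RK4 on
the variational equations (dt = 1e-4 s along the cycle), Floquet
multipliers as its eigenvalues.  Converged cycles close to 1e-9 and
carry the trivial multiplier within 1e-3 of +1 (asserted in the tests).
Solutions that collapse onto an equilibrium (PY excursion < 1e-4) or
leave the plausible period range [0.02, 10] s are rejected.  Cycle
continuation is natural (parameter-stepping) with adaptive steps; LPC is
flagged when a non-trivial real multiplier crosses +1 or, at a fold
where the corrector is lost at the minimum step, by bisection on
shootability (tolerance 1e-3); a complex pair crossing the unit circle
is TR; a real multiplier at −1 (period doubling) is reported as OTHER
rather than dropped.  Events of one kind within 0.01 of each other are
merged (a fold typically announces itself both ways).

Selection rules where a scan meets several Hopf points: the coupled-k₁
"loss of steady state" is the Hopf terminating the widest contiguous
stable window in range (the k₁ branch also has a narrow unstable window
near k₁ ≈ 0.2–0.35); the k₃ "stable window lower edge" is the first
Hopf whose upper side is stable.

## Synthetic waveforms

Surrogates exist to test the feature extractors and classifier
independently of the model: raised-cosine slow wave (pure fundamental
plus offset) with n narrow Gaussian spikes per period for the SWD
family, plain sinusoids for tonic/clonic/slow-wave, constant baselines
for the saturated classes, plus seeded white noise.  Default spike width
is σ = 0.5% of the period — narrow enough that the spectral peak stays
at the fundamental rather than the spike comb (the generator guarantees
fundamental dominance for σ ≤ 0.005/f and exact spike-count recovery up
to σ ≈ 0.02/f).  Suite noise levels are relative to each clean
waveform's AC RMS (0.1 ↔ 20 dB SNR); steady-class surrogates carry only
1e-4-scale jitter, since a fixed-point trace with real measurement noise
above the classifier's amplitude floor is indistinguishable from an
oscillation by design — these surrogates do not emulate instrument noise
on flat EEG, nor 1/f background, artifacts, or non-stationarity, so
passing tests validate the decision rules, not clinical robustness.

## Known limitations and computed discrepancies

- **k₈ low-discharge onset.**  The literature value 9.152 for the
  collapse to steady low discharge does not emerge from this protocol:
  the equilibrium stabilizes via Hopf at k₈ ≈ 8.92, the SWD cycle
  persists (verified over 60 s horizons and for a range of fixed ICs)
  until ≈ 10.8, and the fixed-IC bisection therefore lands near 10.75.
  Both boundary values of the computed bistable window 8.92 < k₈ < 10.8
  are reported; the corresponding acceptance test is left failing rather
  than re-tuned.
- The tonic dominant frequency rises across the k₂ band (≈ 15.8 Hz at
  onset, ≈ 17.4 Hz at k₂ = 1.8); "≈ 16 Hz" matches just above onset.
- In bistable windows the fixed-IC protocol lands on one attractor (the
  SWD cycle at k₇ = 3, defaults) where published figures show the other;
  the hysteresis scans expose both.
- The re-stabilization Hopf in k₇ computes to 2.47 at k₀ = 0 and 2.041
  at k₀ = 0.5 — the printed "k₇ > 2.041" therefore belongs to the
  memristor case.
- One- parameter scans only; no two-parameter continuation, no branch
  switching at period doubling, no normal-form (sub/supercritical)
  coefficients — stability near a Hopf is judged by simulation.
- Analysis-script problem sizes (81–201 grid points, 17-point hysteresis
  grids) are the package's defaults for desk-scale runs; all are
  arguments.
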