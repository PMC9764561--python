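"""Model parameterization.

The model couples four neural populations per compartment — cortical
pyramidal cells (PY), cortical interneurons (IN), thalamocortical relay
cells (TC) and the thalamic reticular nucleus (RE) — through sigmoidal
(cortical) and linear (thalamic) activation functions, with an optional
flux-controlled memristor feeding the average magnetic flux back onto the
pyramidal membrane potential.  All quantities are dimensionless except
the timescale factors ``tau1..tau4`` (1/s) which set the physical time
unit; with the defaults below the model's discharge rhythms land in the
empirically reported 2–20 Hz range.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, fields

import numpy as np

__all__ = ["ModelParams", "PARAM_VECTOR_FIELDS"]

# Order of the flat parameter vector consumed by the numerical kernels.
PARAM_VECTOR_FIELDS = (
    "k0", "k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8", "k9",
    "tau1", "tau2", "tau3", "tau4",
    "eps_py", "eps_in", "eps_tc", "eps_re",
    "lin_a", "lin_b",
    "lambda1", "lambda2",
    "alpha1", "beta1",
    "coupling_scale",
    "log_sigmoid_base",  # derived: ln(sigmoid_base), precomputed for the kernels
)


@dataclass(frozen=True)
class ModelParams:
    """All constants of the single and coupled vector fields.

    Coupling strengths
    ------------------
    k0 : memristor feedback gain (0 = electromagnetic induction off; the
         comparison value used throughout is 0.5)
    k1 : PY -> PY     k2 : IN -> PY     k3 : TC -> PY
    k4 : PY -> IN     k5 : PY -> TC     k6 : RE -> TC
    k7 : PY -> RE     k8 : TC -> RE     k9 : RE -> RE

    Other constants
    ---------------
    tau1..tau4      population timescale multipliers (PY, IN, TC, RE)
    eps_*           additive input constants per population
    sigmoid_base    steepness base of the cortical activation
                    F[x] = 1 / (1 + sigmoid_base**(-x))
    lin_a, lin_b    slope/offset of the thalamic activation G[x] = a*x + b
    lambda1         electromagnetic-induction gain (flux gain from PY)
    lambda2         flux self-induction decay rate
    alpha1, beta1   memristance constants, rho(phi) = alpha1 + 3*beta1*phi**2
    coupling_scale  attenuation of the one-way inter-compartment drive
                    (the printed equations hard-code 1/3)
    """

    k0: float = 0.0
    k1: float = 1.8
    k2: float = 1.5
    k3: float = 1.0
    k4: float = 4.0
    k5: float = 3.0
    k6: float = 0.6
    k7: float = 3.0
    k8: float = 10.5
    k9: float = 0.2
    tau1: float = 26.0
    tau2: float = 32.5
    tau3: float = 2.6
    tau4: float = 2.6
    eps_py: float = -0.35
    eps_in: float = -3.4
    eps_tc: float = -2.0
    eps_re: float = -5.0
    sigmoid_base: float = 2.5e5
    lin_a: float = 2.8
    lin_b: float = 0.5
    lambda1: float = 0.9
    lambda2: float = 0.5
    alpha1: float = 0.4
    beta1: float = 0.02
    coupling_scale: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        for name in ("tau1", "tau2", "tau3", "tau4"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)!r}")
        if not self.sigmoid_base > 1:
            raise ValueError(f"sigmoid_base must exceed 1, got {self.sigmoid_base!r}")
        if not 0 < self.coupling_scale <= 1:
            raise ValueError(
                f"coupling_scale must lie in (0, 1], got {self.coupling_scale!r}"
            )
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"{f.name} must be finite, got {v!r}")

    # -- conversions -----------------------------------------------------

    def replace(self, **changes: float) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_vector(self) -> np.ndarray:
        """Flat float64 vector in ``PARAM_VECTOR_FIELDS`` order (kernel input)."""
        vals = []
        for name in PARAM_VECTOR_FIELDS:
            if name == "log_sigmoid_base":
                vals.append(math.log(self.sigmoid_base))
            else:
                vals.append(float(getattr(self, name)))
        return np.asarray(vals, dtype=np.float64)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    @classmethod
    def field_names(cls) -> tuple:
        return tuple(f.name for f in fields(cls))
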