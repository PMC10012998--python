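"""Parameters of the four-variable minimal ventricular action-potential model.

The parameter set reproduces action-potential shape, conduction velocity and
restitution of canine endocardial tissue at physiological temperature.  The
membrane potential ``u`` is dimensionless; ``u_m = 85.7*u - 84`` mV recovers
millivolts.  Time constants are in milliseconds, diffusivities in cm^2/ms.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["ModelParameters", "PARAM_NAMES"]

# Order matters: this is the packing order of the parameter vector handed to
# the compiled kernels.
PARAM_NAMES = (
    "u_o", "u_u", "u_s", "u_so", "u_w_minus", "u_w_plus", "w_inf_star",
    "theta_v", "theta_v_minus", "theta_w", "theta_o",
    "tau_v_plus", "tau_v1_minus", "tau_v2_minus",
    "tau_w1_plus", "tau_w2_plus", "tau_w1_minus", "tau_w2_minus",
    "tau_w_inf", "tau_fi", "tau_si", "tau_s1", "tau_s2",
    "tau_so1", "tau_so2", "tau_o1", "tau_o2",
    "k_w_plus", "k_w_minus", "k_s", "k_so",
    "D_par", "D_perp",
)


@dataclass(frozen=True)
class ModelParameters:
    """Constants of the minimal ventricular model (canine endocardium defaults).

    Attributes
    ----------
    u_o, u_u, u_s, u_so, u_w_minus, u_w_plus, w_inf_star
        Dimensionless voltage offsets and gate asymptote.
    theta_v, theta_v_minus, theta_w, theta_o
        Dimensionless voltage thresholds of the Heaviside gating.
    tau_*
        Gating and current time constants, ms.
    k_w_plus, k_w_minus, k_s, k_so
        Dimensionless slopes of the tanh rate functions.
    D_par, D_perp
        Diffusivity along / across the fiber direction, cm^2/ms.
    """

    u_o: float = 0.0
    u_u: float = 1.56
    u_s: float = 0.9087
    u_so: float = 0.65
    u_w_minus: float = 0.00615
    u_w_plus: float = 0.0005
    w_inf_star: float = 0.78
    theta_v: float = 0.3
    theta_v_minus: float = 0.2
    theta_w: float = 0.13
    theta_o: float = 0.006
    tau_v_plus: float = 1.4506
    tau_v1_minus: float = 55.0
    tau_v2_minus: float = 40.0
    tau_w1_plus: float = 175.0
    tau_w2_plus: float = 230.0
    tau_w1_minus: float = 40.0
    tau_w2_minus: float = 115.0
    tau_w_inf: float = 0.0273
    tau_fi: float = 0.10
    tau_si: float = 2.9013
    tau_s1: float = 2.7342
    tau_s2: float = 2.0
    tau_so1: float = 40.0
    tau_so2: float = 1.2
    tau_o1: float = 470.0
    tau_o2: float = 6.0
    k_w_plus: float = 8.0
    k_w_minus: float = 20.0
    k_s: float = 2.0994
    k_so: float = 2.0
    D_par: float = 0.010
    D_perp: float = 0.003

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            if name.startswith("tau_") and getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (self.D_par >= self.D_perp > 0):
            raise ValueError("require D_par >= D_perp > 0")

    def as_vector(self) -> np.ndarray:
        """Pack into the flat float64 vector consumed by the kernels."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=np.float64)

    def replace(self, **kwargs) -> "ModelParameters":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {n: getattr(self, n) for n in PARAM_NAMES}

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        unknown = set(d) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "ModelParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))
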