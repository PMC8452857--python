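"""Electrochemical rate coefficients of the corrosion progression rule.

The progression update weights four contributions — the cell's own reaction
activity, the activity of its orthogonal neighbors, the raw state of its
diagonal neighbors, and a stochastic term — by coefficients k1..k4.  Each
coefficient shares one environmental factor built from pH, the metal/solution
potential difference, temperature, and the concentration, diffusivity and
charge of the reaction species; they differ only by a distance-dependent
discount factor λ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import ModelParams, ParameterError

__all__ = [
    "RateCoefficients",
    "reaction_activity",
    "step_band",
    "ph_response",
    "rate_coefficient",
    "coefficients",
]


@dataclass(frozen=True)
class RateCoefficients:
    """The four weights of the progression update, in state units per step
    per activity unit.  Invariant for the default discounts: k1 >= k2 >= k3
    (neighbors farther away play a smaller role)."""

    k1: float
    k2: float
    k3: float
    k4: float


def reaction_activity(s):
    """Chemical reaction activity f(s) = 128^2 - (s - 128)^2 of a cell state.

    The activity is a downward parabola on the 0–255 corrosion scale: zero
    for an intact cell, maximal (128^2 = 16384) at half corrosion, and back
    to zero at full corrosion.  Accepts scalars or arrays; inputs are assumed
    pre-clamped to [0, 255].
    """
    s = np.asarray(s, dtype=np.float64)
    out = 128.0**2 - (s - 128.0) ** 2
    return out if out.ndim else float(out)


def step_band(pH: float) -> int:
    """Passivation band indicator: 0 for pH in the closed band [4, 8.5]
    (passive regime), 1 otherwise."""
    return 0 if 4.0 <= pH <= 8.5 else 1


def ph_response(pH: float, mode: str = "quadratic") -> float:
    """pH factor of the environmental rate.

    - ``as_printed``: (pH-7)^2 * step_band(pH) — the literal form; zero for
      any pH inside the passive band, including the physiological default.
    - ``quadratic`` (default): 1 + (pH-7)^2 — keeps a unit baseline so the
      physiological condition corrodes, and grows monotonically away from
      neutral; reproduces the observed monotone pH trend on 7–10.
    - ``banded``: 1 + (pH-7)^2 * step_band(pH) — unit baseline, band-gated
      quadratic boost.
    """
    if mode == "as_printed":
        return (pH - 7.0) ** 2 * step_band(pH)
    if mode == "quadratic":
        return 1.0 + (pH - 7.0) ** 2
    if mode == "banded":
        return 1.0 + (pH - 7.0) ** 2 * step_band(pH)
    raise ParameterError(f"unknown ph_mode {mode!r}")


def rate_coefficient(params: ModelParams, lam: float) -> float:
    """One rate coefficient: lam * ph_response(pH) * e^(phi_M - phi_S) * (1/T) * C * D * z.

    The exponential acts on the potential difference in volts; the reciprocal
    temperature factor makes corrosion slightly slower at higher T over the
    physiological range.
    """
    if params.T <= 0:
        raise ParameterError(f"absolute temperature must be positive, got T={params.T}")
    return (
        lam
        * ph_response(params.pH, params.ph_mode)
        * math.exp(params.phi_M - params.phi_S)
        * (1.0 / params.T)
        * params.C
        * params.D
        * params.z
    )


def coefficients(params: ModelParams) -> RateCoefficients:
    """Compute k1..k4 from the parameter set (one shared environmental
    factor, four discount factors)."""
    return RateCoefficients(
        k1=rate_coefficient(params, params.lambda1),
        k2=rate_coefficient(params, params.lambda2),
        k3=rate_coefficient(params, params.lambda3),
        k4=rate_coefficient(params, params.lambda4),
    )
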