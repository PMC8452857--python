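"""Simulation parameter set: definition, validation, serialization.

The environmental parameters (pH, electrode potentials, temperature, and the
concentration / diffusivity / charge of the reaction species) feed the rate
coefficients of the progression rule; the remaining fields control the
lattice, the run length, pit initiation, and stochastic variants.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
import warnings
from dataclasses import dataclass
from typing import Any

import yaml

__all__ = [
    "ModelParams",
    "ParameterError",
    "default_params",
    "validate",
    "load_params",
    "save_params",
]


class ParameterError(ValueError):
    """Raised for non-physical or structurally invalid parameter values."""


#: Recommended stability ranges for the environmental inputs.  Values outside
#: these ranges are legal (the model is not limited to them) but warned about.
RECOMMENDED_RANGES: dict[str, tuple[float, float]] = {
    "pH": (7.0, 10.0),
    "phi_M": (0.1, 1.0),
    "phi_S": (0.1, 1.0),
    "T": (297.15, 313.15),
    "C": (0.1, 0.5),
    "D": (0.1, 0.5),
    "z": (0.1, 0.5),
}


@dataclass
class ModelParams:
    """All parameters of one corrosion simulation.

    Environmental fields (units):

    - ``pH``   — solution acidity (dimensionless)
    - ``phi_M``, ``phi_S`` — metal / solution potentials (V)
    - ``T``    — absolute temperature (K)
    - ``C``    — reaction-species concentration (M/dm^3)
    - ``D``    — reaction-species diffusivity (dm^2/s)
    - ``z``    — reaction-species charge (faraday)

    Numerical / lattice fields:

    - ``steps``       — simulation length in time steps; must be divisible by
      ``emit_every`` (a frame is rendered every ``emit_every`` steps)
    - ``lattice_h``, ``lattice_w`` — lattice dimensions in cells
    - ``lambda1..4``  — discount factors of the four rate coefficients, each
      nominally in [1, 3]; defaults tie the discount to neighbor distance
      (self > orthogonal > diagonal)
    - ``alpha_mean``  — mean per-step initialization-potential increment
    - ``theta``       — pit-initiation threshold on the neighborhood score
    - ``s_init``      — corrosion state assigned to a freshly initiated cell
    - ``ph_mode``     — pH response variant: ``quadratic`` (default),
      ``as_printed`` or ``banded`` (see :mod:`pitcorr.kinetics`)
    - ``alpha_dist``  — ``uniform`` (per-cell Uniform(0, 2*alpha_mean)) or
      ``constant`` (deterministic shared increment)
    - ``boundary``    — ``zero`` (inert sample edge) or ``periodic``
    - ``diag_activity`` — apply the activity parabola to diagonal neighbors
      too, instead of their raw state
    - ``seed``        — RNG seed; ``None`` means nondeterministic
    """

    pH: float = 7.4
    phi_M: float = 0.23
    phi_S: float = 0.2
    T: float = 310.15
    C: float = 0.2
    D: float = 0.3
    z: float = 0.2
    steps: int = 100
    emit_every: int = 20
    lattice_h: int = 200
    lattice_w: int = 200
    lambda1: float = 3.0
    lambda2: float = 2.0
    lambda3: float = 1.0
    lambda4: float = 1.0
    alpha_mean: float = 1.0
    theta: float = 50.0
    s_init: float = 1.0
    ph_mode: str = "quadratic"
    alpha_dist: str = "uniform"
    boundary: str = "zero"
    diag_activity: bool = False
    seed: int | None = None

    def replace(self, **changes: Any) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)


def default_params() -> ModelParams:
    """Return the default parameter set.

    Environmental defaults are the reference values of the model (pH 7.4,
    φM 0.23 V, φS 0.2 V, T 310.15 K, C 0.2, D 0.3, z 0.2, 100 steps with a
    frame every 20 on a 200×200 lattice).  The initiation constants are
    calibrated so that the expected interior initiation time,
    3·theta/(5·alpha_mean) = 30 steps, falls between the first (t=20,
    uncorroded) and second (t=40, corroded) emitted frames.
    """
    return ModelParams()


def validate(params: ModelParams) -> list[str]:
    """Validate a parameter set.

    Non-physical values (``T`` <= 0, lattice dimensions < 3, ``steps`` <= 0,
    ``emit_every`` not dividing ``steps``, unknown mode strings) raise
    :class:`ParameterError`.  Values merely outside the recommended stability
    ranges produce one warning each; the returned list contains the warning
    messages (empty when everything is in range).
    """
    if params.T <= 0:
        raise ParameterError(f"absolute temperature must be positive, got T={params.T}")
    if params.lattice_h < 3 or params.lattice_w < 3:
        raise ParameterError(
            f"lattice dimensions must be at least 3x3, got {params.lattice_h}x{params.lattice_w}"
        )
    if params.steps <= 0:
        raise ParameterError(f"steps must be a positive integer, got {params.steps}")
    if params.emit_every <= 0:
        raise ParameterError(f"emit_every must be a positive integer, got {params.emit_every}")
    if params.steps % params.emit_every != 0:
        raise ParameterError(
            f"steps ({params.steps}) must be divisible by emit_every ({params.emit_every})"
        )
    if params.s_init <= 0:
        raise ParameterError(f"s_init must be positive, got {params.s_init}")
    if params.theta < 0:
        raise ParameterError(f"theta must be nonnegative, got {params.theta}")
    if params.ph_mode not in ("quadratic", "as_printed", "banded"):
        raise ParameterError(f"unknown ph_mode {params.ph_mode!r}")
    if params.alpha_dist not in ("uniform", "constant"):
        raise ParameterError(f"unknown alpha_dist {params.alpha_dist!r}")
    if params.boundary not in ("zero", "periodic"):
        raise ParameterError(f"unknown boundary {params.boundary!r}")

    msgs: list[str] = []
    for name, (lo, hi) in RECOMMENDED_RANGES.items():
        v = getattr(params, name)
        if not (lo <= v <= hi):
            msgs.append(
                f"{name}={v} is outside the recommended stability range [{lo}, {hi}]"
            )
    for i in (1, 2, 3, 4):
        lam = getattr(params, f"lambda{i}")
        if not (1.0 <= lam <= 3.0):
            msgs.append(f"lambda{i}={lam} is outside the nominal discount range [1, 3]")
    for m in msgs:
        warnings.warn(m, stacklevel=2)
    return msgs


def save_params(params: ModelParams, path: str | pathlib.Path) -> None:
    """Serialize to YAML (``.yaml``/``.yml``) or JSON (``.json``) by suffix."""
    path = pathlib.Path(path)
    d = params.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    elif path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        raise ParameterError(f"unsupported parameter-file suffix {path.suffix!r}")


def load_params(path: str | pathlib.Path, **overrides: Any) -> ModelParams:
    """Load a parameter file; keyword overrides take precedence over the file."""
    path = pathlib.Path(path)
    if path.suffix in (".yaml", ".yml"):
        d = yaml.safe_load(path.read_text()) or {}
    elif path.suffix == ".json":
        d = json.loads(path.read_text())
    else:
        raise ParameterError(f"unsupported parameter-file suffix {path.suffix!r}")
    d.update(overrides)
    return ModelParams.from_dict(d)
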