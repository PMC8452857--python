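"""The two-sub-model cellular automaton of multi-pit corrosion.

A square lattice of cells represents the metal surface; each cell carries a
corrosion state S on a 0 (intact) to 255 (fully corroded) scale and an
initialization potential I.  Each synchronous time step performs, against
the previous step's buffers:

1. *Potential accumulation* — every uncorroded cell's I grows by a random
   increment with mean ``alpha_mean`` (per-cell draws, so discrete pits can
   nucleate at distinct times rather than the whole surface at once).
2. *Pit initiation* — an uncorroded cell initiates when its Von Neumann
   neighborhood score, (I(u) + sum of the 4 orthogonal neighbors' I) / 3,
   exceeds the threshold ``theta``; its state jumps to ``s_init``.
3. *Progression* — every previously corroded cell x updates by
   ``S + k1*f(S(x)) + k2*sum_orth f(S) + k3*sum_diag S + k4*N(0,1)``,
   where f is the reaction-activity parabola and the sums run over the
   Moore neighborhood (orthogonal terms through f, diagonal terms raw, as
   the model defines).  The result is clamped to [0, 255].

Out-of-lattice neighbors contribute 0 with the default inert boundary;
periodic wrap-around is available.  Corrosion status is irreversible: noise
may transiently lower S but never clears the corroded mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from . import metrics as _metrics
from .kinetics import RateCoefficients, coefficients, reaction_activity
from .params import ModelParams, ParameterError, validate
from .timescale import Calibration, frame_time

__all__ = [
    "LatticeState",
    "Frame",
    "init_lattice",
    "accumulate_potential",
    "initiation_scores",
    "apply_initiation",
    "progress_step",
    "quantize",
    "run",
]

logger = logging.getLogger(__name__)

# Neighbor offsets as (row, col) shifts.  The summation order below is part
# of the reproducibility contract (floating-point addition is not
# associative): orthogonal = up, down, left, right; diagonal = up-right,
# up-left, down-left, down-right.
_ORTH = ((-1, 0), (1, 0), (0, -1), (0, 1))
_DIAG = ((-1, 1), (-1, -1), (1, -1), (1, 1))


@dataclass
class LatticeState:
    """Paired 2-D fields of one simulation instant: corrosion state ``S``
    (real-valued in [0, 255]), initialization potential ``I``, the
    irreversible ``corroded`` mask, and the step counter ``t``."""

    S: np.ndarray
    I: np.ndarray
    corroded: np.ndarray
    t: int

    def copy(self) -> "LatticeState":
        return LatticeState(self.S.copy(), self.I.copy(), self.corroded.copy(), self.t)


@dataclass(frozen=True)
class Frame:
    """An emitted 8-bit grayscale rendering of the corrosion state: 0 is
    uncorroded (black), 255 fully corroded (white)."""

    img: np.ndarray
    step: int
    physical_time_h: float


def init_lattice(h: int, w: int) -> LatticeState:
    """A pristine surface at t=0: S and I identically zero, nothing corroded."""
    if h < 3 or w < 3:
        raise ParameterError(f"lattice dimensions must be at least 3x3, got {h}x{w}")
    return LatticeState(
        S=np.zeros((h, w)),
        I=np.zeros((h, w)),
        corroded=np.zeros((h, w), dtype=bool),
        t=0,
    )


def _shift(a: np.ndarray, dr: int, dc: int, boundary: str) -> np.ndarray:
    """Field value of the neighbor at offset (dr, dc), for every cell:
    result[r, c] = a[r + dr, c + dc]."""
    dr, dc = -dr, -dc
    if boundary == "periodic":
        return np.roll(np.roll(a, dr, axis=0), dc, axis=1)
    out = np.zeros_like(a)
    h, w = a.shape
    rs_src = slice(max(0, -dr), h - max(0, dr))
    cs_src = slice(max(0, -dc), w - max(0, dc))
    rs_dst = slice(max(0, dr), h - max(0, -dr))
    cs_dst = slice(max(0, dc), w - max(0, -dc))
    out[rs_dst, cs_dst] = a[rs_src, cs_src]
    return out


def accumulate_potential(
    state: LatticeState,
    alpha_mean: float,
    rng: np.random.Generator,
    dist: str = "uniform",
) -> LatticeState:
    """Grow the initialization potential of every uncorroded cell.

    ``uniform`` draws one Uniform(0, 2*alpha_mean) increment per cell
    (expectation ``alpha_mean``); ``constant`` adds ``alpha_mean`` exactly.
    Corroded cells' I is frozen but remains visible to their neighbors'
    initiation scores.  One full-lattice field is drawn per call regardless
    of the mask, so the RNG stream depends only on the lattice shape.
    """
    if dist == "uniform":
        incr = rng.uniform(0.0, 2.0 * alpha_mean, size=state.I.shape)
    elif dist == "constant":
        incr = np.full(state.I.shape, float(alpha_mean))
    else:
        raise ParameterError(f"unknown alpha_dist {dist!r}")
    new = state.copy()
    new.I = state.I + np.where(state.corroded, 0.0, incr)
    return new


def initiation_scores(state: LatticeState, boundary: str = "zero") -> np.ndarray:
    """Von Neumann neighborhood score (I(u) + sum of 4 orthogonal neighbors)/3
    for every cell; out-of-lattice neighbors contribute 0."""
    I = state.I
    s = I + _shift(I, -1, 0, boundary)
    s = s + _shift(I, 1, 0, boundary)
    s = s + _shift(I, 0, -1, boundary)
    s = s + _shift(I, 0, 1, boundary)
    return s / 3.0


def apply_initiation(
    state: LatticeState, theta: float, s_init: float, boundary: str = "zero"
) -> LatticeState:
    """Initiate pits: every uncorroded cell whose score exceeds ``theta``
    becomes corroded with state ``s_init``.  All decisions use the same
    pre-update I buffer (synchronous); already-corroded cells are untouched."""
    scores = initiation_scores(state, boundary)
    fresh = (~state.corroded) & (scores > theta)
    new = state.copy()
    new.S = np.where(fresh, float(s_init), state.S)
    new.corroded = state.corroded | fresh
    return new


def _progress_field(
    S: np.ndarray,
    corroded: np.ndarray,
    k: RateCoefficients,
    noise: np.ndarray,
    boundary: str = "zero",
    diag_activity: bool = False,
) -> np.ndarray:
    """New S field given the previous S buffer and a pre-drawn noise field.

    The summation order (self, then orthogonal up/down/left/right, then
    diagonal ur/ul/dl/dr, then noise) is fixed so runs are bit-reproducible.
    """
    fS = reaction_activity(S)
    orth = _shift(fS, *_ORTH[0], boundary)
    for dr, dc in _ORTH[1:]:
        orth = orth + _shift(fS, dr, dc, boundary)
    dbase = fS if diag_activity else S
    diag = _shift(dbase, *_DIAG[0], boundary)
    for dr, dc in _DIAG[1:]:
        diag = diag + _shift(dbase, dr, dc, boundary)
    new = S + k.k1 * fS
    new = new + k.k2 * orth
    new = new + k.k3 * diag
    new = new + k.k4 * noise
    return np.where(corroded, np.clip(new, 0.0, 255.0), 0.0)


def progress_step(
    state: LatticeState,
    k: RateCoefficients,
    rng: np.random.Generator,
    boundary: str = "zero",
    diag_activity: bool = False,
) -> LatticeState:
    """Advance corrosion on every corroded cell by one synchronous step.

    One standard-normal field is drawn per call (the stochastic term, one
    independent draw per cell); uncorroded cells keep S = 0 — noise never
    initiates corrosion.
    """
    noise = rng.standard_normal(state.S.shape)
    new = state.copy()
    new.S = _progress_field(state.S, state.corroded, k, noise, boundary, diag_activity)
    return new


def quantize(S: np.ndarray) -> np.ndarray:
    """Render a real-valued state field as an 8-bit grayscale image."""
    return np.round(np.clip(S, 0.0, 255.0)).astype(np.uint8)


def run(
    params: ModelParams,
    calibration: Calibration | None = None,
    collect_metrics: bool = True,
) -> tuple[list[Frame], list[_metrics.MetricsRecord]]:
    """Run a full simulation: ``params.steps`` iterations of accumulate →
    initiate → progress, emitting a frame (and its metrics record) at t = 0
    and every ``emit_every`` steps.

    RNG stream order per step: the uniform accumulation field first, then
    the per-cell noise field — identical seeds give bit-identical runs.
    Returns the emitted frames and, unless ``collect_metrics`` is False, one
    :class:`~pitcorr.metrics.MetricsRecord` per frame.
    """
    validate(params)
    if calibration is None:
        calibration = Calibration(n_pixels=params.lattice_w, n_steps=params.steps)
    rng = np.random.default_rng(params.seed)
    k = coefficients(params)
    state = init_lattice(params.lattice_h, params.lattice_w)

    frames: list[Frame] = []
    records: list[_metrics.MetricsRecord] = []

    def emit(st: LatticeState) -> None:
        img = quantize(st.S)
        t_h = frame_time(st.t // params.emit_every, params.emit_every, calibration)
        frames.append(Frame(img=img, step=st.t, physical_time_h=t_h))
        if collect_metrics:
            records.append(_metrics.metrics_record(img, st.t))
        logger.info(
            "step %d (%.1f h): corroded %.2f%%",
            st.t,
            t_h,
            100.0 * np.count_nonzero(img) / img.size,
        )

    emit(state)
    S, I, mask = state.S, state.I, state.corroded
    for t in range(1, params.steps + 1):
        # accumulation (uniform field drawn first in the stream)
        if params.alpha_dist == "uniform":
            incr = rng.uniform(0.0, 2.0 * params.alpha_mean, size=I.shape)
        else:
            incr = np.full(I.shape, params.alpha_mean)
        I = I + np.where(mask, 0.0, incr)
        # initiation, scored on the freshly accumulated I buffer
        scores = initiation_scores(
            LatticeState(S, I, mask, t), boundary=params.boundary
        )
        fresh = (~mask) & (scores > params.theta)
        # progression on the cells corroded *before* this step, reading the
        # previous-step S buffer
        noise = rng.standard_normal(S.shape)
        S = _progress_field(S, mask, k, noise, params.boundary, params.diag_activity)
        S[fresh] = params.s_init
        mask = mask | fresh
        if t % params.emit_every == 0:
            emit(LatticeState(S, I, mask, t))
    return frames, records
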