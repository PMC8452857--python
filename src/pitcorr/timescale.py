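"""Physical calibration of the lattice and unit conversions.

The simulation lattice is mapped to a physical sample surface and the step
counter to experiment time: a 0.2 × 0.2 mm surface imaged as 200 × 200
pixels gives 1 µm per pixel, and a 4-day experiment simulated in 100 steps
gives 57.6 min per step, so emitted frames 1..5 (every 20 steps) correspond
to 19.2, 38.4, 57.6, 76.8 and 96 h.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "Calibration",
    "pixel_length",
    "step_duration",
    "frame_time",
    "convert_rate",
    "MIL_IN_MM",
]

#: 1 mil = 0.0254 mm; converts mils/year (mpy) to mm/year.
MIL_IN_MM = 0.0254

#: A day is exactly 1440 minutes.
MINUTES_PER_DAY = 1440.0


@dataclass(frozen=True)
class Calibration:
    """Space/time equivalence of one simulation.

    ``physical_width_mm`` over ``n_pixels`` fixes the pixel length;
    ``total_time_days`` over ``n_steps`` fixes the step duration.
    """

    physical_width_mm: float = 0.2
    n_pixels: int = 200
    total_time_days: float = 4.0
    n_steps: int = 100

    def __post_init__(self) -> None:
        if self.physical_width_mm <= 0 or self.total_time_days <= 0:
            raise ValueError("physical width and total time must be positive")
        if self.n_pixels <= 0:
            raise ValueError(f"n_pixels must be positive, got {self.n_pixels}")
        if self.n_steps <= 0:
            raise ValueError(f"n_steps must be positive, got {self.n_steps}")


def pixel_length(cal: Calibration) -> float:
    """Physical length of one pixel in micrometers."""
    return cal.physical_width_mm / cal.n_pixels * 1000.0


def step_duration(cal: Calibration) -> float:
    """Physical duration of one time step in minutes."""
    return cal.total_time_days * MINUTES_PER_DAY / cal.n_steps


def frame_time(frame_index: int, emit_every: int, cal: Calibration) -> float:
    """Physical time of the ``frame_index``-th emitted frame, in hours."""
    if frame_index < 0:
        raise ValueError(f"frame index must be nonnegative, got {frame_index}")
    return frame_index * emit_every * step_duration(cal) / 60.0


_RATE_IN_MM_PER_YEAR = {"mpy": MIL_IN_MM, "mm_per_year": 1.0}


def convert_rate(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a corrosion rate between mils/year (``mpy``) and
    ``mm_per_year`` using 1 mil = 0.0254 mm."""
    try:
        f = _RATE_IN_MM_PER_YEAR[from_unit]
        t = _RATE_IN_MM_PER_YEAR[to_unit]
    except KeyError as e:
        raise ValueError(
            f"unknown corrosion-rate unit {e.args[0]!r}; expected one of "
            f"{sorted(_RATE_IN_MM_PER_YEAR)}"
        ) from None
    return value * f / t
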