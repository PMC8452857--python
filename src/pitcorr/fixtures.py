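"""Deterministic test images with closed-form statistics.

Every fixture kind has analytically known values for the metric suite, so
metric arithmetic can be pinned without downloads: ``constant`` (all one
level), ``two_level`` (stated fractions at two levels), ``uniform_noise``
and ``gaussian_noise`` (stated pre-quantization moments), ``blobs`` (an
exact count of corroded pixels in non-overlapping disks), ``rank_one``
(an exactly rank-1 integer image), and ``sequence`` (frames with
monotonically growing corroded fraction and intensity, emulating a
progression run).  Same spec + seed always gives identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FixtureSpec", "make_image", "make_sequence"]

_KINDS = (
    "constant",
    "two_level",
    "uniform_noise",
    "gaussian_noise",
    "blobs",
    "rank_one",
    "sequence",
)


@dataclass
class FixtureSpec:
    """Recipe for one deterministic fixture image or sequence.

    Per-kind parameters (others ignored):

    - constant: ``level``
    - two_level: ``levels`` (two grey values), ``fraction`` of the first
    - uniform_noise: integer levels drawn uniformly from [``low``, ``high``]
    - gaussian_noise: pre-quantization ``mean`` and ``std``, clipped to 0–255
    - blobs: ``n_blobs`` non-overlapping disks of exactly ``blob_pixels``
      pixels each at grey value ``level``
    - rank_one: outer product of a random integer row profile and a random
      binary column profile (exactly rank <= 1 after 8-bit storage)
    - sequence: ``length`` frames, corroded fraction growing to
      ``max_fraction`` and intensity to ``max_level``
    """

    kind: str
    h: int = 100
    w: int = 100
    seed: int = 0
    level: int = 255
    levels: tuple[int, int] = (0, 255)
    fraction: float = 0.5
    low: int = 0
    high: int = 255
    mean: float = 128.0
    std: float = 30.0
    n_blobs: int = 3
    blob_pixels: int = 12
    length: int = 6
    max_fraction: float = 0.6
    max_level: int = 200


def _check(spec: FixtureSpec) -> None:
    if spec.kind not in _KINDS:
        raise ValueError(f"unknown fixture kind {spec.kind!r}")
    if spec.h < 1 or spec.w < 1:
        raise ValueError(f"bad fixture dimensions {spec.h}x{spec.w}")
    for lv in (spec.level, *spec.levels, spec.low, spec.high):
        if not (0 <= lv <= 255):
            raise ValueError(f"grey level {lv} outside [0, 255]")
    if not (0.0 <= spec.fraction <= 1.0):
        raise ValueError(f"fraction {spec.fraction} outside [0, 1]")


def _disk_pixels(cr: int, cc: int, n: int, h: int, w: int) -> np.ndarray:
    """Indices of the n lattice pixels nearest (cr, cc): a disk of exactly
    n pixels (distance ties broken by row-major order)."""
    r = int(np.ceil(np.sqrt(n))) + 2
    rows = np.arange(max(0, cr - r), min(h, cr + r + 1))
    cols = np.arange(max(0, cc - r), min(w, cc + r + 1))
    rr, cc2 = np.meshgrid(rows, cols, indexing="ij")
    d2 = (rr - cr) ** 2 + (cc2 - cc) ** 2
    flat = np.argsort(d2.ravel(), kind="stable")[:n]
    return rr.ravel()[flat] * w + cc2.ravel()[flat]


def make_image(spec: FixtureSpec) -> np.ndarray:
    """Build the 8-bit fixture image described by ``spec``."""
    _check(spec)
    if spec.kind == "sequence":
        raise ValueError("use make_sequence for the 'sequence' kind")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.h, spec.w
    n = h * w
    if spec.kind == "constant":
        return np.full((h, w), spec.level, dtype=np.uint8)
    if spec.kind == "two_level":
        n_first = round(spec.fraction * n)
        flat = np.full(n, spec.levels[1], dtype=np.uint8)
        flat[:n_first] = spec.levels[0]
        rng.shuffle(flat)
        return flat.reshape(h, w)
    if spec.kind == "uniform_noise":
        return rng.integers(spec.low, spec.high + 1, size=(h, w)).astype(np.uint8)
    if spec.kind == "gaussian_noise":
        a = rng.normal(spec.mean, spec.std, size=(h, w))
        return np.round(np.clip(a, 0, 255)).astype(np.uint8)
    if spec.kind == "blobs":
        if spec.n_blobs * spec.blob_pixels > n:
            raise ValueError("blobs do not fit on the lattice")
        img = np.zeros(n, dtype=np.uint8)
        placed = 0
        for _ in range(10000):
            if placed == spec.n_blobs:
                break
            cr = int(rng.integers(0, h))
            cc = int(rng.integers(0, w))
            idx = _disk_pixels(cr, cc, spec.blob_pixels, h, w)
            if len(idx) < spec.blob_pixels or np.any(img[idx]):
                continue
            img[idx] = spec.level
            placed += 1
        else:
            raise ValueError("could not place non-overlapping blobs")
        return img.reshape(h, w)
    if spec.kind == "rank_one":
        # integer row profile x binary column profile: entries stay in
        # [0, 255] and the stored image is exactly rank <= 1
        u = rng.integers(0, 256, size=h)
        v = rng.integers(0, 2, size=w)
        return np.outer(u, v).astype(np.uint8)
    raise AssertionError("unreachable")


def make_sequence(spec: FixtureSpec) -> list[np.ndarray]:
    """Frames with monotonically growing corroded fraction and intensity.

    Frame 0 is all-zero (pristine surface); frame k corrodes the first
    ``round(k/(L-1) * max_fraction * Npix)`` pixels of one fixed seeded
    permutation (nested prefixes, so the corroded set only grows) at level
    ``round(k/(L-1) * max_level)``.
    """
    _check(spec)
    if spec.kind != "sequence":
        raise ValueError(f"make_sequence requires kind='sequence', got {spec.kind!r}")
    if spec.length < 2:
        raise ValueError("sequence length must be at least 2")
    rng = np.random.default_rng(spec.seed)
    n = spec.h * spec.w
    order = rng.permutation(n)
    frames = []
    for k in range(spec.length):
        g = k / (spec.length - 1)
        m = round(g * spec.max_fraction * n)
        lvl = max(1, round(g * spec.max_level)) if m else 0
        flat = np.zeros(n, dtype=np.uint8)
        flat[order[:m]] = lvl
        frames.append(flat.reshape(spec.h, spec.w))
    return frames
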