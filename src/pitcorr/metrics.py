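"""Image statistics quantifying corrosion progression.

Ten measures computed on any 8-bit grayscale frame, simulated or micrograph:
histogram moments (mean, standard deviation, skew, kurtosis), corroded-area
percentage, histogram energy and entropy, spectral power, contrast, and two
wavelet/SVD features.  A per-frame record and a per-sequence table mirror the
simulation platform's output; a least-squares trend slope quantifies
near-constancy of a measure across repeat images of one physical sample.

Conventions (documented because the literature varies): moments are
population moments of the 256-bin grey-level histogram; skew and kurtosis
are undefined (NaN) for a constant image; kurtosis is the plain fourth
standardized moment (3 for a normal distribution, not excess); entropy is in
bits; spectral power is the sum of squared magnitudes of the un-normalized
2-D DFT, equal to Npix * sum(I^2) by Parseval's identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as _dc_fields

import numpy as np
import pandas as pd
from scipy import stats as _sstats

__all__ = [
    "MetricsRecord",
    "METRIC_COLUMNS",
    "grey_histogram",
    "histogram_moments",
    "corroded_percent",
    "energy",
    "entropy",
    "spectral_power",
    "contrast",
    "wavelet_svd_features",
    "metrics_record",
    "metrics_table",
    "metric_trend",
]

#: Column order of the metrics table (stable across versions).
METRIC_COLUMNS = [
    "step",
    "mean",
    "std",
    "skew",
    "corroded_pct",
    "kurtosis",
    "energy",
    "entropy_bits",
    "power",
    "contrast",
    "wavelet_s1",
    "wavelet_s2",
]


@dataclass(frozen=True)
class MetricsRecord:
    """The ten statistics of one frame (plus its step index).

    ``skew`` and ``kurtosis`` are NaN exactly when ``std`` is 0 (e.g. the
    fully uncorroded initial frame).
    """

    step: int
    mean: float
    std: float
    skew: float
    corroded_pct: float
    kurtosis: float
    energy: float
    entropy_bits: float
    power: float
    contrast: float
    wavelet_s1: float
    wavelet_s2: float

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in _dc_fields(self)}


def _as_uint8(img) -> np.ndarray:
    a = np.asarray(img)
    if a.size == 0:
        raise ValueError("empty image")
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {a.shape}")
    if a.dtype == np.uint8:
        return a
    if np.any((a < 0) | (a > 255)):
        raise ValueError("pixel values outside [0, 255]; quantize first")
    return np.round(a).astype(np.uint8)


def grey_histogram(img) -> np.ndarray:
    """Probability vector over the 256 grey levels; sums to 1."""
    a = _as_uint8(img)
    counts = np.bincount(a.ravel(), minlength=256)
    return counts / a.size


def histogram_moments(p) -> tuple[float, float, float, float]:
    """(mean, std, skew, kurtosis) of a grey-level probability vector.

    Population moments; skew is the third and kurtosis the fourth
    standardized moment (non-excess).  Both are NaN when std is 0.
    """
    p = np.asarray(p, dtype=np.float64)
    levels = np.arange(p.size, dtype=np.float64)
    mean = float(p @ levels)
    d = levels - mean
    var = float(p @ d**2)
    std = math.sqrt(var)
    if std == 0.0:
        return mean, 0.0, math.nan, math.nan
    skew = float(p @ d**3) / std**3
    kurt = float(p @ d**4) / std**4
    return mean, std, skew, kurt


def corroded_percent(img) -> float:
    """Percentage of corroded pixels: nonzero pixels over total, times 100."""
    a = _as_uint8(img)
    return 100.0 * np.count_nonzero(a) / a.size


def energy(p) -> float:
    """Histogram energy sum(p^2): 1 for a constant image, 1/256 for a
    uniform histogram; lower means intensities spread over more levels."""
    p = np.asarray(p, dtype=np.float64)
    return float(p @ p)


def entropy(p) -> float:
    """Shannon entropy of the grey-level distribution in bits (0 to 8)."""
    return float(_sstats.entropy(np.asarray(p, dtype=np.float64), base=2))


def spectral_power(img) -> float:
    """Total spectral power: sum of squared magnitudes of the un-normalized
    2-D DFT.  Equals Npix * sum(I^2) (Parseval), i.e. Npix^2*(mean^2+std^2)."""
    a = _as_uint8(img).astype(np.float64)
    return float(np.sum(np.abs(np.fft.fft2(a)) ** 2))


def contrast(img) -> float:
    """Difference between the maximum and minimum pixel intensity."""
    a = _as_uint8(img)
    return float(int(a.max()) - int(a.min()))


def _haar_approx(a: np.ndarray) -> np.ndarray:
    """Approximation subband of a single-level 2-D Haar decomposition.

    Orthonormal Haar: each 2x2 block maps to (sum of the four pixels)/2.
    Odd dimensions are edge-padded to even first.
    """
    h, w = a.shape
    if h % 2:
        a = np.vstack([a, a[-1:]])
    if w % 2:
        a = np.hstack([a, a[:, -1:]])
    return (a[0::2, 0::2] + a[0::2, 1::2] + a[1::2, 0::2] + a[1::2, 1::2]) / 2.0


def wavelet_svd_features(img) -> tuple[float, float]:
    """Two largest singular values of the Haar approximation subband,
    scaled by the subband's row count; (s1, s2) with s1 >= s2 >= 0.

    The scaling makes the features roughly independent of lattice size; the
    exact normalization is a package convention (see the methods note) and
    the pipeline is pluggable via this function.
    """
    a = _as_uint8(img).astype(np.float64)
    if a.shape[0] < 2 or a.shape[1] < 2:
        raise ValueError(f"image too small for a wavelet decomposition: {a.shape}")
    approx = _haar_approx(a)
    s = np.linalg.svd(approx, compute_uv=False) / approx.shape[0]
    s2 = float(s[1]) if s.size > 1 else 0.0
    return float(s[0]), s2


def metrics_record(img, step: int = 0) -> MetricsRecord:
    """Assemble all ten measures of one frame into a :class:`MetricsRecord`."""
    a = _as_uint8(img)
    p = grey_histogram(a)
    mean, std, skew, kurt = histogram_moments(p)
    s1, s2 = wavelet_svd_features(a)
    return MetricsRecord(
        step=int(step),
        mean=mean,
        std=std,
        skew=skew,
        corroded_pct=corroded_percent(a),
        kurtosis=kurt,
        energy=energy(p),
        entropy_bits=entropy(p),
        power=spectral_power(a),
        contrast=contrast(a),
        wavelet_s1=s1,
        wavelet_s2=s2,
    )


def metrics_table(frames, steps=None) -> pd.DataFrame:
    """Metrics of a frame sequence as a DataFrame, one row per frame,
    columns in the platform's table order.

    ``frames`` may be 2-D arrays or objects with ``img``/``step`` attributes
    (:class:`pitcorr.automaton.Frame`); ``steps`` overrides the step column.
    """
    rows = []
    for i, fr in enumerate(frames):
        img = getattr(fr, "img", fr)
        step = getattr(fr, "step", i)
        if steps is not None:
            step = steps[i]
        rows.append(metrics_record(img, step).to_dict())
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def metric_trend(values, full: bool = False):
    """Least-squares slope of a metric against image index.

    Used to check near-constancy of a measure across repeat images of one
    physical sample (slope close to 0).  With ``full=True`` the complete
    :func:`scipy.stats.linregress` result (slope, stderr, p-value, ...) is
    returned instead of the bare slope.
    """
    y = np.asarray(values, dtype=np.float64)
    if y.size < 2:
        raise ValueError("trend needs at least 2 values")
    res = _sstats.linregress(np.arange(y.size, dtype=np.float64), y)
    return res if full else float(res.slope)
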