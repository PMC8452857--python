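"""File I/O, simulation runner, and the parameter-sweep driver.

These functions are the scripting surface of the package: load micrographs
(PNG/TIFF) as 8-bit grayscale, run a simulation and write its frames +
metrics table + manifest, quantify a batch of images, sweep one
environmental parameter over a grid with replicate seeds, and write fixture
images for inspection.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

from . import __version__
from .automaton import Frame, run
from .fixtures import FixtureSpec, make_image
from .metrics import METRIC_COLUMNS, metric_trend, metrics_record, metrics_table
from .params import ModelParams, validate
from .timescale import Calibration

__all__ = [
    "load_image",
    "save_frame",
    "run_simulation",
    "quantify_images",
    "SweepSpec",
    "PAPER_GRIDS",
    "run_sweep",
    "plot_sweep",
    "write_fixture",
]

logger = logging.getLogger(__name__)

#: Luminance weights for RGB -> grayscale conversion (ITU-R BT.601).
_LUMA = np.array([0.299, 0.587, 0.114])


def load_image(path: str | pathlib.Path) -> np.ndarray:
    """Load a PNG/TIFF surface image as an 8-bit single-channel array.

    RGB(A) inputs are converted by luminance weighting (0.299, 0.587,
    0.114); 16-bit inputs are rescaled to 8-bit by linear mapping of the
    full nominal range.
    """
    path = pathlib.Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            mode = im.mode
            a = np.asarray(im)
    except Exception as e:
        raise IOError(f"cannot read image {path}: {e}") from e
    if mode in ("RGB", "RGBA"):
        a = a[..., :3].astype(np.float64) @ _LUMA
        return np.round(a).astype(np.uint8)
    if mode == "L":
        return a.astype(np.uint8)
    if mode in ("I;16", "I;16B", "I"):
        a = a.astype(np.float64) * (255.0 / 65535.0)
        return np.round(np.clip(a, 0, 255)).astype(np.uint8)
    raise IOError(f"cannot read image {path}: unsupported mode {mode!r}")


def save_frame(img: np.ndarray, path: str | pathlib.Path) -> None:
    """Write an 8-bit grayscale frame as PNG (or any Pillow-supported format)."""
    Image.fromarray(np.asarray(img, dtype=np.uint8), mode="L").save(path)


def run_simulation(
    params: ModelParams,
    outdir: str | pathlib.Path,
    calibration: Calibration | None = None,
) -> tuple[list[Frame], pd.DataFrame]:
    """Run the automaton and write all artifacts to ``outdir``.

    Artifacts: one ``frame_NNNNNN.png`` per emitted step, ``metrics.csv``
    (one row per frame, platform column order, NaN for undefined values),
    and ``manifest.json`` recording the parameters, seed, calibration,
    package version and every file written.  Partial outputs are removed if
    the run fails.
    """
    validate(params)
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[pathlib.Path] = []
    try:
        frames, records = run(params, calibration=calibration)
        for fr in frames:
            p = outdir / f"frame_{fr.step:06d}.png"
            save_frame(fr.img, p)
            written.append(p)
        table = pd.DataFrame([r.to_dict() for r in records], columns=METRIC_COLUMNS)
        csv_path = outdir / "metrics.csv"
        table.to_csv(csv_path, index=False, na_rep="NaN")
        written.append(csv_path)
        cal = calibration or Calibration(n_pixels=params.lattice_w, n_steps=params.steps)
        manifest = {
            "package": "pitcorr",
            "version": __version__,
            "params": params.to_dict(),
            "seed": params.seed,
            "calibration": dataclasses.asdict(cal),
            "emitted_steps": [fr.step for fr in frames],
            "artifacts": [p.name for p in written] + ["manifest.json"],
        }
        mpath = outdir / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2))
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return frames, table


def quantify_images(
    paths_or_images, trend: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, pd.Series]:
    """Metrics table for a batch of images (paths or arrays), one row each.

    With ``trend=True`` also return the per-metric least-squares slope
    against image index — near-zero slopes indicate the images come from
    one statistically homogeneous sample.  Unreadable files are logged and
    skipped; an error is raised only if every input fails.
    """
    rows, failures = [], 0
    items = list(paths_or_images)
    if not items:
        raise ValueError("no input images")
    for i, item in enumerate(items):
        try:
            img = item if isinstance(item, np.ndarray) else load_image(item)
            rows.append(metrics_record(img, step=i).to_dict())
        except Exception as e:
            failures += 1
            logger.error("skipping %r: %s", item, e)
    if not rows:
        raise IOError(f"all {failures} input images failed to load")
    table = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    if not trend:
        return table
    slopes = pd.Series(
        {c: metric_trend(table[c].to_numpy()) for c in METRIC_COLUMNS[1:]},
        name="slope",
    )
    return table, slopes


#: Sensitivity-study grids: parameter name -> values swept.
PAPER_GRIDS: dict[str, np.ndarray] = {
    "pH": np.round(np.arange(7.4, 10.0 + 1e-9, 0.2), 10),
    "potential_difference": np.round(np.arange(0.1, 1.0 + 1e-9, 0.1), 10),
    "T": np.round(np.arange(297.15, 313.15 + 1e-9, 2.0), 10),
    "C": np.round(np.arange(0.1, 0.5 + 1e-9, 0.1), 10),
    "D": np.round(np.arange(0.1, 0.5 + 1e-9, 0.1), 10),
    "z": np.round(np.arange(0.1, 0.5 + 1e-9, 0.1), 10),
}

_SWEEPABLE = tuple(PAPER_GRIDS)


@dataclass
class SweepSpec:
    """One-parameter sensitivity study.

    ``parameter`` is one of pH, potential_difference (varies phi_M with
    phi_S fixed, since only the difference enters the kinetics), T, C, D, z.
    ``values`` defaults to the parameter's standard grid; each value is run
    with ``replicates`` independent seeds derived from ``seed``.
    """

    parameter: str
    values: np.ndarray | None = None
    replicates: int = 20
    base: ModelParams = field(default_factory=ModelParams)
    metrics: tuple[str, ...] = ("mean", "entropy_bits", "corroded_pct")
    seed: int = 0

    def grid(self) -> np.ndarray:
        if self.parameter not in _SWEEPABLE:
            raise ValueError(
                f"unknown sweep parameter {self.parameter!r}; expected one of {_SWEEPABLE}"
            )
        v = PAPER_GRIDS[self.parameter] if self.values is None else np.asarray(self.values)
        if v.size == 0:
            raise ValueError("empty sweep range")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        return v


def _with_value(base: ModelParams, parameter: str, value: float) -> ModelParams:
    if parameter == "potential_difference":
        return base.replace(phi_M=base.phi_S + float(value))
    return base.replace(**{parameter: float(value)})


def run_sweep(spec: SweepSpec, outdir: str | pathlib.Path | None = None) -> pd.DataFrame:
    """Run the sweep and aggregate metrics across replicates.

    Returns a tidy DataFrame with one row per (parameter value, emitted
    step, metric): columns ``parameter, value, step, metric, mean, std, n``.
    With ``outdir`` given, writes it as ``sweep_<parameter>.csv``.
    """
    values = spec.grid()
    ss = np.random.SeedSequence(spec.seed)
    rep_seeds = [int(s) for s in ss.generate_state(spec.replicates) >> 1]
    rows = []
    for value in values:
        per_rep = []
        for rs in rep_seeds:
            p = _with_value(spec.base, spec.parameter, value).replace(seed=rs)
            _, records = run(p)
            per_rep.append(pd.DataFrame([r.to_dict() for r in records]))
        stacked = pd.concat(per_rep)
        for step, grp in stacked.groupby("step"):
            for m in spec.metrics:
                rows.append(
                    {
                        "parameter": spec.parameter,
                        "value": float(value),
                        "step": int(step),
                        "metric": m,
                        "mean": float(grp[m].mean()),
                        "std": float(grp[m].std(ddof=1)) if len(grp) > 1 else 0.0,
                        "n": int(len(grp)),
                    }
                )
        logger.info("sweep %s=%s done (%d replicates)", spec.parameter, value, spec.replicates)
    result = pd.DataFrame(rows)
    if outdir is not None:
        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        result.to_csv(outdir / f"sweep_{spec.parameter}.csv", index=False, na_rep="NaN")
    return result


def plot_sweep(result: pd.DataFrame, metric: str, path: str | pathlib.Path) -> None:
    """Line plot of one metric vs. the swept parameter value, one line per
    emitted step (the sensitivity-figure shape).  Optional artifact only."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sel = result[result["metric"] == metric]
    fig, ax = plt.subplots(figsize=(6, 4))
    for step, grp in sel.groupby("step"):
        grp = grp.sort_values("value")
        ax.plot(grp["value"], grp["mean"], marker="o", label=f"step {step}")
    ax.set_xlabel(str(sel["parameter"].iloc[0]))
    ax.set_ylabel(metric)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_fixture(spec: FixtureSpec, path: str | pathlib.Path) -> np.ndarray:
    """Render a fixture image to disk (PNG) for manual inspection."""
    img = make_image(spec)
    save_frame(img, path)
    return img
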