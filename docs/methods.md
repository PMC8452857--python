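# Methods

## Model and assumptions

The simulation treats pitting corrosion of a metal surface in solution as a
two-sub-model stochastic cellular automaton on a 2-D square lattice with
synchronous updates.  Corrosion is purely two-dimensional (no pit depth),
irreversible (a cell's corroded status never clears, although its intensity
can fluctuate), and locally driven: a cell's evolution depends only on its
Moore neighborhood and on a shared electrochemical rate factor.

**Initiation.** Every uncorroded cell accumulates an initialization
potential I by a per-step increment with mean `alpha_mean`.  A cell
initiates when its Von Neumann score — (own I + the four orthogonal
neighbors' I) / 3, with out-of-lattice terms contributing 0 — exceeds the
threshold `theta`; its state becomes `s_init`.  The divisor 3 (not a 5-term
average) is the model's stated form and is implemented literally.

**Progression.** Corroded cells update by
`S + k1·f(S) + k2·Σ_orth f(S) + k3·Σ_diag S + k4·N(0,1)`, clamped to
[0, 255], reading only the previous step's buffers.  The diagonal term uses
the raw state, not f(S), exactly as the model defines it; a
`diag_activity=True` switch enables the f-on-diagonals variant.  The
activity parabola `f(x) = 128² − (x−128)²` encodes reaction activity rising
from zero at an intact surface, peaking at half corrosion, and vanishing
again at saturation.  A fully corroded cell still contributes f(255) = 255
to its neighbors.

**Kinetics.** All four coefficients share the environmental factor
`r(pH)·e^(φM−φS)·(1/T)·C·D·z` and differ only by discount factors λ1..λ4
(defaults 3, 2, 1, 1: the influence decays with neighbor distance; λ4
scales the noise).  The exponential acts on the potential difference in
volts.  The pH response `r` has three modes:

- `as_printed`: `(pH−7)²·step(4, 8.5)`, where the step factor is 0 on the
  closed passive band [4, 8.5] and 1 outside.  Taken literally this zeroes
  every rate at physiological pH 7.4, freezing progression entirely —
  inconsistent with the model's own reference outputs at that pH.
- `quadratic` (default): `1 + (pH−7)²` — a unit baseline plus the quadratic
  acid/alkaline boost.  Reproduces the monotone pH sensitivity on 7–10.
- `banded`: `1 + (pH−7)²·step(4, 8.5)` — unit baseline, band-gated boost.

Which form the original authors actually ran is not recoverable; the
selector keeps the literal form available without silently rewriting it.
Band endpoints are closed by convention (the source states neither).

## Parameters

| name | meaning | unit | default |
|---|---|---|---|
| pH | solution acidity | — | 7.4 |
| phi_M, phi_S | metal / solution potential | V | 0.23, 0.2 |
| T | absolute temperature | K | 310.15 |
| C, D, z | species concentration, diffusivity, charge | M/dm³, dm²/s, faraday | 0.2, 0.3, 0.2 |
| steps, emit_every | run length, frame cadence | steps | 100, 20 |
| lattice_h × lattice_w | surface size | cells | 200 × 200 |
| lambda1..4 | distance discounts / noise gain | — | 3, 2, 1, 1 |
| alpha_mean | mean potential increment | state units/step | 1.0 |
| theta | initiation threshold | state units | 50.0 |
| s_init | state of a fresh pit | state units | 1.0 |

Environmental values outside the recommended stability ranges (pH 7–10,
φ 0.1–1 V, T 297.15–313.15 K, C/D/z 0.1–0.5) warn but do not abort — the
model is not limited to them.  Non-physical values (T ≤ 0, lattice < 3,
steps not divisible by emit_every, …) raise.

`alpha_mean`, `theta` and `s_init` have no published values; the defaults
are a calibration choice: with per-cell Uniform(0, 2α) increments the
expected interior initiation time is 3θ/(5α) = 30 steps, so the first
emitted frame (step 20) is still pristine and corrosion is visible by the
second (step 40), matching the reference trajectory's latency pattern.

**α stochasticity.** A shared deterministic α would initiate every interior
cell on the same step, yielding uniform corrosion instead of discrete pits.
The default draws one Uniform(0, 2·alpha_mean) increment per cell per step
(same mean as the deterministic rule); `alpha_dist="constant"` restores the
deterministic variant.

**Boundaries and RNG.** The default boundary is inert (out-of-lattice
neighbors contribute 0); `boundary="periodic"` wraps.  One seeded generator
drives a run; each step consumes the uniform accumulation field first, then
the per-cell noise field, so equal seeds give bit-identical runs.  The
floating-point summation order of the neighbor terms (self; orthogonal
up, down, left, right; diagonal up-right, up-left, down-left, down-right;
noise) is fixed and verified bit-for-bit against a per-cell reference loop.
Internal state is real-valued; quantization to 8 bits happens only at frame
emission, since per-step increments at realistic rates are ≪ 1.

## Physical calibration

200 pixels ≙ 0.2 mm (1 µm/pixel) and 100 steps ≙ 4 days, giving 57.6 min
per step (a day is exactly 1440 min — the 57.6 figure forces this) and
emitted frames at 19.2, 38.4, 57.6, 76.8, 96 h.  Corrosion rates convert
with 1 mil = 0.0254 mm, so the measured 774.2 mpy at physiological pH is
19.66468 mm/year; the module reports exact conversions only and does not
attempt to reconcile the ≈20 mm/year and 0.2 mm-in-4-days roundings.

## Image statistics

All histogram measures use the 256-bin histogram of the quantized 8-bit
frame with **population** normalization (at 40 000 pixels the sample
correction is negligible).  Skew and kurtosis are undefined (NaN) for a
constant frame.  Kurtosis is the plain fourth standardized moment (3 for a
normal), not excess — the convention consistent with the reference
trajectory's values near 1.2–1.5 for near-half-zero histograms.  Entropy is
base 2 ("bits to code the image").  Spectral power is the sum of squared
magnitudes of the **un-normalized** 2-D DFT — the only convention that
reproduces the published power values from the same table's mean/std via
Parseval (power = Npix·ΣI² = Npix²·(mean²+std²)); the test suite uses the
pixel-domain identity as an independent oracle for the FFT path.

Contrast is max − min as defined, although the reference table prints 0 at
every step (impossible for a frame with any corroded pixel — a defect of
that table, documented here, not enforced).

Wavelet features are the two largest singular values of the single-level
Haar approximation subband, scaled by the subband's row count.  The
original normalization is not recoverable (its printed s1/mean ratio of
≈0.79 matches no standard scaling); this pipeline is the package's own
documented convention, is pluggable, and the features are excluded from
numeric acceptance.  The Haar subband is computed directly (a 2×2 block
sum / 2) rather than through a wavelet library, since only this one
transform is needed.

## Synthetic fixtures

The fixture generator emulates what the metrics need, not physical realism:
constant and two-level images, uniform/Gaussian noise with stated
post-quantization moments, exact-pixel-count disk "pits", exactly rank-1
images (integer row profile × binary column profile, so 8-bit storage
preserves the rank), and monotone corrosion-like sequences.  A green
fixture test establishes the metric arithmetic, and nothing about real
micrographs — real images add illumination gradients, focus variation and
camera noise that the constancy (trend-slope) analysis only partially
absorbs.

## Sensitivity studies

`pitcorr.io.run_sweep` varies one factor over its standard grid (pH
7.4–10 step 0.2; φM−φS 0.1–1 step 0.1, varied through φM; T 297.15–313.15
step 2 K; C, D, z 0.1–0.5 step 0.1) with replicate seeds and aggregates
metrics per emitted step.  The acceptance suite asserts the expected
directions on replicate means with a 3-standard-error allowance per
consecutive pair — a finite-sample test of expected-value monotonicity.
Sweeps there run on a 100×100 lattice for 60 steps: by step 100 every
setting saturates near S = 255 and the comparison degenerates to ties.

## Known limitations

- With the default calibration the progression is logistic with rate
  ≈ 256·(k1+4k2) ≈ 0.13/step, so the surface saturates near S = 255 by
  ~step 75.  The reference trajectory's much slower intensity growth
  (mean ≈ 7 at step 100) is not reachable from the printed equations with
  any published constants — the literal kinetics give *zero* rates at the
  default pH — so the final-frame magnitude-envelope check in the
  acceptance suite is expected to fail and documents this inconsistency;
  intermediate frames (steps 40–60) do fall in the expected envelope.
- Initiation under the default calibration is nearly simultaneous across
  the interior (the score's standard deviation is small relative to its
  drift), so coverage jumps from 0% to ~97% between frames 1 and 2 rather
  than through the reference's ~51% intermediate. Raising `theta` spreads
  nucleation out; the default keeps the published latency pattern instead.
- No pit depth (2-D only), no passivation chemistry beyond the pH band
  factor, no parallel execution.
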