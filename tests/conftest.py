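"""Shared fixtures and the naive per-cell reference for the progression rule."""

import numpy as np
import pytest

from pitcorr.kinetics import RateCoefficients
from pitcorr.params import ModelParams


def naive_progress(S, corroded, k: RateCoefficients, noise, diag_activity=False):
    """Reference progression update: explicit double loop over cells.

    Independent of the vectorized implementation but mirrors its documented
    floating-point summation order (self, orthogonal up/down/left/right,
    diagonal ur/ul/dl/dr, noise) so results are comparable bit-for-bit.
    Visits cells in *reverse* row-major order and writes to a fresh output
    buffer, so agreement also demonstrates visitation-order independence.
    """
    h, w = S.shape

    def f(s):
        return 128.0**2 - (s - 128.0) ** 2

    def at(r, c):
        return S[r, c] if 0 <= r < h and 0 <= c < w else 0.0

    out = np.zeros_like(S)
    for r in reversed(range(h)):
        for c in reversed(range(w)):
            if not corroded[r, c]:
                continue
            orth = f(at(r - 1, c))
            orth = orth + f(at(r + 1, c))
            orth = orth + f(at(r, c - 1))
            orth = orth + f(at(r, c + 1))
            if diag_activity:
                diag = f(at(r - 1, c + 1))
                diag = diag + f(at(r - 1, c - 1))
                diag = diag + f(at(r + 1, c - 1))
                diag = diag + f(at(r + 1, c + 1))
            else:
                diag = at(r - 1, c + 1)
                diag = diag + at(r - 1, c - 1)
                diag = diag + at(r + 1, c - 1)
                diag = diag + at(r + 1, c + 1)
            v = S[r, c] + k.k1 * f(S[r, c])
            v = v + k.k2 * orth
            v = v + k.k3 * diag
            v = v + k.k4 * noise[r, c]
            out[r, c] = min(max(v, 0.0), 255.0)
    return out


@pytest.fixture
def default_params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def default_run():
    """One full default-parameter run (200x200, 100 steps), shared."""
    from pitcorr.automaton import run

    return run(ModelParams(seed=20260918))
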