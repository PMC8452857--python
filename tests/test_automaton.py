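import warnings

import numpy as np
import pytest

from conftest import naive_progress
from pitcorr.automaton import (
    LatticeState,
    accumulate_potential,
    apply_initiation,
    init_lattice,
    initiation_scores,
    progress_step,
    quantize,
    run,
)
from pitcorr.kinetics import RateCoefficients, coefficients
from pitcorr.params import ModelParams, ParameterError

K0 = RateCoefficients(0.0, 0.0, 0.0, 0.0)


def random_state(h, w, seed, frac=0.5):
    rng = np.random.default_rng(seed)
    return LatticeState(
        S=np.where(rng.random((h, w)) < frac, rng.uniform(0, 255, (h, w)), 0.0),
        I=rng.uniform(0, 60, (h, w)),
        corroded=rng.random((h, w)) < frac,
        t=0,
    )


def test_init_lattice_pristine():
    st = init_lattice(200, 200)
    assert st.t == 0
    assert not st.S.any() and not st.I.any() and not st.corroded.any()
    assert quantize(st.S).mean() == 0.0


def test_init_lattice_rejects_tiny():
    with pytest.raises(ParameterError):
        init_lattice(2, 5)


def test_accumulate_zero_increment_is_identity():
    st = random_state(10, 10, 0)
    new = accumulate_potential(st, 0.0, np.random.default_rng(1))
    assert np.array_equal(new.I, st.I)


def test_accumulate_mean_matches_alpha():
    # after n updates from zero, mean of I over uncorroded cells ~ n*alpha,
    # within 3 standard errors of the uniform-increment mean
    st = init_lattice(50, 50)
    n, alpha = 30, 1.0
    rng = np.random.default_rng(7)
    for _ in range(n):
        st = accumulate_potential(st, alpha, rng)
    se = np.sqrt(n * alpha**2 / 3.0 / st.I.size)
    assert abs(st.I.mean() - n * alpha) < 3 * se


def test_accumulate_freezes_corroded_cells_and_is_deterministic():
    st = random_state(12, 12, 3)
    a = accumulate_potential(st, 1.0, np.random.default_rng(42))
    b = accumulate_potential(st, 1.0, np.random.default_rng(42))
    assert np.array_equal(a.I, b.I)
    assert np.array_equal(a.I[st.corroded], st.I[st.corroded])
    assert np.all(a.I[~st.corroded] > st.I[~st.corroded])


def test_initiation_scores_uniform_field():
    st = init_lattice(5, 5)
    st.I[:] = 3.0
    sc = initiation_scores(st)
    assert sc[2, 2] == pytest.approx(5.0)  # interior: 5 stencil terms / 3
    assert sc[0, 0] == pytest.approx(3.0)  # corner: 2 neighbors outside
    assert sc[0, 2] == pytest.approx(4.0)  # edge: 1 neighbor outside
    assert not initiation_scores(init_lattice(5, 5)).any()


def test_apply_initiation_thresholds():
    st = init_lattice(4, 4)
    st.I[:] = 5.0
    assert not apply_initiation(st, 1e12, 1.0).corroded.any()
    all_on = apply_initiation(st, 0.0, 1.0)
    assert all_on.corroded.all() and np.all(all_on.S == 1.0)


def test_apply_initiation_center_only_on_3x3():
    # I = 30 everywhere: center score 50, edges 40, corners 30 -> only the
    # center crosses theta = 49
    st = init_lattice(3, 3)
    st.I[:] = 30.0
    new = apply_initiation(st, 49.0, 0.5)
    expected = np.zeros((3, 3), dtype=bool)
    expected[1, 1] = True
    assert np.array_equal(new.corroded, expected)
    assert new.S[1, 1] == 0.5


def test_apply_initiation_never_touches_existing_pits():
    st = random_state(8, 8, 11)
    new = apply_initiation(st, 0.0, 2.0)
    assert np.array_equal(new.S[st.corroded], st.S[st.corroded])


def test_progress_zero_coefficients_is_identity():
    st = random_state(9, 9, 5)
    new = progress_step(st, K0, np.random.default_rng(0))
    assert np.array_equal(new.S, np.where(st.corroded, np.clip(st.S, 0, 255), 0.0))


def test_progress_single_cell_hand_value():
    # lone pit at half corrosion, only the self term active:
    # 128 + 1e-4 * f(128) = 129.6384
    st = init_lattice(5, 5)
    st.S[2, 2] = 128.0
    st.corroded[2, 2] = True
    k = RateCoefficients(1e-4, 0.0, 0.0, 0.0)
    new = progress_step(st, k, np.random.default_rng(0))
    assert new.S[2, 2] == pytest.approx(129.6384)
    assert np.count_nonzero(new.S) == 1


def test_progress_clamps_and_never_initiates():
    st = random_state(10, 10, 8)
    k = RateCoefficients(1.0, 1.0, 1.0, 50.0)  # absurdly fast on purpose
    new = progress_step(st, k, np.random.default_rng(2))
    assert np.all(new.S >= 0.0) and np.all(new.S <= 255.0)
    assert not new.S[~st.corroded].any()
    assert np.array_equal(new.corroded, st.corroded)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
@pytest.mark.parametrize("diag_activity", [False, True])
def test_progress_matches_naive_reference_bitwise(seed, diag_activity):
    # vectorized synchronous update == per-cell double loop (visiting cells
    # in the opposite order), bit for bit
    st = random_state(8, 10, seed)
    k = coefficients(ModelParams())
    k = RateCoefficients(k.k1 * 50, k.k2 * 50, k.k3 * 50, 0.5)
    noise = np.random.default_rng(seed + 100).standard_normal(st.S.shape)
    got = progress_step(
        st, k, np.random.default_rng(seed + 100), diag_activity=diag_activity
    )
    want = naive_progress(st.S, st.corroded, k, noise, diag_activity=diag_activity)
    assert np.array_equal(got.S, want)


def test_periodic_boundary_wraps_neighbors():
    # a uniform fully corroded lattice is a fixed point of the neighbor sums
    # only under periodic wrap; with an inert edge the border cells see fewer
    # neighbors and fall behind
    st = init_lattice(6, 6)
    st.S[:] = 100.0
    st.corroded[:] = True
    k = RateCoefficients(1e-4, 1e-4, 1e-4, 0.0)
    per = progress_step(st, k, np.random.default_rng(0), boundary="periodic")
    assert np.allclose(per.S, per.S[0, 0])
    zero = progress_step(st, k, np.random.default_rng(0), boundary="zero")
    assert zero.S[0, 0] < zero.S[3, 3]


def test_run_emission_schedule(default_run):
    frames, records = default_run
    assert [f.step for f in frames] == [0, 20, 40, 60, 80, 100]
    assert len(records) == 6
    assert frames[-1].physical_time_h == pytest.approx(96.0)


def test_run_is_deterministic_given_seed():
    p = ModelParams(lattice_h=40, lattice_w=40, steps=40, seed=123)
    fa, _ = run(p)
    fb, _ = run(p)
    for a, b in zip(fa, fb):
        assert np.array_equal(a.img, b.img)


def test_run_corroded_area_monotone(default_run):
    _, records = default_run
    pct = [r.corroded_pct for r in records]
    assert all(b >= a for a, b in zip(pct, pct[1:]))
    assert pct[1] == 0.0 and pct[2] > 0.0  # latent at t=20, corroding by t=40


def test_run_without_noise_is_per_cell_monotone():
    # with the stochastic gain removed, every cell's state is nondecreasing
    p = ModelParams(lattice_h=30, lattice_w=30, steps=60, emit_every=10, seed=4,
                    lambda4=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # lambda4 outside nominal range
        frames, _ = run(p)
    for a, b in zip(frames, frames[1:]):
        assert np.all(b.img.astype(int) >= a.img.astype(int))


def test_run_concentration_raises_expected_corrosion():
    # cheap two-point check of the sensitivity direction (the full grid runs
    # in the acceptance suite): higher species concentration -> more mean
    # corrosion at the final step, on replicate averages
    base = ModelParams(lattice_h=60, lattice_w=60, steps=60)
    means = {}
    for c in (0.1, 0.5):
        vals = [
            run(base.replace(C=c, seed=s))[1][-1].mean for s in range(10)
        ]
        means[c] = np.mean(vals)
    assert means[0.5] > means[0.1]
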