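import numpy as np
import pytest

import extrande as ex
from extrande.exceptions import InvalidParameterError
from extrande.trajectory import Trajectory


def _const_bd():
    return ex.build_birth_death(input_birth=True)


def _const_input_factory(seed):
    return ex.constant_input(10.0, T=60.0, dt=1.0)


def test_single_cell_ensemble_runs():
    res = ex.run_ensemble(1, _const_bd(), _const_input_factory, T=10.0, master_seed=3)
    assert res.n_cells == 1
    assert len(res.outcomes) == 1
    assert res.mean_states.shape == (201, 1)


def test_ensemble_reproducible():
    a = ex.run_ensemble(5, _const_bd(), _const_input_factory, T=20.0, master_seed=9)
    b = ex.run_ensemble(5, _const_bd(), _const_input_factory, T=20.0, master_seed=9)
    assert np.array_equal(a.mean_states, b.mean_states)
    assert a.seeds == b.seeds


def test_sem_scales_with_cell_count():
    """Cell-to-cell SEM of the stationary mean scales as 1/sqrt(n): the
    SEM ratio between n=100 and n=400 is 2 within a factor 1.5."""
    grid = np.linspace(20.0, 60.0, 81)
    sems = {}
    for n, seed in ((100, 1), (400, 2)):
        res = ex.run_ensemble(
            n, _const_bd(), _const_input_factory, T=60.0, master_seed=seed,
            output_grid=grid, keep_trajectories=True,
        )
        cell_means = [tr.sample_states[:, 0].mean() for tr in res.trajectories]
        sems[n] = np.std(cell_means) / np.sqrt(n)
    ratio = sems[100] / sems[400]
    assert 2.0 / 1.5 < ratio < 2.0 * 1.5


def _comk_traj(levels, times, T):
    """Piecewise-constant single-species path for progress tests."""
    return Trajectory(
        x0=np.array([levels[0]]), t0=0.0, T=T, species_names=["ComK"],
        times=np.array(times, dtype=float),
        labels=np.zeros(len(times), dtype=np.int64),
        states=np.array(levels[1:]).reshape(-1, 1),
    )


def test_progress_constant_level_entry_time():
    tr = _comk_traj([4], [], 10.0)
    k_diff = 0.05
    prog, entry = ex.progress_to_competence(tr, "ComK", k_diff)
    assert entry == pytest.approx(1.0 / (k_diff * 4))
    assert prog == pytest.approx(k_diff * 4 * 10.0)


def test_progress_zero_level_never_enters():
    tr = _comk_traj([0], [], 10.0)
    prog, entry = ex.progress_to_competence(tr, "ComK", 1.0)
    assert prog == 0.0 and entry is None


def test_progress_piecewise_integral_by_hand():
    """ComK = 2 on [0,1] h then 0; k_diff = 0.25: progress at 4 h is 0.5."""
    tr = _comk_traj([2, 0], [1.0], 4.0)
    prog, entry = ex.progress_to_competence(tr, "ComK", 0.25)
    assert prog == pytest.approx(0.5)
    assert entry is None


def test_entry_times_scale_inversely_with_k_diff():
    tr = _comk_traj([5], [], 100.0)
    _, e1 = ex.progress_to_competence(tr, "ComK", 0.01)
    _, e2 = ex.progress_to_competence(tr, "ComK", 0.02)
    assert e1 == pytest.approx(2.0 * e2)
    with pytest.raises(InvalidParameterError):
        ex.progress_to_competence(tr, "ComK", -1.0)


def test_competent_fraction_examples():
    def outs(n_in, n_out):
        return [ex.CellOutcome(i, 0, entry_time=5.0) for i in range(n_in)] + [
            ex.CellOutcome(n_in + i, 0, entry_time=None) for i in range(n_out)
        ]

    assert ex.competent_fraction(outs(10, 0), 20.0)[0] == 1.0
    assert ex.competent_fraction(outs(0, 10), 20.0)[0] == 0.0
    frac, se = ex.competent_fraction(outs(180, 820), 20.0)
    assert frac == pytest.approx(0.18)
    assert se == pytest.approx(np.sqrt(0.18 * 0.82 / 1000), rel=1e-9)


def _outcomes_from_probs(x, p, rng):
    y = rng.random(len(x)) < p
    return [
        ex.CellOutcome(i, 0, entry_time=5.0 if yi else None, mean_input=xi)
        for i, (xi, yi) in enumerate(zip(x, y))
    ]


def test_logistic_null_slope_consistent_with_zero():
    rng = np.random.default_rng(10)
    x = rng.normal(1000.0, 150.0, size=800)
    fit = ex.prob_competence_vs_mean_input(_outcomes_from_probs(x, 0.3, rng))
    assert abs(fit.slope) < 2 * fit.slope_se
    assert not fit.separated


def test_logistic_recovers_known_slope():
    rng = np.random.default_rng(11)
    x = rng.normal(1000.0, 150.0, size=1000)
    true_b = 0.02
    p = 1.0 / (1.0 + np.exp(-(-(true_b * 1000.0) + true_b * x)))
    fit = ex.prob_competence_vs_mean_input(_outcomes_from_probs(x, p, rng))
    assert abs(fit.slope - true_b) < 2 * fit.slope_se
    # p = 0.5 at the generator's symmetry point
    assert fit.predict(1000.0) == pytest.approx(0.5, abs=0.08)


def test_logistic_complete_separation_flagged():
    rng = np.random.default_rng(12)
    x = np.concatenate([rng.normal(800, 30, 50), rng.normal(1200, 30, 50)])
    outs = [
        ex.CellOutcome(i, 0, entry_time=5.0 if xi > 1000 else None, mean_input=xi)
        for i, xi in enumerate(x)
    ]
    fit = ex.prob_competence_vs_mean_input(outs)
    assert fit.separated
    assert fit.slope > 0
    with pytest.raises(InvalidParameterError):
        ex.prob_competence_vs_mean_input(outs[:50])  # one class only


def test_fate_pipeline_end_to_end():
    """Toy bistable-expression network driven by the baseline quorum-sensing
    input: the full per-cell outcome pipeline produces coherent results."""
    net = ex.build_competence_toy()
    spec = ex.benchmarks.pcoma_baseline_spec()

    def factory(seed):
        return ex.simulate_ou(spec, dt=0.005, T=20.0, seed=seed)

    res = ex.run_ensemble(
        30, net, factory, T=20.0, master_seed=21, x0=[1, 0, 0],
        progress_species="ComK", k_diff=2e-4, clip_input=True,
    )
    frac, se = ex.competent_fraction(res.outcomes, 20.0)
    assert 0.0 <= frac <= 1.0
    for o in res.outcomes:
        assert o.mean_input is not None and o.mean_input > 0
        if o.entry_time is not None:
            assert 0.0 < o.entry_time <= 20.0
            assert o.final_progress >= 1.0 - 1e-9
        else:
            assert o.final_progress < 1.0


def test_shared_input_mean_matches_conditional_ode(two_stage_net):
    """Population mean over cells sharing one input realization converges to
    the conditional-moment ODE solution."""
    T = 8.0
    k = ex.circadian_rate(kdp=0.5, dt=1e-3, T=T)
    grid = np.linspace(0.5, T, 16)
    n = 300
    res = ex.run_ensemble(
        n, two_stage_net, k, T=T, master_seed=33, output_grid=grid,
        keep_trajectories=True,
    )
    ode = ex.conditional_mean_ode(k, 2.0, 3.0, 0.5, grid=grid)
    prot = np.array([tr.sample_states[:, 1] for tr in res.trajectories])
    se = prot.std(0, ddof=1) / np.sqrt(n)
    z = (prot.mean(0) - ode.mean_protein) / np.maximum(se, 1e-9)
    assert np.max(np.abs(z)) < 4.0
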