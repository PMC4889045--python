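import numpy as np
import pytest
from scipy import stats as sps

import extrande as ex
from extrande.exceptions import BoundViolationError, InvalidParameterError


def test_bound_policy_validation():
    with pytest.raises(InvalidParameterError):
        ex.BoundPolicy(strategy="nope")
    with pytest.raises(InvalidParameterError):
        ex.BoundPolicy(L=-1.0)
    with pytest.raises(InvalidParameterError):
        ex.BoundPolicy(safety_factor=0.5)


def test_bound_constant_input_all_strategies_agree(two_stage_net):
    c = ex.constant_input(4.0, T=10.0)
    x = np.array([2, 5])
    a0, _ = ex.total_propensity(two_stage_net, x, 4.0)
    for strat in ("window-max", "monotone-sup", "global"):
        B, L, _ = ex.compute_bound(
            two_stage_net, x, c, 1.0, ex.BoundPolicy(strategy=strat, L=2.0)
        )
        assert B == pytest.approx(a0)


def test_bound_step_input_birth_only(step_traj):
    """Birth-only network with a0 = I: window [0, 2) gives B = 3."""
    net = ex.build_pure_birth()
    B, L, _ = ex.compute_bound(
        net, np.array([0]), step_traj, 0.0, ex.BoundPolicy(strategy="monotone-sup", L=2.0)
    )
    assert B == pytest.approx(3.0)
    B, _, _ = ex.compute_bound(
        net, np.array([0]), step_traj, 0.0, ex.BoundPolicy(strategy="window-max", L=0.5)
    )
    assert B == pytest.approx(1.0)


def test_monotone_sup_equals_window_max_for_two_stage(two_stage_net):
    """For an input-monotone network on a step-function input the cheap
    supremum bound coincides with the exhaustive window maximum."""
    rng = np.random.default_rng(0)
    grid = np.linspace(0.0, 10.0, 101)
    tr = ex.InputTrajectory(grid, rng.gamma(2.0, 2.0, size=101))
    for _ in range(20):
        x = rng.integers(0, 20, size=2)
        t = rng.uniform(0, 9.0)
        L = rng.uniform(0.1, 3.0)
        B1, _, _ = ex.compute_bound(
            two_stage_net, x, tr, t, ex.BoundPolicy(strategy="monotone-sup", L=L)
        )
        B2, _, _ = ex.compute_bound(
            two_stage_net, x, tr, t, ex.BoundPolicy(strategy="window-max", L=L)
        )
        assert B1 == pytest.approx(B2, rel=1e-12)


def test_monotone_sup_requires_declaration(step_traj):
    rxn = ex.Reaction("odd", np.array([1]), lambda x, I, t: max(0.0, 10.0 - I))
    net = ex.ReactionNetwork(["X"], [rxn], input_monotone=False)
    with pytest.raises(InvalidParameterError, match="monotone"):
        ex.compute_bound(
            net, np.array([0]), step_traj, 0.0,
            ex.BoundPolicy(strategy="monotone-sup", L=1.0),
        )


def test_bound_violation_is_a_hard_failure():
    """A propensity that *decreases* with the input but claims monotonicity
    invalidates the thinning bound; the simulator must fail loudly."""
    rxn = ex.Reaction("antagonist", np.array([1]), lambda x, I, t: max(0.0, 10.0 - I))
    net = ex.ReactionNetwork(["X"], [rxn], input_monotone=True)  # a lie
    grid = np.linspace(0.0, 10.0, 11)
    tr = ex.InputTrajectory(grid, np.linspace(1.0, 9.0, 11))
    with pytest.raises(BoundViolationError):
        ex.extrande_simulate(
            net, [0], tr, 10.0, ex.BoundPolicy(strategy="monotone-sup", L=5.0), seed=0
        )


@pytest.mark.parametrize("engine", ["python", "auto"])
def test_constant_input_birth_death_poisson_mean(engine):
    """With a constant input the thinning simulator reduces to the SSA: the
    birth-death stationary law is Poisson(k/kd)."""
    net = ex.build_birth_death(input_birth=True)
    k, kd, T = 10.0, 1.0, 400.0
    cin = ex.constant_input(k, T=T, dt=0.5)
    grid = np.arange(20.0, T, 0.25)
    tr, st = ex.extrande_simulate(
        net, [0], cin, T, ex.BoundPolicy(strategy="monotone-sup", L=1.0),
        seed=11, record_events=False, sample_grid=grid, engine=engine,
    )
    xs = tr.sample_states[:, 0]
    # ~T/2 effective independent samples (relaxation time 1/kd)
    se = np.sqrt(k / kd / (T / 2.0))
    assert abs(xs.mean() - k / kd) < 3 * se


def test_acceptance_fraction_matches_thinning_identity():
    """With a global (constant) bound the fraction of accepted draws is the
    time-average of a0/B — the defining identity of thinning."""
    net = ex.build_pure_birth()
    T = 2000.0
    grid = np.arange(0.0, T + 1e-9, 0.01)
    lam = 4.0 * (1.0 + np.sin(2 * np.pi * grid / 24.0))
    tr = ex.InputTrajectory(grid, lam)
    _, st = ex.extrande_simulate(
        net, [0], tr, T, ex.BoundPolicy(strategy="global"),
        seed=13, record_events=False, sample_grid=np.array([T]), engine="python",
    )
    B = lam.max()
    expected = np.trapezoid(lam, grid) / T / B  # = 0.5 up to grid effects
    frac = st.fractions()
    se = np.sqrt(expected * (1 - expected) / st.n_exponentials_drawn)
    assert abs(frac["accepted"] - expected) < 4 * se
    assert st.n_exponentials_drawn == st.n_accepted + st.n_thinned + st.n_rejected


def test_event_and_grid_recording_agree(two_stage_net):
    """The same seeded run recorded as events or on a grid yields the same
    sampled path (recording never consumes randomness)."""
    k = ex.circadian_rate(kdp=0.5, dt=0.01, T=24.0)
    grid = np.linspace(0.0, 24.0, 97)
    pol = ex.BoundPolicy(strategy="monotone-sup", L=1.0)
    tr1, st1 = ex.extrande_simulate(
        two_stage_net, [0, 0], k, 24.0, pol, seed=5, engine="python"
    )
    tr2, st2 = ex.extrande_simulate(
        two_stage_net, [0, 0], k, 24.0, pol, seed=5, engine="python",
        record_events=False, sample_grid=grid,
    )
    assert np.array_equal(tr1.sample(grid), tr2.sample_states)
    assert st1.to_dict() == st2.to_dict()


@pytest.mark.parametrize("engine", ["python", "numba"])
def test_reproducibility_same_seed_same_trajectory(two_stage_net, engine):
    k = ex.circadian_rate(kdp=0.5, dt=0.01, T=12.0)
    grid = np.linspace(0.0, 12.0, 49)
    pol = ex.BoundPolicy(strategy="monotone-sup", L=1.0)
    kw = dict(record_events=False, sample_grid=grid, engine=engine)
    a, sa = ex.extrande_simulate(two_stage_net, [0, 0], k, 12.0, pol, seed=8, **kw)
    b, sb = ex.extrande_simulate(two_stage_net, [0, 0], k, 12.0, pol, seed=8, **kw)
    assert np.array_equal(a.sample_states, b.sample_states)
    assert sa.to_dict() == sb.to_dict()


def test_engines_sample_the_same_law(two_stage_net):
    """Compiled and pure-Python engines agree distributionally (they are two
    implementations of one algorithm with distinct RNG streams)."""
    k = ex.circadian_rate(kdp=0.5, dt=0.01, T=24.0)
    pol = ex.BoundPolicy(strategy="monotone-sup", L=1.0)
    grid = np.array([24.0])
    finals = {eng: [] for eng in ("python", "numba")}
    for eng in finals:
        for s in np.random.SeedSequence(17).spawn(120):
            tr, _ = ex.extrande_simulate(
                two_stage_net, [0, 0], k, 24.0, pol, rng=np.random.default_rng(s),
                record_events=False, sample_grid=grid, engine=eng,
            )
            finals[eng].append(tr.sample_states[0, 1])
    p = sps.mannwhitneyu(finals["python"], finals["numba"]).pvalue
    assert p > 0.005


def test_event_stats_vs_L_trends():
    """Large L: at most terminal-clipping rejections.  Smaller L raises the
    rejected fraction on the noisy-circadian input; accepted counts stay
    statistically indistinguishable (the physical process is L-invariant)."""
    net = ex.build_two_stage_model(ex.TwoStageParams(ks=5.0, kdm=5.0, kdp=1.0))
    ou = ex.simulate_ou(ex.OUSpec(mean=0.0, gamma=0.15, variance=0.125), 1e-3, 48.0, seed=3)
    k = ex.modulated_circadian_rate(ou)
    tab = ex.event_stats_vs_L(net, [0, 0], k, 48.0, [0.05, 1.0, 48.0], seed=2)
    by_L = tab.set_index("L")
    assert by_L.loc[48.0, "n_rejected"] <= 1
    assert by_L.loc[0.05, "frac_rejected"] >= by_L.loc[1.0, "frac_rejected"]
    # accepted counts across L: same-law comparison via a rank test
    accs = {L: [] for L in (0.5, 48.0)}
    for L in accs:
        for s in np.random.SeedSequence(int(L * 10)).spawn(60):
            _, st = ex.extrande_simulate(
                net, [0, 0], k, 48.0, ex.BoundPolicy(strategy="monotone-sup", L=L),
                rng=np.random.default_rng(s), record_events=False,
                sample_grid=np.array([48.0]),
            )
            accs[L].append(st.n_accepted)
    assert sps.mannwhitneyu(accs[0.5], accs[48.0]).pvalue > 0.005
    with pytest.raises(InvalidParameterError):
        ex.event_stats_vs_L(net, [0, 0], k, 48.0, [], seed=0)


def test_choose_lookahead_and_adaptive_policy():
    net = ex.build_two_stage_model(ex.TwoStageParams(ks=5.0, kdm=5.0, kdp=1.0))
    k = ex.circadian_rate(kdp=1.0, dt=0.01, T=48.0)
    L = ex.choose_lookahead(net, [0, 0], k, 48.0, candidates=[0.1, 1.0, 10.0], seed=1)
    assert L in (0.1, 1.0, 10.0)
    tr, st = ex.extrande_simulate(
        net, [0, 0], k, 48.0,
        ex.BoundPolicy(strategy="monotone-sup", L=1.0, adaptive=True),
        seed=4, record_events=False, sample_grid=np.array([48.0]),
    )
    assert st.n_accepted > 0
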