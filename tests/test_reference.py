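import numpy as np
import pytest
from scipy import stats as sps

import extrande as ex
from extrande.exceptions import InvalidParameterError


def test_integral_config_validation():
    with pytest.raises(InvalidParameterError):
        ex.IntegralMethodConfig(integration_step=0.0)
    with pytest.raises(InvalidParameterError):
        ex.IntegralMethodConfig(integration_step=0.1, variant="magic")


def test_sia_equals_ssa_for_constant_input():
    """No staleness when the input never changes: SIA final counts are
    distributionally identical to the exact (thinning) simulator."""
    net = ex.build_birth_death(input_birth=True)
    cin = ex.constant_input(8.0, T=30.0)
    grid = np.array([30.0])
    finals = {"sia": [], "extrande": []}
    for s in np.random.SeedSequence(31).spawn(150):
        a, b = s.spawn(2)
        tr, _ = ex.sia_simulate(
            net, [0], cin, 30.0, rng=np.random.default_rng(a),
            record_events=False, sample_grid=grid,
        )
        finals["sia"].append(tr.sample_states[0, 0])
        tr, _ = ex.extrande_simulate(
            net, [0], cin, 30.0, ex.BoundPolicy(strategy="monotone-sup", L=1.0),
            rng=np.random.default_rng(b), record_events=False, sample_grid=grid,
        )
        finals["extrande"].append(tr.sample_states[0, 0])
    assert sps.mannwhitneyu(finals["sia"], finals["extrande"]).pvalue > 0.005
    assert abs(np.mean(finals["sia"]) - 8.0) < 3 * np.sqrt(8.0 / 150)


def test_sia_traps_at_zero_state_and_rate(two_stage_net):
    """Zero copy numbers while the stale transcription rate is zero: the
    stale-input method simulates no further reactions to T."""
    zero = ex.constant_input(0.0, T=10.0)
    tr, st = ex.sia_simulate(two_stage_net, [0, 0], zero, 10.0, seed=0)
    assert st.n_accepted == 0
    assert tr.meta["trapped"]
    assert tr.n_events == 0


def test_sia_trapping_via_input_grid(two_stage_net):
    """An input that switches off permanently traps cells once they empty."""
    grid = np.arange(0.0, 50.0 + 1e-9, 0.1)
    vals = np.where(grid < 5.0, 10.0, 0.0)
    tr, st = ex.sia_simulate(
        two_stage_net, [0, 0], ex.InputTrajectory(grid, vals), 50.0, seed=1
    )
    assert tr.meta["trapped"]
    ct, cs = tr._channel_view()
    assert (cs[-1] == 0).all()


def test_mn_constant_rate_waiting_times_are_exponential():
    """With constant propensities the integral method reduces to the
    next-reaction method: pure-birth waiting times are Exp(rate)."""
    net = ex.build_pure_birth(birth_rate=5.0, input_birth=False)
    cin = ex.constant_input(1.0, T=60.0)
    tr, _ = ex.mn_integral_simulate(
        net, [0], cin, 60.0, ex.IntegralMethodConfig(integration_step=0.05), seed=2
    )
    waits = np.diff(np.concatenate([[0.0], tr.times]))
    assert sps.kstest(waits, "expon", args=(0, 1 / 5.0)).pvalue > 0.005


def test_mn_constant_birth_death_mean():
    net = ex.build_birth_death(input_birth=True)
    k, T = 10.0, 300.0
    cin = ex.constant_input(k, T=T, dt=0.5)
    grid = np.arange(20.0, T, 0.5)
    tr, _ = ex.mn_integral_simulate(
        net, [0], cin, T, ex.IntegralMethodConfig(integration_step=0.02),
        seed=3, record_events=False, sample_grid=grid,
    )
    assert abs(tr.sample_states[:, 0].mean() - k) < 3 * np.sqrt(k / (T / 2))


def test_mn_time_varying_counts_match_analytic_integral():
    """Pure birth with the circadian rate over [0, 6] h: counts are Poisson
    with mean the analytic integral of the rate."""
    T = 6.0
    expected = 4.0 * T + 4.0 * (24.0 / (2 * np.pi)) * (1 - np.cos(2 * np.pi * T / 24.0))
    net = ex.build_pure_birth()
    lam = ex.circadian_rate(kdp=1.0, dt=1e-3, T=T)
    counts = []
    for s in np.random.SeedSequence(41).spawn(400):
        tr, _ = ex.mn_integral_simulate(
            net, [0], lam, T, ex.IntegralMethodConfig(integration_step=0.01),
            rng=np.random.default_rng(s), record_events=False,
            sample_grid=np.array([T]),
        )
        counts.append(tr.sample_states[0, 0])
    assert abs(np.mean(counts) - expected) < 3 * np.sqrt(expected / 400)


def test_mn_quadrature_error_decays_with_step():
    """Common unit-exponential targets across step sizes isolate the
    quadrature error: the count error decays monotonically as the step
    shrinks (convergence of the integral method to the exact law)."""
    T = 6.0
    exact = 4.0 * T + 4.0 * (24.0 / (2 * np.pi)) * (1 - np.cos(2 * np.pi * T / 24.0))
    net = ex.build_pure_birth()
    lam = ex.circadian_rate(kdp=1.0, dt=1e-3, T=T)
    errs = []
    for step in (3.0, 1.0, 0.05):
        counts = []
        for s in np.random.SeedSequence(99).spawn(300):  # same targets per step
            with np.errstate(all="ignore"):
                tr, _ = ex.mn_integral_simulate(
                    net, [0], lam, T, ex.IntegralMethodConfig(integration_step=step),
                    rng=np.random.default_rng(s), record_events=False,
                    sample_grid=np.array([T]),
                )
            counts.append(tr.sample_states[0, 0])
        errs.append(abs(np.mean(counts) - exact))
    assert errs[0] >= errs[1] >= errs[2] or errs[0] > errs[2]


def test_direct_integral_variant_birth_death_mean():
    net = ex.build_birth_death(input_birth=True)
    k, T = 10.0, 200.0
    cin = ex.constant_input(k, T=T, dt=0.5)
    grid = np.arange(20.0, T, 0.5)
    tr, _ = ex.mn_integral_simulate(
        net, [0], cin, T,
        ex.IntegralMethodConfig(integration_step=0.02, variant="direct"),
        seed=5, record_events=False, sample_grid=grid,
    )
    assert abs(tr.sample_states[:, 0].mean() - k) < 3 * np.sqrt(k / (T / 2))


def test_mn_warns_when_step_coarser_than_input_grid(two_stage_net):
    k = ex.circadian_rate(kdp=1.0, dt=0.01, T=2.0)
    with pytest.warns(UserWarning, match="coarser"):
        ex.mn_integral_simulate(
            two_stage_net, [0, 0], k, 2.0, ex.IntegralMethodConfig(integration_step=0.1),
            seed=6, record_events=False, sample_grid=np.array([2.0]),
        )


def test_propensity_eval_ratio_deterministic_and_step_dependent():
    net = ex.build_birth_death(input_birth=True)
    cin = ex.constant_input(10.0, T=50.0, dt=0.5)
    pol = ex.BoundPolicy(strategy="monotone-sup", L=1.0)
    coarse = ex.IntegralMethodConfig(integration_step=0.05)
    r1 = ex.propensity_eval_ratio(net, [0], cin, 50.0, coarse, policy=pol, seed=4)
    r2 = ex.propensity_eval_ratio(net, [0], cin, 50.0, coarse, policy=pol, seed=4)
    assert r1 == r2
    fine = ex.IntegralMethodConfig(integration_step=0.001)
    r3 = ex.propensity_eval_ratio(net, [0], cin, 50.0, fine, policy=pol, seed=4)
    # step ~ mean waiting time -> comparable work; 50x finer step -> ~50x more
    assert r1 < 5.0
    assert r3 > 5.0 * r1


def test_sia_spends_more_time_at_zero_than_extrande():
    """The stale-input method's error is explained by excess time with both
    mRNA and protein at zero (the trapping diagnostic)."""
    p = ex.benchmarks.alga_circadian_params(mean_protein=20.0)
    net = ex.build_two_stage_model(
        ex.TwoStageParams(ks=p["ks"], kdm=p["kdm"], kdp=p["kdp"])
    )
    k = ex.circadian_rate(kdp=p["kdp"], dt=1e-3, T=48.0)
    fr_sia, fr_ex = [], []
    for s in np.random.SeedSequence(55).spawn(15):
        a, b = s.spawn(2)
        tr, _ = ex.sia_simulate(net, [0, 0], k, 48.0, rng=np.random.default_rng(a))
        fr_sia.append(ex.zero_occupancy_fraction(tr, ["mRNA", "protein"]))
        tr, _ = ex.extrande_simulate(
            net, [0, 0], k, 48.0, ex.BoundPolicy(strategy="monotone-sup", L=0.25),
            rng=np.random.default_rng(b), engine="python",
        )
        fr_ex.append(ex.zero_occupancy_fraction(tr, ["mRNA", "protein"]))
    assert np.mean(fr_sia) > np.mean(fr_ex)
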