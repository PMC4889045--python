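import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import extrande as ex
from extrande.exceptions import InvalidParameterError, TrajectoryRangeError


# ------------------------------------------------------------------ queries
def test_value_at_interpolation_rules(step_traj):
    assert step_traj.value_at(1.5) == 3.0  # left-constant
    lin = ex.InputTrajectory(step_traj.grid, step_traj.values, interpolation="linear")
    assert lin.value_at(1.5) == pytest.approx(2.5)
    # exactly on a grid point both rules return the grid value
    for tr in (step_traj, lin):
        assert tr.value_at(1.0) == 3.0
    with pytest.raises(TrajectoryRangeError):
        step_traj.value_at(2.5)


def test_window_sup_examples(step_traj):
    assert step_traj.window_sup(0.0, 2.0) == 3.0
    assert step_traj.window_sup(0.0, 0.5) == 1.0
    assert step_traj.window_sup(1.2, 5.0) == 3.0  # carried-in value; clipped at T
    with pytest.raises(InvalidParameterError):
        step_traj.window_sup(0.0, 0.0)


@given(
    vals=st.lists(st.floats(min_value=-50, max_value=50), min_size=2, max_size=30),
    t0=st.floats(min_value=0.0, max_value=0.99),
    L=st.floats(min_value=0.01, max_value=1.5),
    interp=st.sampled_from(["previous", "linear"]),
    data=st.data(),
)
def test_window_sup_dominates_pointwise_values(vals, t0, L, interp, data):
    """The window supremum bounds the trajectory everywhere in [t, t+L)."""
    grid = np.linspace(0.0, 1.0, len(vals))
    tr = ex.InputTrajectory(grid, np.array(vals), interpolation=interp)
    t = t0
    sup = tr.window_sup(t, L)
    us = data.draw(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50)
    )
    for u in us:
        q = min(t + u * L * 0.999999, tr.T)
        assert tr.value_at(q) <= sup + 1e-9


# --------------------------------------------------------------- generators
def test_circadian_time_average_is_four_kdp():
    kdp = 0.37
    k = ex.circadian_rate(kdp=kdp, dt=1e-3, T=24.0)
    avg = np.trapezoid(k.values, k.grid) / 24.0
    assert avg / kdp == pytest.approx(4.0, abs=1e-9)


def test_ou_zero_variance_is_constant():
    tr = ex.simulate_ou(ex.OUSpec(mean=3.0, gamma=2.0, variance=0.0), 0.01, 5.0, seed=0)
    assert np.allclose(tr.values, 3.0)


def test_ou_moments_and_autocovariance():
    gamma, s2 = 1.0, 5.0
    T = 600.0
    tr = ex.simulate_ou(ex.OUSpec(mean=0.0, gamma=gamma, variance=s2), 1e-3, T, seed=3)
    var = tr.values.var()
    se_var = s2 * np.sqrt(2.0 / (gamma * T))
    assert abs(var - s2) < 3 * se_var
    # autocovariance at lag 1/gamma decays to sigma^2 / e
    lag = int(round(1.0 / gamma / 1e-3))
    acv = ex.sample_autocovariance(tr, [0, lag])
    assert acv[0] == pytest.approx(var, rel=1e-9)
    assert acv[1] == pytest.approx(s2 * np.exp(-1.0), abs=3 * se_var)


def test_ou_exact_scheme_matches_stationary_law():
    tr = ex.simulate_ou(
        ex.OUSpec(mean=10.0, gamma=0.5, variance=4.0), 0.01, 800.0, seed=5,
        scheme="exact",
    )
    assert abs(tr.values.mean() - 10.0) < 3 * np.sqrt(4.0 * 2 * 2 / 800.0)
    assert abs(tr.values.var() - 4.0) < 3 * 4.0 * np.sqrt(2 * 0.5 / 800.0 / 0.5)


def test_ou_reproducible_and_warns_on_coarse_step():
    spec = ex.OUSpec(mean=0.0, gamma=1.0, variance=1.0)
    a = ex.simulate_ou(spec, 1e-2, 10.0, seed=42)
    b = ex.simulate_ou(spec, 1e-2, 10.0, seed=42)
    assert np.array_equal(a.values, b.values)
    with pytest.warns(UserWarning, match="dt\\*gamma"):
        ex.simulate_ou(spec, 0.5, 10.0, seed=1)
    with pytest.raises(InvalidParameterError):
        ex.simulate_ou(spec, -0.1, 10.0)


def test_lognormal_normalization_constant():
    """<exp xi> = exp(sigma^2/2): for sigma^2 = 5 the normalization is
    exp(2.5) ~= 12.182, so k(t) = k_bar exp(-2.5) exp(xi)."""
    ou = ex.simulate_ou(ex.OUSpec(mean=0.0, gamma=1.0, variance=5.0), 0.01, 5.0, seed=2)
    k = ex.lognormal_normalized_rate(ou, k_bar=7.0)
    ratio = k.values / (7.0 * np.exp(ou.values))
    assert np.allclose(ratio, np.exp(-2.5))
    assert np.exp(2.5) == pytest.approx(12.182493960703473)


def test_lognormal_zero_variance_returns_k_bar():
    ou = ex.simulate_ou(ex.OUSpec(mean=0.0, gamma=1.0, variance=0.0), 0.01, 5.0, seed=2)
    k = ex.lognormal_normalized_rate(ou, k_bar=7.0, sigma2=0.0)
    assert np.allclose(k.values, 7.0)


def test_lognormal_stationary_mean_is_k_bar():
    gamma, s2, T = 1.0, 2.0, 2000.0
    ou = ex.simulate_ou(ex.OUSpec(mean=0.0, gamma=gamma, variance=s2), 1e-2, T, seed=9)
    k = ex.lognormal_normalized_rate(ou, k_bar=1.0)
    # SE of the ergodic average of a lognormal-of-OU: conservative bound via
    # the process variance (e^{s2}-1) and integrated autocorrelation ~2/gamma
    se = np.sqrt((np.exp(s2) - 1.0) * 2.0 / (gamma * T))
    assert abs(k.values.mean() - 1.0) < 3 * se


def test_lognormal_requires_known_variance():
    tr = ex.InputTrajectory(np.array([0.0, 1.0]), np.array([0.0, 0.1]))
    with pytest.raises(InvalidParameterError):
        ex.lognormal_normalized_rate(tr, k_bar=1.0)


def test_modulated_circadian_noiseless_limit():
    ou = ex.simulate_ou(ex.OUSpec(mean=0.0, gamma=1.0, variance=0.0), 1e-2, 24.0, seed=0)
    k = ex.modulated_circadian_rate(ou, amplitude=20.0, f=1.0 / 24.0)
    expect = 20.0 * (1.0 + np.sin(2 * np.pi * ou.grid / 24.0))
    assert np.allclose(k.values, expect)
    assert k.value_at(18.0) == pytest.approx(0.0, abs=1e-9)  # sin(3pi/2) = -1


def test_sum_of_ou_constants_and_variance():
    specs = [
        ex.OUSpec(mean=2.0, gamma=1.0, variance=0.0),
        ex.OUSpec(mean=5.0, gamma=3.0, variance=0.0),
    ]
    tr = ex.sum_of_ou(specs, 0.01, 5.0, seed=1)
    assert np.allclose(tr.values, 7.0)
    specs = [
        ex.OUSpec(mean=0.0, gamma=1.0, variance=2.0),
        ex.OUSpec(mean=0.0, gamma=4.0, variance=3.0),
    ]
    tr = ex.sum_of_ou(specs, 1e-2, 1500.0, seed=4)
    se = 5.0 * np.sqrt(2.0 / 1500.0) * 2
    assert abs(tr.values.var() - 5.0) < 3 * se


def test_sum_of_ou_two_exponential_autocovariance():
    """Autocovariance of the sum of independent OU paths is the sum of the
    component exponentials."""
    g1, g2, v1, v2 = 0.5, 5.0, 2.0, 3.0
    dt, T = 1e-2, 3000.0
    tr = ex.sum_of_ou(
        [ex.OUSpec(mean=0.0, gamma=g1, variance=v1),
         ex.OUSpec(mean=0.0, gamma=g2, variance=v2)],
        dt, T, seed=8,
    )
    lags = np.array([0, 20, 100, 300])  # 0, 0.2, 1, 3 h
    acv = ex.sample_autocovariance(tr, lags)
    expect = v1 * np.exp(-g1 * lags * dt) + v2 * np.exp(-g2 * lags * dt)
    se = (v1 + v2) * np.sqrt(2.0 * 2.0 / (g1 * T))  # slowest mode dominates
    assert np.all(np.abs(acv - expect) < 3 * se)


def test_autocovariance_recovers_ou_decay_rate():
    gamma = 2.0
    tr = ex.simulate_ou(ex.OUSpec(mean=0.0, gamma=gamma, variance=1.0), 1e-3, 400.0, seed=6)
    lags = np.arange(0, 500, 25)
    acv = ex.sample_autocovariance(tr, lags)
    slope = np.polyfit(lags * 1e-3, np.log(acv), 1)[0]
    assert -slope == pytest.approx(gamma, rel=0.15)


def test_csv_round_trip(tmp_path, step_traj):
    path = tmp_path / "traj.csv"
    step_traj.meta["generator"] = "handmade"
    step_traj.to_csv(path)
    back = ex.InputTrajectory.from_csv(path)
    assert np.allclose(back.grid, step_traj.grid)
    assert np.allclose(back.values, step_traj.values)
    assert back.interpolation == "previous"
    assert back.meta["generator"] == "handmade"


def test_clip_nonnegative_records_fraction():
    tr = ex.InputTrajectory(np.array([0.0, 1.0, 2.0, 3.0]), np.array([1.0, -2.0, 3.0, -1.0]))
    clipped = tr.clip_nonnegative()
    assert (clipped.values >= 0).all()
    assert clipped.meta["clip_fraction"] == pytest.approx(0.5)
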