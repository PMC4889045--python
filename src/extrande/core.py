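"""The Extrande simulator: thinning with a look-ahead propensity bound.

The algorithm simulates a reaction network whose propensities vary in time
under a pre-simulated exogenous input, *exactly* conditional on that input.
Each iteration: (i) choose a look-ahead horizon L <= T - t and a bound B with
a0(t+u) <= B for 0 <= u < L while the state is unchanged; (ii) draw a putative
waiting time tau ~ Exp(rate B); (iii) if tau > L the putative time is
*rejected* and the clock advances by L; otherwise the clock advances by tau,
the propensities are refreshed at the new time, and a single uniform u decides
both acceptance and channel choice: the smallest channel j with
cumsum(a)_j >= B*u fires if a0 >= B*u, else the draw is *thinned* (the
virtual channel fires and the state is unchanged).  The same uniform is
deliberately reused for the acceptance test and the channel selection.

Bound strategies
----------------
``window-max``
    B = safety * max over the input-grid evaluation points in [t, t+L) of
    a0(X, I(s), s).  Exact for step-function inputs (the trajectory only
    takes grid values); generic but costs one propensity-vector evaluation
    per grid point in the window.
``monotone-sup``
    B = safety * a0(X, sup_{[t,t+L)} I, t).  Valid only for networks that
    declare every propensity nondecreasing in the input; costs a single
    evaluation (this is the cheap bound that makes long ensemble runs fast).
``global``
    monotone-sup applied to the whole remaining horizon (L = T - t).

A detected a0 > B at an acceptance evaluation raises
:class:`~extrande.exceptions.BoundViolationError` — a hard failure, since the
sampled law would no longer be exact.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .exceptions import (
    BoundViolationError,
    ConsistencyError,
    InvalidParameterError,
    PropensityError,
)
from .inputs import InputTrajectory
from .network import ReactionNetwork
from .trajectory import REJECT, THIN, EventStats, Recorder, Trajectory

__all__ = [
    "BoundPolicy",
    "compute_bound",
    "extrande_simulate",
    "event_stats_vs_L",
    "choose_lookahead",
]

_BOUND_STRATEGIES = ("window-max", "monotone-sup", "global")


@dataclasses.dataclass
class BoundPolicy:
    """How the propensity bound B and look-ahead horizon L are chosen.

    ``L=None`` means the remaining horizon (L = T - t).  ``adaptive=True``
    enables an experimental heuristic (the base algorithm leaves the adaptive
    rule open): L doubles after 32 consecutive draws without a rejection and
    halves after each rejection, clamped to [L/64, 64 L] around the initial
    value.
    """

    strategy: str = "window-max"
    L: float | None = None
    safety_factor: float = 1.0
    adaptive: bool = False

    def __post_init__(self):
        if self.strategy not in _BOUND_STRATEGIES:
            raise InvalidParameterError(
                f"unknown bound strategy {self.strategy!r}; "
                f"choose from {_BOUND_STRATEGIES}"
            )
        if self.L is not None and self.L <= 0:
            raise InvalidParameterError(f"fixed look-ahead L must be > 0, got {self.L}")
        if self.safety_factor < 1.0:
            raise InvalidParameterError("safety_factor must be >= 1")


class _DrawBuffer:
    """Block-buffered Exp(1) and U(0,1) draws (vectorised RNG calls)."""

    __slots__ = ("rng", "n", "_exp", "_uni", "_ie", "_iu")

    def __init__(self, rng, n=8192):
        self.rng = rng
        self.n = n
        self._exp = rng.standard_exponential(n)
        self._uni = rng.random(n)
        self._ie = 0
        self._iu = 0

    def exponential(self):
        i = self._ie
        if i == self.n:
            self._exp = self.rng.standard_exponential(self.n)
            i = 0
        self._ie = i + 1
        return self._exp[i]

    def uniform(self):
        i = self._iu
        if i == self.n:
            self._uni = self.rng.random(self.n)
            i = 0
        self._iu = i + 1
        return self._uni[i]


def _window_points(traj: InputTrajectory, t: float, end: float):
    """(times, values) of the input-grid evaluation points covering [t, end)."""
    g, v = traj.grid, traj.values
    lo = max(int(np.searchsorted(g, t, side="right")) - 1, 0)
    if traj.interpolation == "previous":
        hi = max(int(np.searchsorted(g, end, side="left")), lo + 1)
        tt = g[lo:hi].copy()
        tt[0] = t  # the carried-in value applies from t
        return tt, v[lo:hi]
    hi = int(np.searchsorted(g, end, side="right"))
    tt = np.concatenate([[t], g[lo + 1 : hi], [end]])
    vv = np.concatenate([[traj.value_at(t)], v[lo + 1 : hi], [traj.value_at(end)]])
    return tt, vv


def compute_bound(
    net: ReactionNetwork,
    x,
    traj: InputTrajectory,
    t: float,
    policy: BoundPolicy,
    T: float | None = None,
    L_override: float | None = None,
):
    """Propensity bound for the window starting at t.

    Returns ``(B, L_effective, n_propensity_evaluations)``.  L is clipped to
    the remaining horizon T - t.  The bound holds provided no reaction channel
    fires in the window (the state is held fixed).
    """
    T = traj.T if T is None else T
    if t >= T:
        raise InvalidParameterError(f"t={t} must be < T={T}")
    L = L_override if L_override is not None else policy.L
    L_eff = (T - t) if L is None else min(L, T - t)
    x = np.asarray(x)
    a = np.empty(net.n_reactions)
    if policy.strategy == "window-max":
        tt, vv = _window_points(traj, t, t + L_eff)
        best = 0.0
        for s, val in zip(tt, vv):
            tot = net.propensities_into(x, val, s, a)
            if tot > best:
                best = tot
        return policy.safety_factor * best, L_eff, len(vv) * net.n_reactions
    if not net.input_monotone:
        raise InvalidParameterError(
            f"bound strategy {policy.strategy!r} requires a network declared "
            "input-monotone (every propensity nondecreasing in the input)"
        )
    if policy.strategy == "global":
        L_eff = T - t
        i_star = traj.global_sup()
    else:  # monotone-sup
        i_star = traj.window_sup(t, L_eff)
    tot = net.propensities_into(x, i_star, t, a)
    return policy.safety_factor * tot, L_eff, net.n_reactions


def _numba_eligible(net, traj, policy, record_events, sample_grid):
    from . import _kernels

    return (
        _kernels.HAVE_NUMBA
        and net.is_mass_action
        and traj.interpolation == "previous"
        and traj.uniform_dt is not None
        and policy.strategy == "monotone-sup"
        and net.input_monotone
        and not policy.adaptive
        and not record_events
        and sample_grid is not None
    )


def extrande_simulate(
    net: ReactionNetwork,
    x0,
    traj: InputTrajectory,
    T: float,
    policy: BoundPolicy | None = None,
    seed=None,
    *,
    rng=None,
    record_events: bool = True,
    sample_grid=None,
    engine: str = "auto",
):
    """Exact simulation of ``net`` on [0, T] conditional on ``traj``.

    Returns ``(Trajectory, EventStats)``.  ``record_events=False`` with a
    ``sample_grid`` keeps memory bounded for long ensemble runs (thin/reject
    pseudo-events are only stored when events are recorded).  ``engine``:
    ``auto`` uses the compiled mass-action kernel when the run qualifies
    (mass-action network, uniform step-function input, monotone-sup bound,
    grid-only recording), ``python``/``numba`` force one path.  The two
    engines sample the same law but consume distinct RNG streams.
    """
    if traj.T < T:
        raise InvalidParameterError(
            f"input trajectory covers [0, {traj.T}] but horizon T={T}"
        )
    policy = policy if policy is not None else BoundPolicy()
    rng = np.random.default_rng(seed) if rng is None else rng
    if engine not in ("auto", "python", "numba"):
        raise InvalidParameterError(f"unknown engine {engine!r}")
    if engine != "python":
        eligible = _numba_eligible(net, traj, policy, record_events, sample_grid)
        if engine == "numba" and not eligible:
            raise InvalidParameterError(
                "numba engine requires a mass-action, input-monotone network, "
                "a uniform step-function input, the monotone-sup bound and "
                "grid-only recording"
            )
        if eligible:
            return _extrande_numba(net, x0, traj, T, policy, rng, sample_grid)
    draws = _DrawBuffer(rng)
    x = np.asarray(x0, dtype=np.int64).copy()
    if (x < 0).any():
        raise InvalidParameterError("initial state has negative copy numbers")
    M = net.n_reactions
    S = net.S
    a = np.empty(M)
    props = net.propensities_into
    stats = EventStats()
    rec = Recorder(
        x,
        T,
        net.species_names,
        sample_grid=sample_grid,
        keep_events=record_events,
        channel_names=[r.name for r in net.reactions],
    )
    # interpolation fast path
    grid, vals = traj.grid, traj.values
    step_interp = traj.interpolation == "previous"

    # adaptive-L bookkeeping (experimental heuristic)
    adaptive = policy.adaptive
    L_init = policy.L if policy.L is not None else T
    L_cur = L_init
    streak = 0

    t = 0.0
    while t < T:
        L_override = min(L_cur, T - t) if adaptive else None
        B, L_eff, n_eval = compute_bound(
            net, x, traj, t, policy, T=T, L_override=L_override
        )
        stats.n_propensity_evaluations += n_eval
        if not math.isfinite(B):
            raise PropensityError(f"non-finite propensity bound B={B} at t={t}")
        if B <= 0.0:
            # nothing can fire while the state is unchanged: the whole window
            # is traversed; counted as an (automatic) rejection
            stats.n_rejected += 1
            stats.n_exponentials_drawn += 1
            t += L_eff
            rec.pseudo_event(t, REJECT)
            continue
        tau = draws.exponential() / B
        stats.n_exponentials_drawn += 1
        if tau > L_eff:
            t += L_eff
            stats.n_rejected += 1
            rec.pseudo_event(t, REJECT)
            if adaptive:
                L_cur = max(L_cur * 0.5, L_init / 64.0)
                streak = 0
            continue
        t += tau
        if adaptive:
            streak += 1
            if streak >= 32:
                L_cur = min(L_cur * 2.0, L_init * 64.0)
                streak = 0
        # refresh propensities at the accepted candidate time
        if step_interp:
            I_t = vals[grid.searchsorted(t, side="right") - 1]
        else:
            I_t = traj.value_at(t)
        a0 = props(x, I_t, t, a)
        stats.n_propensity_evaluations += M
        if not math.isfinite(a0) or (a < 0.0).any():
            bad = int(np.argmin(a)) if np.isfinite(a0) else -1
            raise PropensityError(
                f"invalid propensity vector {a} at t={t:.6g}, state {x}",
                channel=None if bad < 0 else net.reactions[bad].name,
            )
        if a0 > B * (1.0 + 1e-9):
            raise BoundViolationError(
                f"a0(t)={a0:.6g} exceeded bound B={B:.6g} at t={t:.6g} "
                f"(state {x}): the thinning bound is not valid for this "
                "input/policy combination"
            )
        Bu = B * draws.uniform()
        if a0 >= Bu:
            # smallest j with cumulative propensity >= B*u (single uniform
            # reused for acceptance and channel selection)
            if Bu <= 0.0:
                j = int(np.argmax(a > 0.0))
            else:
                j = int(np.searchsorted(np.cumsum(a), Bu, side="left"))
            x += S[j]
            if (x < 0).any():
                raise ConsistencyError(
                    f"channel {net.reactions[j].name!r} drove state negative "
                    f"at t={t:.6g}; its propensity must vanish when a "
                    "consumed species is exhausted"
                )
            stats.n_accepted += 1
            rec.state_change(t, j, x)
        else:
            stats.n_thinned += 1
            rec.pseudo_event(t, THIN)
    return (
        rec.finalize(
            meta={
                "method": "extrande",
                "policy": dataclasses.asdict(policy),
                "channel_names": [r.name for r in net.reactions],
            }
        ),
        stats,
    )


def _extrande_numba(net, x0, traj, T, policy, rng, sample_grid):
    from . import _kernels

    rates, orders, iscaled = net.mass_action_arrays()
    sgrid = np.asarray(sample_grid, dtype=float)
    out = np.empty((len(sgrid), net.n_species), dtype=np.int64)
    stats_vec = np.zeros(5, dtype=np.int64)
    x0 = np.asarray(x0, dtype=np.int64)
    if (x0 < 0).any():
        raise InvalidParameterError("initial state has negative copy numbers")
    L = float(T) if policy.L is None else float(policy.L)
    kseed = int(rng.integers(2**31))
    rc = _kernels.extrande_ma_kernel(
        net.S,
        rates,
        orders,
        iscaled,
        traj.values,
        1.0 / traj.uniform_dt,
        float(T),
        L,
        float(policy.safety_factor),
        kseed,
        sgrid,
        out,
        stats_vec,
        x0,
    )
    if rc == -1:
        raise BoundViolationError(
            "total propensity exceeded the bound B at an acceptance "
            "evaluation (compiled kernel); the thinning bound is not valid "
            "for this input/policy combination"
        )
    stats = EventStats(
        n_accepted=int(stats_vec[0]),
        n_thinned=int(stats_vec[1]),
        n_rejected=int(stats_vec[2]),
        n_propensity_evaluations=int(stats_vec[3]),
        n_exponentials_drawn=int(stats_vec[4]),
    )
    traj_out = Trajectory(
        x0=x0.copy(),
        t0=0.0,
        T=float(T),
        species_names=net.species_names,
        sample_times=sgrid,
        sample_states=out,
        meta={
            "method": "extrande",
            "engine": "numba",
            "policy": dataclasses.asdict(policy),
            "channel_names": [r.name for r in net.reactions],
        },
    )
    return traj_out, stats


def event_stats_vs_L(
    net, x0, traj, T, L_values, seed=None, policy: BoundPolicy | None = None
):
    """Run once per fixed look-ahead L and tabulate the event statistics.

    Returns a DataFrame with accepted/thinned/rejected counts and fractions
    and the propensity-evaluation count, one row per L (independent seeds
    spawned from ``seed``).
    """
    import pandas as pd

    L_values = list(L_values)
    if not L_values:
        raise InvalidParameterError("L_values must be non-empty")
    base = policy or BoundPolicy(strategy="monotone-sup")
    ss = np.random.SeedSequence(seed)
    rows = []
    for L, child in zip(L_values, ss.spawn(len(L_values))):
        pol = dataclasses.replace(base, L=float(L), adaptive=False)
        _, st = extrande_simulate(
            net, x0, traj, T, pol, rng=np.random.default_rng(child), record_events=False
        )
        frac = st.fractions()
        rows.append(
            {
                "L": float(L),
                "n_accepted": st.n_accepted,
                "n_thinned": st.n_thinned,
                "n_rejected": st.n_rejected,
                "frac_accepted": frac["accepted"],
                "frac_thinned": frac["thinned"],
                "frac_rejected": frac["rejected"],
                "n_propensity_evaluations": st.n_propensity_evaluations,
                "n_exponentials_drawn": st.n_exponentials_drawn,
            }
        )
    return pd.DataFrame(rows)


def choose_lookahead(
    net,
    x0,
    traj,
    T,
    candidates=None,
    seed=None,
    policy: BoundPolicy | None = None,
    pilot_T: float | None = None,
):
    """Pick a look-ahead horizon by a short pilot scan.

    Runs a pilot simulation for each candidate L (log-spaced over
    [T/1000, T] by default) and returns the L minimising the total work
    proxy ``n_propensity_evaluations + n_exponentials_drawn``.
    """
    if candidates is None:
        candidates = np.geomspace(T / 1000.0, T, 7)
    pilot_T = min(T, pilot_T) if pilot_T else min(T, max(T / 10.0, 10 * max(candidates[0], 1e-9)))
    tab = event_stats_vs_L(net, x0, traj, pilot_T, candidates, seed=seed, policy=policy)
    cost = tab["n_propensity_evaluations"] + tab["n_exponentials_drawn"]
    return float(tab["L"].iloc[int(np.argmin(cost.to_numpy()))])
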