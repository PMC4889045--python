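"""Reference simulation methods for time-varying propensities.

Two competing approaches are implemented for comparison with the thinning
simulator in :mod:`extrande.core`:

* **SIA** (Slow Input Approximation): a classic SSA loop in which the input is
  approximated by a piecewise-constant function whose value can only change
  when a biomolecular reaction fires.  Both the waiting time *and* the channel
  selection use the stale input value sampled at the previous firing.  This is
  an approximation, faithfully reproduced here including its pathological
  trapping: if the total propensity reaches exactly zero, no further reaction
  can ever fire (the input is never re-read), so the simulation runs silently
  to T with a logged warning.

* **Modified-next integral method**: the next-reaction construction in which
  each channel j carries a unit-exponential target P_j and an internal clock
  T_j = integral of a_j; propensities are accumulated by the trapezoidal rule
  stepping on the union of the input grid and a configured integration step.
  Within the crossing step the firing time solves the trapezoid's linear
  interpolant (or is bisected, per config).  The method is exact up to
  numerical quadrature error, at the cost of one propensity-vector evaluation
  per integration step.  A direct-integral variant (single integral of a0 to a
  unit-exponential target, channel chosen proportional to a_j at the firing
  time) is available behind ``variant="direct"``.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings

import numpy as np

from .core import BoundPolicy, extrande_simulate
from .exceptions import InvalidParameterError, PropensityError
from .inputs import InputTrajectory
from .network import ReactionNetwork
from .trajectory import EventStats, Recorder, Trajectory

__all__ = [
    "IntegralMethodConfig",
    "sia_simulate",
    "mn_integral_simulate",
    "propensity_eval_ratio",
]

logger = logging.getLogger("extrande")


@dataclasses.dataclass
class IntegralMethodConfig:
    """Configuration of the integral method.

    ``integration_step`` (hours) sets the trapezoid step; accuracy is governed
    by the coarser of this and the input grid.  ``root_rule`` chooses how the
    within-step firing time is located on the linear propensity interpolant.
    """

    integration_step: float
    variant: str = "modified-next"
    root_rule: str = "linear-interpolant-solve"

    def __post_init__(self):
        if self.integration_step <= 0:
            raise InvalidParameterError(
                f"integration_step must be > 0, got {self.integration_step}"
            )
        if self.variant not in ("modified-next", "direct"):
            raise InvalidParameterError(f"unknown variant {self.variant!r}")
        if self.root_rule not in ("linear-interpolant-solve", "bisection"):
            raise InvalidParameterError(f"unknown root rule {self.root_rule!r}")


# --------------------------------------------------------------------- SIA
def sia_simulate(
    net: ReactionNetwork,
    x0,
    traj: InputTrajectory,
    T: float,
    seed=None,
    *,
    rng=None,
    record_events: bool = True,
    sample_grid=None,
    engine: str = "auto",
):
    """SSA with the input frozen between reaction firings (SIA).

    Returns ``(Trajectory, EventStats)``.  The input value used for the
    propensities is I at the time of the *last* firing (I(0) initially); it is
    refreshed only when a reaction fires.  If the total propensity hits zero
    the run is trapped: no further events to T (warning logged,
    ``meta['trapped'] = True``).
    """
    if traj.T < T:
        raise InvalidParameterError(
            f"input trajectory covers [0, {traj.T}] but horizon T={T}"
        )
    rng = np.random.default_rng(seed) if rng is None else rng
    if (
        engine != "python"
        and net.is_mass_action
        and traj.interpolation == "previous"
        and traj.uniform_dt is not None
        and not record_events
        and sample_grid is not None
    ):
        return _sia_numba(net, x0, traj, T, rng, sample_grid)
    if engine == "numba":
        raise InvalidParameterError(
            "numba engine requires a mass-action network, a uniform "
            "step-function input and grid-only recording"
        )
    x = np.asarray(x0, dtype=np.int64).copy()
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
    grid, vals = traj.grid, traj.values
    step_interp = traj.interpolation == "previous"
    exp_buf = rng.standard_exponential(4096)
    uni_buf = rng.random(4096)
    ib = 0
    trapped = False

    I_stale = traj.value_at(0.0)
    t = 0.0
    while True:
        a0 = props(x, I_stale, t, a)
        stats.n_propensity_evaluations += M
        if not math.isfinite(a0) or (a < 0.0).any():
            raise PropensityError(
                f"invalid propensity vector {a} at t={t:.6g}, state {x}"
            )
        if a0 <= 0.0:
            trapped = True
            logger.warning(
                "SIA trapped at t=%.4g h (total stale propensity 0); "
                "no further events to T=%.4g h",
                t,
                T,
            )
            break
        if ib == 4096:
            exp_buf = rng.standard_exponential(4096)
            uni_buf = rng.random(4096)
            ib = 0
        t += exp_buf[ib] / a0
        if t >= T:
            ib += 1
            break
        # channel selection with the *stale* propensities
        j = int(np.searchsorted(np.cumsum(a), a0 * uni_buf[ib], side="left"))
        j = min(j, M - 1)
        ib += 1
        x += S[j]
        stats.n_accepted += 1
        stats.n_exponentials_drawn += 1
        rec.state_change(t, j, x)
        # the input value only updates when a reaction fires
        if step_interp:
            I_stale = vals[grid.searchsorted(t, side="right") - 1]
        else:
            I_stale = traj.value_at(t)
    return (
        rec.finalize(
            meta={
                "method": "sia",
                "trapped": trapped,
                "channel_names": [r.name for r in net.reactions],
            }
        ),
        stats,
    )


def _sia_numba(net, x0, traj, T, rng, sample_grid):
    from . import _kernels

    rates, orders, iscaled = net.mass_action_arrays()
    sgrid = np.asarray(sample_grid, dtype=float)
    out = np.empty((len(sgrid), net.n_species), dtype=np.int64)
    stats_vec = np.zeros(5, dtype=np.int64)
    x0 = np.asarray(x0, dtype=np.int64)
    kseed = int(rng.integers(2**31))
    trapped = _kernels.sia_ma_kernel(
        net.S,
        rates,
        orders,
        iscaled,
        traj.values,
        1.0 / traj.uniform_dt,
        float(T),
        kseed,
        sgrid,
        out,
        stats_vec,
        x0,
    )
    if trapped:
        logger.warning(
            "SIA trapped (total stale propensity 0); no further events to T=%.4g h", T
        )
    stats = EventStats(
        n_accepted=int(stats_vec[0]),
        n_propensity_evaluations=int(stats_vec[3]),
        n_exponentials_drawn=int(stats_vec[0]),
    )
    traj_out = Trajectory(
        x0=x0.copy(),
        t0=0.0,
        T=float(T),
        species_names=net.species_names,
        sample_times=sgrid,
        sample_states=out,
        meta={
            "method": "sia",
            "engine": "numba",
            "trapped": bool(trapped),
            "channel_names": [r.name for r in net.reactions],
        },
    )
    return traj_out, stats


# ---------------------------------------------------------------- integral
def _crossing_time(a_lo, slope, need, h, rule):
    """Smallest s in (0, h] with a_lo*s + slope*s^2/2 = need (a linear
    propensity interpolant), assuming the step integral reaches `need`."""
    if rule == "bisection":
        f = lambda s: a_lo * s + 0.5 * slope * s * s - need
        lo, hi = 0.0, h
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if f(mid) < 0.0:
                lo = mid
            else:
                hi = mid
        return hi
    if abs(slope) < 1e-300 or a_lo * a_lo > 1e12 * abs(2.0 * slope * need):
        # effectively constant propensity within the step
        return need / a_lo if a_lo > 0 else h
    disc = a_lo * a_lo + 2.0 * slope * need
    if disc < 0.0:
        return h
    s = (math.sqrt(disc) - a_lo) / slope
    if s < 0.0 or s > h:
        # fall back: other root / clamp
        s = min(max(s, 0.0), h)
    return s


def mn_integral_simulate(
    net: ReactionNetwork,
    x0,
    traj: InputTrajectory,
    T: float,
    cfg: IntegralMethodConfig,
    seed=None,
    *,
    rng=None,
    record_events: bool = True,
    sample_grid=None,
):
    """Next-reaction simulation by numerical integration of the propensities.

    Returns ``(Trajectory, EventStats)``.  See the module docstring for the
    construction; ``EventStats.n_propensity_evaluations`` records the
    per-channel evaluation count that dominates the method's CPU time.
    """
    if traj.T < T:
        raise InvalidParameterError(
            f"input trajectory covers [0, {traj.T}] but horizon T={T}"
        )
    h_in = float(np.min(np.diff(traj.grid)))
    if cfg.integration_step > h_in * (1.0 + 1e-9) and len(traj.grid) > 2:
        warnings.warn(
            f"integration_step {cfg.integration_step:.3g} h is coarser than the "
            f"input grid ({h_in:.3g} h); accuracy is governed by the coarser step",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed) if rng is None else rng
    x = np.asarray(x0, dtype=np.int64).copy()
    M = net.n_reactions
    S = net.S
    direct = cfg.variant == "direct"
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

    # step points: union of the input grid and the uniform integration grid
    n_int = int(np.ceil(T / cfg.integration_step))
    int_grid = np.linspace(0.0, n_int * cfg.integration_step, n_int + 1)
    pts = np.union1d(traj.grid[(traj.grid > 0) & (traj.grid < T)], int_grid[1:])
    pts = pts[pts <= T]
    if len(pts) == 0 or pts[-1] < T:
        pts = np.append(pts, T)

    val_at = traj.value_at
    a_prev = np.empty(M)
    a_new = np.empty(M)
    props(x, val_at(0.0), 0.0, a_prev)
    stats.n_propensity_evaluations += M
    if direct:
        targets = rng.standard_exponential()
        clocks = 0.0
    else:
        targets = rng.standard_exponential(M)
        clocks = np.zeros(M)
    stats.n_exponentials_drawn += 1 if direct else M

    t_cur = 0.0
    ptr = 0
    while ptr < len(pts):
        t_next = pts[ptr]
        h = t_next - t_cur
        if h <= 0.0:
            ptr += 1
            continue
        props(x, val_at(t_next), t_next, a_new)
        stats.n_propensity_evaluations += M
        if direct:
            a0_lo = a_prev.sum()
            a0_hi = a_new.sum()
            dT = 0.5 * (a0_lo + a0_hi) * h
            if clocks + dT < targets:
                clocks += dT
                a_prev, a_new = a_new, a_prev
                t_cur = t_next
                ptr += 1
                continue
            slope = (a0_hi - a0_lo) / h
            s = _crossing_time(a0_lo, slope, targets - clocks, h, cfg.root_rule)
            t_fire = t_cur + s
            # channel chosen proportional to a_j at the firing time
            props(x, val_at(t_fire), t_fire, a_new)
            stats.n_propensity_evaluations += M
            a0 = a_new.sum()
            j = int(np.searchsorted(np.cumsum(a_new), a0 * rng.random(), side="left"))
            j = min(j, M - 1)
            clocks = 0.0
            targets = rng.standard_exponential()
            stats.n_exponentials_drawn += 1
        else:
            dT = 0.5 * (a_prev + a_new) * h
            crossing = clocks + dT >= targets
            if not crossing.any():
                clocks += dT
                a_prev, a_new = a_new, a_prev
                t_cur = t_next
                ptr += 1
                continue
            slopes = (a_new - a_prev) / h
            s_best = np.inf
            j = -1
            for jj in np.flatnonzero(crossing):
                s = _crossing_time(
                    a_prev[jj], slopes[jj], targets[jj] - clocks[jj], h, cfg.root_rule
                )
                if s < s_best:
                    s_best, j = s, int(jj)
            s = s_best
            t_fire = t_cur + s
            # advance every internal clock to the firing time
            clocks += a_prev * s + 0.5 * slopes * s * s
            targets[j] += rng.standard_exponential()
            stats.n_exponentials_drawn += 1
        x += S[j]
        stats.n_accepted += 1
        rec.state_change(t_fire, j, x)
        props(x, val_at(t_fire), t_fire, a_prev)
        stats.n_propensity_evaluations += M
        t_cur = t_fire
        # ptr unchanged: finish the partial step to pts[ptr]
    return (
        rec.finalize(
            meta={
                "method": "direct-integral" if direct else "mn-integral",
                "integration_step": cfg.integration_step,
                "channel_names": [r.name for r in net.reactions],
            }
        ),
        stats,
    )


def propensity_eval_ratio(
    net,
    x0,
    traj,
    T,
    cfg: IntegralMethodConfig,
    policy: BoundPolicy | None = None,
    seed=None,
):
    """Ratio of integral-method to Extrande propensity-evaluation counts.

    Both methods run on the identical pre-simulated input; the count ratio is
    the hardware-independent surrogate for the CPU-time ratio (propensity
    evaluation dominates the integral method's cost).  Deterministic given
    seeds and configs.
    """
    ss = np.random.SeedSequence(seed)
    s_mn, s_ex = ss.spawn(2)
    _, st_mn = mn_integral_simulate(
        net, x0, traj, T, cfg, rng=np.random.default_rng(s_mn), record_events=False
    )
    _, st_ex = extrande_simulate(
        net,
        x0,
        traj,
        T,
        policy or BoundPolicy(strategy="monotone-sup", L=min(1.0, T)),
        rng=np.random.default_rng(s_ex),
        record_events=False,
    )
    return st_mn.n_propensity_evaluations / st_ex.n_propensity_evaluations
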