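"""Cell ensembles and the competence decision mechanic.

An ensemble run simulates ``n_cells`` independent cells, each with its own
RNG stream (spawned from a master seed) and either its own input realization
or one shared pre-generated input.  The population mean is accumulated on a
fixed output grid by sampling each cell's piecewise-constant path.

The fate layer models differentiation driven by a master regulator ("ComK"):
progress to competence is the running integral

    Progress(t) = k_diff * integral_0^t ComK(s) ds,

and a cell enters (functional) competence when Progress reaches 1.  Because
the simulated ComK path is piecewise constant, Progress is piecewise linear
and the crossing is solved exactly.  Per-cell outcomes carry the entry time,
the time-averaged input <pComA> over the experiment window, and the final
progress; the population summary is the competent fraction (with binomial
standard error) and a logistic regression of entry probability on <pComA>.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .core import BoundPolicy, extrande_simulate
from .exceptions import InvalidParameterError, SimulationError
from .inputs import InputTrajectory
from .network import ReactionNetwork
from .reference import IntegralMethodConfig, mn_integral_simulate, sia_simulate
from .trajectory import Trajectory

__all__ = [
    "CellOutcome",
    "EnsembleResult",
    "run_ensemble",
    "progress_to_competence",
    "competent_fraction",
    "prob_competence_vs_mean_input",
    "LogisticCompetenceFit",
]

logger = logging.getLogger("extrande")


@dataclasses.dataclass
class CellOutcome:
    """Per-cell fate summary."""

    cell_id: int
    seed: int
    entry_time: float | None = None
    mean_input: float | None = None
    final_progress: float | None = None


@dataclasses.dataclass
class EnsembleResult:
    """Outcome of an ensemble run."""

    n_cells: int
    method: str
    mean_grid: np.ndarray
    mean_states: np.ndarray  # (n_grid, n_species) population mean
    species_names: list
    outcomes: list
    seeds: list
    shared_input: bool = False
    trajectories: list | None = None  # kept only on request

    def mean_species(self, name: str) -> np.ndarray:
        return self.mean_states[:, self.species_names.index(name)]

    def outcomes_frame(self):
        import pandas as pd

        return pd.DataFrame([dataclasses.asdict(o) for o in self.outcomes])


def _simulate(method, net, x0, traj, T, rng, sample_grid, record_events, policy, mn_cfg):
    if method == "extrande":
        return extrande_simulate(
            net,
            x0,
            traj,
            T,
            policy or BoundPolicy(strategy="monotone-sup", L=min(0.5, T)),
            rng=rng,
            record_events=record_events,
            sample_grid=sample_grid,
        )
    if method == "sia":
        return sia_simulate(
            net, x0, traj, T, rng=rng, record_events=record_events, sample_grid=sample_grid
        )
    if method in ("mn-integral", "direct-integral"):
        cfg = mn_cfg or IntegralMethodConfig(integration_step=1e-3)
        if method == "direct-integral":
            cfg = dataclasses.replace(cfg, variant="direct")
        return mn_integral_simulate(
            net, x0, traj, T, cfg, rng=rng, record_events=record_events, sample_grid=sample_grid
        )
    raise InvalidParameterError(f"unknown method {method!r}")


def run_ensemble(
    n_cells: int,
    net_factory,
    input_factory,
    method: str = "extrande",
    T: float = 24.0,
    master_seed=0,
    shared_input: bool = False,
    output_grid=None,
    x0=None,
    policy: BoundPolicy | None = None,
    mn_config: IntegralMethodConfig | None = None,
    progress_species: str | None = None,
    k_diff: float | None = None,
    T_exp: float | None = None,
    clip_input: bool = False,
    record_events: bool | None = None,
    keep_trajectories: bool = False,
) -> EnsembleResult:
    """Simulate an ensemble of cells and aggregate population statistics.

    ``net_factory`` is a ReactionNetwork or a zero-argument callable building
    one; ``input_factory`` is an InputTrajectory (implies a shared input) or a
    callable ``f(seed) -> InputTrajectory``.  With ``shared_input=True`` one
    realization is pre-generated and reused by every cell; otherwise each cell
    receives an independent realization.  Per-cell RNG streams are spawned
    from ``master_seed``, so results are reproducible and independent of
    scheduling.  If ``progress_species`` and ``k_diff`` are given, per-cell
    competence outcomes are computed over ``[0, T_exp]`` (default T).
    """
    if n_cells < 1:
        raise InvalidParameterError(f"n_cells must be >= 1, got {n_cells}")
    net = net_factory() if callable(net_factory) else net_factory
    x0 = np.zeros(net.n_species, dtype=np.int64) if x0 is None else np.asarray(x0)
    T_exp = T if T_exp is None else T_exp
    if output_grid is None:
        output_grid = np.linspace(0.0, T, 201)
    output_grid = np.asarray(output_grid, dtype=float)
    fate = progress_species is not None
    if fate:
        if k_diff is None or k_diff <= 0:
            raise InvalidParameterError("fate runs need k_diff > 0")
        if progress_species not in net.species_names:
            raise InvalidParameterError(
                f"species {progress_species!r} not in network {net.species_names}"
            )
    if record_events is None:
        record_events = fate

    ss = np.random.SeedSequence(master_seed)
    cell_seeds = ss.spawn(n_cells)
    shared_traj = None
    if isinstance(input_factory, InputTrajectory):
        shared_traj = input_factory
        shared_input = True
    elif shared_input:
        shared_traj = input_factory(_seed_int(ss.spawn(1)[0]))
    if shared_traj is not None and clip_input:
        shared_traj = shared_traj.clip_nonnegative()

    mean_acc = np.zeros((len(output_grid), net.n_species))
    outcomes: list[CellOutcome] = []
    seeds = []
    trajectories = [] if keep_trajectories else None
    for i, cseed in enumerate(cell_seeds):
        input_ss, sim_ss = cseed.spawn(2)
        seed_int = _seed_int(sim_ss)
        seeds.append(seed_int)
        try:
            if shared_traj is not None:
                traj_in = shared_traj
            else:
                traj_in = input_factory(_seed_int(input_ss))
                if clip_input:
                    traj_in = traj_in.clip_nonnegative()
            cell_traj, _ = _simulate(
                method,
                net,
                x0,
                traj_in,
                T,
                np.random.default_rng(sim_ss),
                output_grid,
                record_events,
                policy,
                mn_config,
            )
        except Exception as exc:  # annotate for resumability
            raise SimulationError(
                f"cell {i} (seed {seed_int}) failed: {exc}"
            ) from exc
        mean_acc += cell_traj.sample_states
        if fate:
            prog_T, entry = progress_to_competence(
                cell_traj, progress_species, k_diff, at=T_exp
            )
            gmask = traj_in.grid <= T_exp
            mean_in = float(
                np.trapezoid(traj_in.values[gmask], traj_in.grid[gmask])
                / (traj_in.grid[gmask][-1] - traj_in.grid[0])
            )
            outcomes.append(
                CellOutcome(
                    cell_id=i,
                    seed=seed_int,
                    entry_time=entry if (entry is not None and entry <= T_exp) else None,
                    mean_input=mean_in,
                    final_progress=prog_T,
                )
            )
        else:
            outcomes.append(CellOutcome(cell_id=i, seed=seed_int))
        if keep_trajectories:
            trajectories.append(cell_traj)
    return EnsembleResult(
        n_cells=n_cells,
        method=method,
        mean_grid=output_grid,
        mean_states=mean_acc / n_cells,
        species_names=net.species_names,
        outcomes=outcomes,
        seeds=seeds,
        shared_input=shared_traj is not None,
        trajectories=trajectories,
    )


def _seed_int(seed_seq: np.random.SeedSequence) -> int:
    return int(seed_seq.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


# ------------------------------------------------------------------- fate
def progress_to_competence(
    traj: Trajectory, species: str, k_diff: float, at: float | None = None
):
    """Progress(t) = k_diff * integral of the species path; entry at 1.

    The species path is piecewise constant, so Progress is piecewise linear
    and the crossing of 1 is solved exactly within its segment.  Returns
    ``(final_progress, entry_time_or_None)``; with ``at`` given, progress is
    evaluated at that time instead of T.
    """
    if k_diff <= 0:
        raise InvalidParameterError(f"k_diff must be > 0, got {k_diff}")
    i = traj.species_names.index(species)
    horizon = traj.T if at is None else float(at)
    if traj.has_events:
        ct, cs = traj._channel_view()
        times = np.concatenate([[traj.t0], ct])
        levels = np.concatenate([[traj.x0[i]], cs[:, i]]).astype(float)
    else:
        times = traj.sample_times
        levels = traj.sample_states[:, i].astype(float)
    times = np.minimum(times, horizon)
    seg_end = np.concatenate([times[1:], [horizon]])
    durations = np.maximum(seg_end - times, 0.0)
    increments = k_diff * levels * durations
    cum = np.concatenate([[0.0], np.cumsum(increments)])
    final = float(cum[-1])
    entry = None
    if final >= 1.0:
        seg = int(np.searchsorted(cum, 1.0, side="left")) - 1
        rate = k_diff * levels[seg]
        entry = float(times[seg] + (1.0 - cum[seg]) / rate)
    return final, entry


def competent_fraction(outcomes, T_exp: float):
    """Fraction of cells with entry time <= T_exp, with binomial SE."""
    n = len(outcomes)
    if n == 0:
        raise InvalidParameterError("no outcomes")
    k = sum(1 for o in outcomes if o.entry_time is not None and o.entry_time <= T_exp)
    frac = k / n
    se = float(np.sqrt(frac * (1.0 - frac) / n))
    return frac, se


@dataclasses.dataclass
class LogisticCompetenceFit:
    """Two-parameter logistic curve of entry probability vs mean input."""

    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    converged: bool
    separated: bool
    fitted_probabilities: np.ndarray

    def predict(self, mean_input):
        z = self.intercept + self.slope * np.asarray(mean_input, dtype=float)
        return 1.0 / (1.0 + np.exp(-z))


def prob_competence_vs_mean_input(outcomes) -> LogisticCompetenceFit:
    """Maximum-likelihood logistic regression of competence on <pComA>.

    Needs both classes present for a stable fit.  Under complete separation
    the ML estimate diverges; the fit falls back to a lightly L2-regularised
    Newton solve and is flagged ``separated=True``.
    """
    import statsmodels.api as sm

    y = np.array(
        [1.0 if o.entry_time is not None else 0.0 for o in outcomes], dtype=float
    )
    x = np.array([o.mean_input for o in outcomes], dtype=float)
    if np.any(~np.isfinite(x)):
        raise InvalidParameterError("outcomes lack mean_input values")
    if len(np.unique(y)) < 2 or min((y == 0).sum(), (y == 1).sum()) < 2:
        raise InvalidParameterError(
            "need at least 2 outcomes of each class for a stable logistic fit"
        )
    X = sm.add_constant(x)
    separated = False
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", True))
        params, bse = res.params, res.bse
        fitted = res.predict(X)
        if not np.all(np.isfinite(bse)) or np.max(np.abs(params)) > 1e6:
            raise _Separation()
        if not converged:
            raise _Separation()
    except (Exception,) as exc:  # PerfectSeparationError or unstable fit
        separated = True
        logger.warning("logistic fit separated/unstable (%s); using ridge fallback", exc)
        params, bse, fitted = _ridge_logistic(X, y, alpha=1e-3)
        converged = True
    return LogisticCompetenceFit(
        intercept=float(params[0]),
        slope=float(params[1]),
        intercept_se=float(bse[0]),
        slope_se=float(bse[1]),
        converged=converged,
        separated=separated,
        fitted_probabilities=np.asarray(fitted, dtype=float),
    )


class _Separation(Exception):
    pass


def _ridge_logistic(X, y, alpha=1e-3, n_iter=100):
    """L2-regularised logistic fit by Newton's method (standardised slope)."""
    # standardise the covariate so alpha acts on a unit scale
    mu, sd = X[:, 1].mean(), X[:, 1].std() or 1.0
    Z = X.copy()
    Z[:, 1] = (X[:, 1] - mu) / sd
    beta = np.zeros(2)
    lam = np.array([0.0, alpha])  # do not shrink the intercept
    for _ in range(n_iter):
        eta = Z @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1.0 - p), 1e-10)
        grad = Z.T @ (y - p) - lam * beta
        H = (Z * w[:, None]).T @ Z + np.diag(lam + 1e-12)
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    cov = np.linalg.inv(H)
    # back-transform to the original covariate scale
    slope = beta[1] / sd
    intercept = beta[0] - beta[1] * mu / sd
    se_slope = np.sqrt(cov[1, 1]) / sd
    se_int = np.sqrt(cov[0, 0] + (mu / sd) ** 2 * cov[1, 1])
    p = 1.0 / (1.0 + np.exp(-(X @ np.array([intercept, slope]))))
    return np.array([intercept, slope]), np.array([se_int, se_slope]), p
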