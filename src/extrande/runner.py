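"""Run execution: build the model and input from a config, simulate, report.

Artifacts written to ``output_dir``: ``trajectory.csv`` (time, event label,
species columns), ``stats.json`` (event statistics including the thin /
reject / accept tallies), ``resolved_config.yaml`` (echo of the validated
configuration) and ``run.log`` (version, seeds, config hash, tallies).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig, save_config
from .core import BoundPolicy, choose_lookahead, extrande_simulate
from .exceptions import ConfigError, ExtrandeError
from .inputs import (
    InputTrajectory,
    OUSpec,
    circadian_rate,
    constant_input,
    lognormal_normalized_rate,
    modulated_circadian_rate,
    simulate_ou,
    sum_of_ou,
)
from .models import TwoStageParams, build_two_stage_model
from .network import ReactionNetwork
from .reference import IntegralMethodConfig, mn_integral_simulate, sia_simulate

logger = logging.getLogger("extrande")


def build_network(model: dict) -> ReactionNetwork:
    model = dict(model)
    if "path" in model:
        import yaml

        raw = yaml.safe_load(Path(model["path"]).read_text())
        return ReactionNetwork.from_dict(raw)
    mtype = model.pop("type", None)
    if mtype == "two-stage":
        try:
            params = TwoStageParams(**model)
        except TypeError as exc:
            raise ConfigError(f"two-stage model: {exc}") from exc
        return build_two_stage_model(params)
    if mtype in (None, "mass-action"):
        if "species" not in model or "reactions" not in model:
            raise ConfigError(
                "mass-action model block needs 'species' and 'reactions'"
            )
        return ReactionNetwork.from_dict(model)
    raise ConfigError(f"unknown model type {mtype!r}")


def build_input(spec: dict, T: float, interpolation: str = "previous") -> InputTrajectory:
    spec = dict(spec)
    if "csv" in spec:
        traj = InputTrajectory.from_csv(spec["csv"], interpolation=spec.get("interpolation"))
        if traj.T < T:
            raise ConfigError(
                f"input CSV covers [0, {traj.T}] h but the horizon is T={T} h"
            )
        return traj
    gen = spec.pop("generator", None)
    seed = spec.pop("seed", None)
    dt = spec.pop("dt", 1e-3)
    spec.pop("T", None)
    try:
        if gen == "constant":
            return constant_input(spec["value"], T, dt=None)
        if gen == "circadian":
            return circadian_rate(spec["kdp"], f=spec.get("f", 1 / 24), dt=dt, T=T)
        if gen == "ou":
            return simulate_ou(
                OUSpec(
                    mean=spec.get("mean", 0.0),
                    gamma=spec["gamma"],
                    variance=spec.get("variance"),
                    cv=spec.get("cv"),
                ),
                dt,
                T,
                seed=seed,
                scheme=spec.get("scheme", "euler-maruyama"),
            )
        if gen == "lognormal-ou":
            ou = simulate_ou(
                OUSpec(mean=0.0, gamma=spec["gamma"], variance=spec["variance"]),
                dt,
                T,
                seed=seed,
            )
            return lognormal_normalized_rate(ou, spec["k_bar"])
        if gen == "modulated-circadian":
            ou = simulate_ou(
                OUSpec(mean=0.0, gamma=spec["gamma"], variance=spec["variance"]),
                dt,
                T,
                seed=seed,
            )
            return modulated_circadian_rate(
                ou, amplitude=spec.get("amplitude", 20.0), f=spec.get("f", 1 / 24)
            )
        if gen == "sum-of-ou":
            specs = [OUSpec(**c) for c in spec["components"]]
            return sum_of_ou(specs, dt, T, seed=seed)
    except KeyError as exc:
        raise ConfigError(f"input generator {gen!r}: missing field {exc}") from exc
    raise ConfigError(f"unknown input generator {gen!r}")


def run_and_report(cfg: RunConfig) -> dict:
    """Execute a configured run; returns a dict of artifact paths."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("extrande %s | config hash %s", __version__, cfg.config_hash())
        logger.info("master seed %s", cfg.seed)
        net = build_network(cfg.model)
        input_spec = dict(cfg.input)
        input_spec.setdefault("seed", cfg.seed)
        traj_in = build_input(input_spec, cfg.T, cfg.interpolation)
        x0 = (
            np.zeros(net.n_species, dtype=np.int64)
            if cfg.x0 is None
            else np.asarray(cfg.x0, dtype=np.int64)
        )
        sample_grid = (
            np.arange(0.0, cfg.T + 1e-12, cfg.output_dt) if cfg.output_dt else None
        )
        rng = np.random.default_rng(cfg.seed)
        if cfg.method == "extrande":
            L = cfg.L
            if L == "auto":
                L = choose_lookahead(net, x0, traj_in, cfg.T, seed=cfg.seed)
                logger.info("auto look-ahead pilot chose L = %.4g h", L)
                cfg.L = L  # echo the resolved value for reproducibility
            policy = BoundPolicy(
                strategy=cfg.bound_strategy if net.input_monotone or cfg.bound_strategy == "window-max" else "window-max",
                L=L,
                safety_factor=cfg.safety_factor,
            )
            traj, stats = extrande_simulate(
                net, x0, traj_in, cfg.T, policy, rng=rng,
                record_events=cfg.record_events, sample_grid=sample_grid,
            )
        elif cfg.method == "sia":
            traj, stats = sia_simulate(
                net, x0, traj_in, cfg.T, rng=rng,
                record_events=cfg.record_events, sample_grid=sample_grid,
            )
        else:
            mn_cfg = IntegralMethodConfig(
                integration_step=cfg.integration_step,
                variant="direct" if cfg.method == "direct-integral" else "modified-next",
            )
            traj, stats = mn_integral_simulate(
                net, x0, traj_in, cfg.T, mn_cfg, rng=rng,
                record_events=cfg.record_events, sample_grid=sample_grid,
            )
        paths = {
            "trajectory": outdir / "trajectory.csv",
            "stats": outdir / "stats.json",
            "config": outdir / "resolved_config.yaml",
            "log": log_path,
        }
        traj.to_csv(paths["trajectory"])
        summary = {
            "method": cfg.method,
            "T_h": cfg.T,
            "n_events": int(stats.n_accepted),
            "event_stats": stats.to_dict(),
            "fractions": stats.fractions(),
            "config_hash": cfg.config_hash(),
            "version": __version__,
        }
        paths["stats"].write_text(json.dumps(summary, indent=2))
        save_config(cfg, paths["config"])
        logger.info(
            "done: %d accepted / %d thinned / %d rejected; %d propensity evals",
            stats.n_accepted,
            stats.n_thinned,
            stats.n_rejected,
            stats.n_propensity_evaluations,
        )
        return {k: str(v) for k, v in paths.items()}
    except ExtrandeError as exc:
        logger.error("simulation failed: %s", exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
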