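"""Pre-simulated exogenous input trajectories.

The simulators never integrate the input themselves: an input process is
pre-simulated (or tabulated) on a grid covering [0, T] and wrapped in an
:class:`InputTrajectory` together with a declared interpolation rule.  The
default rule is ``previous`` (left-constant step function), which makes the
window-supremum query *exact* — the trajectory only ever takes grid values —
so the Extrande propensity bound is rigorously valid.  Linear interpolation is
also supported; its supremum is attained at window endpoints or interior grid
points, so the query remains exact.

Generators provided: constant, circadian sinusoid, Ornstein–Uhlenbeck (OU,
Euler–Maruyama or exact discretization), normalized lognormal-of-OU
transcription rate, OU-modulated circadian rate, and sums of independent OU
processes.  All generators are reproducible: identical (spec, dt, T, seed)
give bit-identical trajectories, and the generator name/parameters/seed are
recorded in ``meta``.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .exceptions import InvalidParameterError, TrajectoryRangeError

__all__ = [
    "InputTrajectory",
    "OUSpec",
    "constant_input",
    "simulate_ou",
    "circadian_rate",
    "lognormal_normalized_rate",
    "modulated_circadian_rate",
    "sum_of_ou",
    "sample_autocovariance",
]

_INTERP_ALIASES = {
    "previous": "previous",
    "left-constant": "previous",
    "step": "previous",
    "linear": "linear",
}


@dataclasses.dataclass
class InputTrajectory:
    """A gridded input trajectory I on [0, T].

    Attributes
    ----------
    grid : ndarray
        Strictly increasing times (hours), ``grid[0] == 0``.
    values : ndarray
        One value per grid point; finite.
    interpolation : {"previous", "linear"}
        ``previous`` (default): right-continuous step function holding the
        value of the greatest grid point <= t.
    meta : dict
        Generator provenance (name, parameters, seed, scheme).
    """

    grid: np.ndarray
    values: np.ndarray
    interpolation: str = "previous"
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        try:
            self.interpolation = _INTERP_ALIASES[self.interpolation]
        except KeyError:
            raise InvalidParameterError(
                f"unknown interpolation {self.interpolation!r}; "
                "use 'previous' (left-constant) or 'linear'"
            ) from None
        if self.grid.ndim != 1 or len(self.grid) < 2:
            raise InvalidParameterError("grid needs at least two points")
        if self.grid[0] != 0.0:
            raise InvalidParameterError("grid must start at t = 0")
        if not (np.diff(self.grid) > 0).all():
            raise InvalidParameterError("grid must be strictly increasing")
        if len(self.values) != len(self.grid):
            raise InvalidParameterError("values and grid lengths differ")
        if not np.isfinite(self.values).all():
            raise InvalidParameterError("trajectory values must be finite")

    # ------------------------------------------------------------------ props
    @property
    def T(self) -> float:
        return float(self.grid[-1])

    @property
    def uniform_dt(self) -> float | None:
        """Grid step if the grid is uniform, else None (cached)."""
        if not hasattr(self, "_uniform_dt"):
            d = np.diff(self.grid)
            dt = d[0]
            self._uniform_dt = (
                float(dt) if np.allclose(d, dt, rtol=1e-9, atol=0.0) else None
            )
        return self._uniform_dt

    def _check_range(self, t):
        if np.any(t < 0.0) or np.any(t > self.T):
            raise TrajectoryRangeError(
                f"time {t} outside trajectory domain [0, {self.T}]"
            )

    # ----------------------------------------------------------------- queries
    def value_at(self, t):
        """Trajectory value at time(s) t under the declared interpolation."""
        t = np.asarray(t, dtype=float)
        self._check_range(t)
        if self.interpolation == "previous":
            idx = np.searchsorted(self.grid, t, side="right") - 1
            idx = np.clip(idx, 0, len(self.grid) - 1)
            out = self.values[idx]
        else:
            out = np.interp(t, self.grid, self.values)
        return float(out) if out.ndim == 0 else out

    def window_sup(self, t: float, L: float) -> float:
        """Exact supremum of the trajectory on the window [t, t+L).

        Windows extending beyond T are clipped at T.  Under ``previous``
        interpolation the supremum is the max over the grid values whose step
        intersects the window (including the value carried in from the left);
        under ``linear`` it is attained at the (interpolated) endpoints or at
        interior grid points.
        """
        if L <= 0:
            raise InvalidParameterError(f"look-ahead L must be > 0, got {L}")
        self._check_range(t)
        end = min(t + L, self.T)
        lo = int(np.searchsorted(self.grid, t, side="right")) - 1
        lo = max(lo, 0)
        if self.interpolation == "previous":
            hi = int(np.searchsorted(self.grid, end, side="left"))
            hi = max(hi, lo + 1)
            return float(self.values[lo:hi].max())
        hi = int(np.searchsorted(self.grid, end, side="right"))
        cand = [self.value_at(t), self.value_at(end)]
        interior = self.values[lo + 1 : hi]
        if len(interior):
            cand.append(float(interior.max()))
        return float(max(cand))

    def global_sup(self) -> float:
        return float(self.values.max())

    # -------------------------------------------------------------- transforms
    def clip_nonnegative(self) -> "InputTrajectory":
        """Clip negative values to zero (for molecular-count inputs).

        A Gaussian OU model of an abundance can dip below zero; propensities
        must stay nonnegative, so count-valued inputs are clipped before being
        handed to a simulator.  The clipped mass fraction is recorded in
        ``meta['clip_fraction']``.
        """
        frac = float(np.mean(self.values < 0))
        meta = dict(self.meta, clip_fraction=frac)
        return InputTrajectory(
            self.grid, np.maximum(self.values, 0.0), self.interpolation, meta
        )

    # --------------------------------------------------------------------- io
    def to_csv(self, path, meta_sidecar: bool = True):
        """Write ``time_h,value`` CSV plus a JSON metadata sidecar."""
        path = Path(path)
        pd.DataFrame({"time_h": self.grid, "value": self.values}).to_csv(
            path, index=False
        )
        if meta_sidecar:
            side = path.with_suffix(path.suffix + ".meta.json")
            side.write_text(
                json.dumps(
                    {"interpolation": self.interpolation, "meta": self.meta}, indent=2
                )
            )

    @classmethod
    def from_csv(cls, path, interpolation: str | None = None) -> "InputTrajectory":
        path = Path(path)
        df = pd.read_csv(path)
        meta: dict = {"source": str(path)}
        interp = interpolation
        side = path.with_suffix(path.suffix + ".meta.json")
        if side.exists():
            d = json.loads(side.read_text())
            meta.update(d.get("meta", {}))
            interp = interp or d.get("interpolation")
        tcol = "time_h" if "time_h" in df.columns else df.columns[0]
        vcol = "value" if "value" in df.columns else df.columns[1]
        return cls(
            df[tcol].to_numpy(),
            df[vcol].to_numpy(),
            interpolation=interp or "previous",
            meta=meta,
        )


# ---------------------------------------------------------------------- specs
@dataclasses.dataclass(frozen=True)
class OUSpec:
    """Ornstein–Uhlenbeck process specification.

    dX = -gamma (X - mean) dt + sqrt(2 gamma variance) dW; stationary law
    N(mean, variance), autocovariance variance * exp(-gamma |dt|), lifetime
    (correlation time) 1/gamma hours.  ``cv`` may be given instead of
    ``variance`` when mean > 0.
    """

    mean: float = 0.0
    gamma: float = 1.0
    variance: float | None = None
    cv: float | None = None
    init: str | float = "stationary"

    def __post_init__(self):
        if self.gamma <= 0:
            raise InvalidParameterError(f"gamma must be > 0, got {self.gamma}")
        if self.variance is None and self.cv is None:
            raise InvalidParameterError("give either variance or cv")
        if self.variance is not None and self.variance < 0:
            raise InvalidParameterError("variance must be >= 0")
        if self.cv is not None and self.variance is None and self.mean <= 0:
            raise InvalidParameterError("cv parameterisation needs mean > 0")

    @property
    def sigma2(self) -> float:
        if self.variance is not None:
            return float(self.variance)
        return float((self.cv * self.mean) ** 2)

    @property
    def lifetime(self) -> float:
        return 1.0 / self.gamma


def _make_grid(dt: float, T: float) -> np.ndarray:
    if dt <= 0 or dt > T:
        raise InvalidParameterError(f"step dt={dt} must satisfy 0 < dt <= T={T}")
    n = int(round(T / dt))
    return np.linspace(0.0, n * dt, n + 1)


# ----------------------------------------------------------------- generators
def constant_input(value: float, T: float, dt: float | None = None) -> InputTrajectory:
    """Constant trajectory (two grid points unless a dt is requested)."""
    grid = _make_grid(dt, T) if dt else np.array([0.0, float(T)])
    return InputTrajectory(
        grid,
        np.full_like(grid, float(value)),
        meta={"generator": "constant", "value": value},
    )


def simulate_ou(
    spec: OUSpec,
    dt: float,
    T: float,
    seed=None,
    scheme: str = "euler-maruyama",
) -> InputTrajectory:
    """Simulate an OU path on a uniform grid.

    ``scheme='euler-maruyama'`` (default) uses the explicit Euler–Maruyama
    update x_{n+1} = x_n - gamma (x_n - mean) dt + sqrt(2 gamma sigma^2 dt) Z;
    ``scheme='exact'`` uses the exact AR(1) discretization (no time-step
    bias), kept for validation.  The initial value is drawn from the
    stationary law unless ``spec.init`` is a number.  Both recursions are run
    through ``scipy.signal.lfilter`` for speed.
    """
    grid = _make_grid(dt, T)
    if dt * spec.gamma > 0.1:
        warnings.warn(
            f"dt*gamma = {dt * spec.gamma:.3g} > 0.1: Euler-Maruyama "
            "discretization error may be noticeable",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    sigma2 = spec.sigma2
    n = len(grid) - 1
    if spec.init == "stationary":
        x0 = spec.mean + np.sqrt(sigma2) * rng.standard_normal()
    else:
        x0 = float(spec.init)
    if scheme == "euler-maruyama":
        rho = 1.0 - spec.gamma * dt
        noise_sd = np.sqrt(2.0 * spec.gamma * sigma2 * dt)
        drift = spec.gamma * spec.mean * dt
    elif scheme == "exact":
        rho = np.exp(-spec.gamma * dt)
        noise_sd = np.sqrt(sigma2 * (1.0 - rho**2))
        drift = spec.mean * (1.0 - rho)
    else:
        raise InvalidParameterError(f"unknown OU scheme {scheme!r}")
    u = drift + noise_sd * rng.standard_normal(n)
    # AR(1): x_k = rho x_{k-1} + u_k, seeded with x0
    x, _ = lfilter([1.0], [1.0, -rho], u, zi=np.array([rho * x0]))
    values = np.concatenate([[x0], x])
    return InputTrajectory(
        grid,
        values,
        meta={
            "generator": "ou",
            "mean": spec.mean,
            "gamma": spec.gamma,
            "variance": sigma2,
            "dt": dt,
            "T": T,
            "seed": _seed_repr(seed),
            "scheme": scheme,
        },
    )


def circadian_rate(kdp: float, f: float = 1.0 / 24.0, dt: float = 1e-3, T: float = 24.0):
    """Deterministic circadian transcription rate k(t) = 4 kdp (1 + sin(2 pi f t)).

    Normalised by the protein degradation rate kdp so that the time-average of
    k(t)/kdp over one period is exactly 4; default period 1/f = 24 h.
    """
    if f <= 0:
        raise InvalidParameterError(f"frequency f must be > 0, got {f}")
    grid = _make_grid(dt, T)
    values = 4.0 * kdp * (1.0 + np.sin(2.0 * np.pi * f * grid))
    return InputTrajectory(
        grid,
        values,
        meta={"generator": "circadian", "kdp": kdp, "f": f, "dt": dt, "T": T},
    )


def lognormal_normalized_rate(
    ou: InputTrajectory, k_bar: float, sigma2: float | None = None
) -> InputTrajectory:
    """Normalized lognormal transcription rate k(t) = k_bar <exp xi>^-1 exp(xi(t)).

    ``ou`` must be a zero-mean Gaussian OU path xi with stationary variance
    sigma^2; the lognormal mean identity <exp xi> = exp(sigma^2/2) makes the
    stationary mean of k exactly ``k_bar``.  sigma^2 is read from the OU
    metadata, or must be supplied explicitly.
    """
    if sigma2 is None:
        sigma2 = ou.meta.get("variance")
        if sigma2 is None:
            raise InvalidParameterError(
                "stationary variance of the OU noise unknown; pass sigma2="
            )
    values = k_bar * np.exp(-0.5 * sigma2) * np.exp(ou.values)
    meta = {
        "generator": "lognormal-ou",
        "k_bar": k_bar,
        "variance": float(sigma2),
        "base": ou.meta,
    }
    return InputTrajectory(ou.grid, values, ou.interpolation, meta)


def modulated_circadian_rate(
    ou: InputTrajectory, amplitude: float = 20.0, f: float = 1.0 / 24.0
) -> InputTrajectory:
    """Circadian rate with lognormal amplitude noise:
    k(t) = amplitude * exp(xi(t)) * (1 + sin(2 pi f t)).

    ``ou`` carries the zero-mean Gaussian noise xi; its stationary variance is
    whatever the supplied OU spec says (it is deliberately an explicit
    parameter of the noise process, not hard-coded here).
    """
    values = amplitude * np.exp(ou.values) * (1.0 + np.sin(2.0 * np.pi * f * ou.grid))
    meta = {
        "generator": "modulated-circadian",
        "amplitude": amplitude,
        "f": f,
        "base": ou.meta,
    }
    return InputTrajectory(ou.grid, values, ou.interpolation, meta)


def sum_of_ou(
    specs: Sequence[OUSpec], dt: float, T: float, seed=None, scheme="euler-maruyama"
) -> InputTrajectory:
    """Pointwise sum of independent OU paths (two-exponential autocovariance).

    Useful for matching autocorrelation functions that a single exponential
    cannot fit; a single OU suffices for the main experiments.
    """
    if not specs:
        raise InvalidParameterError("need at least one OUSpec")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(specs))
    paths = [simulate_ou(sp, dt, T, seed=c, scheme=scheme) for sp, c in zip(specs, children)]
    values = np.sum([p.values for p in paths], axis=0)
    meta = {
        "generator": "sum-of-ou",
        "components": [p.meta for p in paths],
        "seed": _seed_repr(seed),
    }
    return InputTrajectory(paths[0].grid, values, meta=meta)


# -------------------------------------------------------------------- summary
def sample_autocovariance(traj_or_values, lags) -> np.ndarray:
    """Biased-normalization sample autocovariance at integer grid lags.

    ``acv[k] = (1/n) sum_i (x_i - xbar)(x_{i+k} - xbar)``; lag 0 equals the
    (biased) sample variance.
    """
    x = traj_or_values.values if isinstance(traj_or_values, InputTrajectory) else np.asarray(traj_or_values, float)
    lags = np.atleast_1d(np.asarray(lags, dtype=int))
    if (lags < 0).any() or (lags >= len(x)).any():
        raise InvalidParameterError("lags must be in [0, n)")
    xc = x - x.mean()
    n = len(x)
    return np.array([np.dot(xc[: n - k], xc[k:]) / n for k in lags])


def _seed_repr(seed):
    if seed is None:
        return None
    if isinstance(seed, np.random.SeedSequence):
        return list(map(int, seed.entropy if isinstance(seed.entropy, (list, tuple)) else [seed.entropy])) + list(seed.spawn_key)
    return int(seed)
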