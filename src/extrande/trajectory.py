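"""Simulated trajectories and event statistics.

A :class:`Trajectory` is a right-continuous piecewise-constant state path with
labelled events.  Channel events (label >= 0) change the state by the
channel's stoichiometry; ``thin`` (label -1) and ``reject-horizon`` (label -2)
events leave the state unchanged.  For long ensemble runs, the simulators can
instead (or additionally) record the state on a fixed sample grid, which keeps
memory bounded.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

THIN = -1
REJECT = -2

_LABEL_NAMES = {THIN: "thin", REJECT: "reject-horizon"}


@dataclasses.dataclass
class EventStats:
    """Tallies of the thinning algorithm's bookkeeping.

    ``n_exponentials_drawn == n_accepted + n_thinned + n_rejected`` always;
    ``n_propensity_evaluations`` counts individual per-channel evaluations
    (the hardware-independent surrogate for propensity-evaluation CPU time).
    """

    n_accepted: int = 0
    n_thinned: int = 0
    n_rejected: int = 0
    n_propensity_evaluations: int = 0
    n_exponentials_drawn: int = 0

    def fractions(self) -> dict:
        n = max(self.n_exponentials_drawn, 1)
        return {
            "accepted": self.n_accepted / n,
            "thinned": self.n_thinned / n,
            "rejected": self.n_rejected / n,
        }

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclasses.dataclass
class Trajectory:
    """Event record and/or gridded sample of one simulated cell.

    ``times``/``labels``/``states`` hold the full event list when recorded
    (states are the post-event states); ``sample_times``/``sample_states``
    hold the path sampled on a fixed grid.  At least one representation is
    always present.
    """

    x0: np.ndarray
    t0: float
    T: float
    species_names: list
    times: np.ndarray | None = None
    labels: np.ndarray | None = None
    states: np.ndarray | None = None
    sample_times: np.ndarray | None = None
    sample_states: np.ndarray | None = None
    meta: dict = dataclasses.field(default_factory=dict)

    # cached channel-only view
    _ct: np.ndarray | None = dataclasses.field(default=None, repr=False)
    _cs: np.ndarray | None = dataclasses.field(default=None, repr=False)

    @property
    def has_events(self) -> bool:
        return self.times is not None

    @property
    def n_events(self) -> int:
        return 0 if self.times is None else len(self.times)

    def _channel_view(self):
        """Times and post-event states of state-changing events only."""
        if self._ct is None:
            if self.times is None:
                raise ValueError("trajectory was recorded on a grid only")
            mask = self.labels >= 0
            self._ct = self.times[mask]
            self._cs = self.states[mask]
        return self._ct, self._cs

    def state_at(self, t):
        """Right-continuous state at time(s) t."""
        t = np.asarray(t, dtype=float)
        if self.has_events:
            ct, cs = self._channel_view()
            idx = np.searchsorted(ct, t, side="right") - 1
        else:
            ct, cs = self.sample_times, self.sample_states
            idx = np.searchsorted(ct, t, side="right") - 1
        out = np.where(
            idx[..., None] < 0, self.x0, cs[np.clip(idx, 0, max(len(ct) - 1, 0))]
        )
        return out

    def sample(self, grid):
        """State sampled on ``grid`` (piecewise-constant, right-continuous)."""
        return self.state_at(np.asarray(grid, dtype=float))

    def replay_check(self, network) -> bool:
        """Verify every state transition equals the stoichiometry of its label."""
        if not self.has_events:
            raise ValueError("replay needs the event record")
        x = np.asarray(self.x0)
        for lbl, st in zip(self.labels, self.states):
            if lbl >= 0:
                x = x + network.S[lbl]
            if not np.array_equal(x, st):
                return False
        return True

    def to_frame(self) -> pd.DataFrame:
        """Event table with readable labels (falls back to the grid sample)."""
        if self.has_events:
            chan = self.meta.get("channel_names")
            lbl = [
                _LABEL_NAMES.get(int(l), chan[int(l)] if chan else f"R{int(l)}")
                for l in self.labels
            ]
            df = pd.DataFrame({"time_h": self.times, "event": lbl})
            for i, s in enumerate(self.species_names):
                df[s] = self.states[:, i]
            return df
        df = pd.DataFrame({"time_h": self.sample_times, "event": "sample"})
        for i, s in enumerate(self.species_names):
            df[s] = self.sample_states[:, i]
        return df

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)


class Recorder:
    """Streaming event/grid recorder used inside the simulator loops."""

    def __init__(
        self,
        x0,
        T,
        species_names,
        sample_grid=None,
        keep_events=True,
        channel_names=None,
    ):
        self.x0 = np.asarray(x0, dtype=np.int64).copy()
        self.T = float(T)
        self.species_names = list(species_names)
        self.keep_events = keep_events
        self._times: list = []
        self._labels: list = []
        self._states: list = []
        self._grid = None
        if sample_grid is not None:
            self._grid = np.asarray(sample_grid, dtype=float)
            self._gs = np.empty((len(self._grid), len(self.x0)), dtype=np.int64)
            self._gi = 0
        self._channel_names = channel_names
        self._x_cur = self.x0

    def state_change(self, t, j, x):
        if self._grid is not None:
            g, gi = self._grid, self._gi
            if gi < len(g) and g[gi] < t:
                x_prev = self._x_cur
                while gi < len(g) and g[gi] < t:
                    self._gs[gi] = x_prev
                    gi += 1
                self._gi = gi
        self._x_cur = np.array(x, dtype=np.int64)
        if self.keep_events:
            self._times.append(t)
            self._labels.append(j)
            self._states.append(self._x_cur.copy())

    def pseudo_event(self, t, label):
        if self.keep_events:
            self._times.append(t)
            self._labels.append(label)
            self._states.append(np.array(self._x_cur, dtype=np.int64))

    def finalize(self, meta=None) -> Trajectory:
        x_cur = self._x_cur
        kw = {}
        if self._grid is not None:
            g, gi = self._grid, self._gi
            while gi < len(g):
                self._gs[gi] = x_cur
                gi += 1
            kw.update(sample_times=self._grid, sample_states=self._gs)
        if self.keep_events:
            n = len(self._times)
            kw.update(
                times=np.array(self._times, dtype=float),
                labels=np.array(self._labels, dtype=np.int64)
                if n
                else np.empty(0, dtype=np.int64),
                states=np.array(self._states, dtype=np.int64).reshape(n, len(self.x0)),
            )
        return Trajectory(
            x0=self.x0,
            t0=0.0,
            T=self.T,
            species_names=self.species_names,
            meta=meta or {},
            **kw,
        )
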