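"""Reaction networks with input-dependent propensities.

A :class:`ReactionNetwork` holds the species list, the stoichiometric matrix
``S`` (one row per reaction channel) and one propensity function per channel.
Propensity functions have the uniform signature ``a(x, input_value, t)`` even
when they do not depend on the input or on time, so that deterministic rates
(e.g. a circadian sinusoid) can be routed either through the input trajectory
or through explicit time dependence; the shipped model builders use the input
route so that all simulators consume identical pre-simulated trajectories.

Mass-action reactions additionally carry a declarative description
(rate constant, reactant/product multisets, optional input modulation) which
enables the YAML round trip and the vectorised finite-state master-equation
oracle.  Time is measured in hours throughout; all rates are per hour.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Mapping, Sequence

import numpy as np

from .exceptions import ConsistencyError, InvalidParameterError, PropensityError

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "SystemState",
    "total_propensity",
    "apply_reaction",
]

#: signature: propensity(x, input_value, t) -> float
PropensityFn = Callable[[np.ndarray, float, float], float]


def _falling_factorial(x: int, k: int) -> int:
    out = 1
    for i in range(k):
        out *= x - i
    return out


@dataclasses.dataclass(frozen=True)
class Reaction:
    """A single reaction channel.

    Parameters
    ----------
    name : str
        Channel label used in error messages and CSV output.
    stoich : ndarray of int
        Net change of each species when the channel fires (one entry per
        species).
    propensity : callable ``(x, input_value, t) -> float``
        Must be finite and >= 0 on every admissible state, and must vanish
        whenever a consumed species has zero copies.
    reactants, products : ndarray of int, optional
        Consumption/production orders per species for mass-action channels
        (``None`` for channels defined only programmatically).
    rate : float, optional
        Mass-action rate constant (per hour).
    input_scaled : bool
        If True the mass-action propensity is multiplied by the current input
        value (e.g. a transcription channel whose rate *is* the input).
    """

    name: str
    stoich: np.ndarray
    propensity: PropensityFn
    reactants: np.ndarray | None = None
    products: np.ndarray | None = None
    rate: float | None = None
    input_scaled: bool = False

    @classmethod
    def mass_action(
        cls,
        name: str,
        rate: float,
        reactants: Mapping[str, int],
        products: Mapping[str, int],
        species: Sequence[str],
        input_scaled: bool = False,
    ) -> "Reaction":
        """Build a mass-action channel from reactant/product multisets.

        The propensity is ``rate * prod_i x_i (x_i-1) ... (x_i-r_i+1)``
        (falling factorials, no combinatorial 1/r! prefactor), optionally
        multiplied by the input value.  It is automatically zero whenever a
        consumed species is exhausted, so mass-action networks can never
        produce negative populations.
        """
        if not math.isfinite(rate) or rate < 0:
            raise InvalidParameterError(
                f"reaction {name!r}: rate must be finite and >= 0, got {rate}"
            )
        idx = {s: i for i, s in enumerate(species)}
        n = len(species)
        r = np.zeros(n, dtype=np.int64)
        p = np.zeros(n, dtype=np.int64)
        for s, k in reactants.items():
            r[idx[s]] = k
        for s, k in products.items():
            p[idx[s]] = k
        terms = [(int(i), int(k)) for i, k in enumerate(r) if k > 0]

        if input_scaled:

            def propensity(x, I, t, _rate=rate, _terms=terms):
                a = _rate * I
                for i, k in _terms:
                    a *= _falling_factorial(x[i], k)
                return a

        else:

            def propensity(x, I, t, _rate=rate, _terms=terms):
                a = _rate
                for i, k in _terms:
                    a *= _falling_factorial(x[i], k)
                return a

        return cls(
            name=name,
            stoich=p - r,
            propensity=propensity,
            reactants=r,
            products=p,
            rate=float(rate),
            input_scaled=input_scaled,
        )


@dataclasses.dataclass
class SystemState:
    """Molecule counts plus the current time (hours)."""

    x: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.int64)
        if (self.x < 0).any():
            raise InvalidParameterError(f"negative copy numbers in state {self.x}")
        if self.t < 0:
            raise InvalidParameterError(f"negative time {self.t}")


class ReactionNetwork:
    """Species, stoichiometries and propensities of a reaction system.

    Parameters
    ----------
    species_names : sequence of str
    reactions : sequence of Reaction
    input_monotone : bool
        Declare that *every* propensity is a nondecreasing function of the
        (scalar) input.  Required by the ``monotone-sup`` and ``global``
        bound strategies of the Extrande simulator.
    """

    def __init__(
        self,
        species_names: Sequence[str],
        reactions: Sequence[Reaction],
        input_monotone: bool = False,
    ):
        self.species_names = list(species_names)
        self.reactions = list(reactions)
        self.input_monotone = bool(input_monotone)
        n = len(self.species_names)
        for rxn in self.reactions:
            if len(rxn.stoich) != n:
                raise InvalidParameterError(
                    f"reaction {rxn.name!r}: stoichiometry has {len(rxn.stoich)} "
                    f"entries for {n} species"
                )
        self.S = np.array([r.stoich for r in self.reactions], dtype=np.int64)
        self._prop_fns = [r.propensity for r in self.reactions]

    # ------------------------------------------------------------------ basic
    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def is_mass_action(self) -> bool:
        return all(r.reactants is not None for r in self.reactions)

    def mass_action_arrays(self):
        """(rates, reactant-order matrix, input-scaled flags) or None.

        Dense array form of a mass-action network, consumed by the compiled
        simulation kernels.
        """
        if not self.is_mass_action:
            return None
        rates = np.array([r.rate for r in self.reactions], dtype=float)
        orders = np.array([r.reactants for r in self.reactions], dtype=np.int64)
        iscaled = np.array([r.input_scaled for r in self.reactions], dtype=np.bool_)
        return rates, orders, iscaled

    def __repr__(self):
        return (
            f"ReactionNetwork({self.n_species} species, "
            f"{self.n_reactions} reactions)"
        )

    # ------------------------------------------------------------- propensity
    def propensities_into(self, x, input_value, t, out) -> float:
        """Fill ``out`` with the per-channel propensities; return their sum.

        Hot-path variant used by the simulators: no validation beyond what the
        callers do themselves.
        """
        total = 0.0
        for j, f in enumerate(self._prop_fns):
            aj = f(x, input_value, t)
            out[j] = aj
            total += aj
        return total

    def propensities(self, x, input_value, t=0.0) -> np.ndarray:
        """Validated per-channel propensity vector."""
        x = np.asarray(x)
        out = np.empty(self.n_reactions)
        for j, f in enumerate(self._prop_fns):
            aj = f(x, input_value, t)
            if not math.isfinite(aj) or aj < 0:
                raise PropensityError(
                    f"channel {j} ({self.reactions[j].name!r}) returned "
                    f"propensity {aj} at state {x}, input {input_value}",
                    channel=self.reactions[j].name,
                )
            out[j] = aj
        return out

    # ------------------------------------------------------------ yaml round trip
    def to_dict(self) -> dict:
        """Declarative description of a mass-action network."""
        if not self.is_mass_action:
            raise InvalidParameterError(
                "only mass-action networks have a declarative form; "
                "arbitrary propensities are programmatic-only"
            )
        rxns = []
        for r in self.reactions:
            rxns.append(
                {
                    "name": r.name,
                    "rate": float(r.rate),
                    "reactants": {
                        s: int(k)
                        for s, k in zip(self.species_names, r.reactants)
                        if k > 0
                    },
                    "products": {
                        s: int(k)
                        for s, k in zip(self.species_names, r.products)
                        if k > 0
                    },
                    "input_modulated": bool(r.input_scaled),
                }
            )
        return {
            "species": list(self.species_names),
            "reactions": rxns,
            "input_monotone": self.input_monotone,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ReactionNetwork":
        species = list(d["species"])
        reactions = [
            Reaction.mass_action(
                name=r.get("name", f"R{i + 1}"),
                rate=r["rate"],
                reactants=r.get("reactants", {}),
                products=r.get("products", {}),
                species=species,
                input_scaled=r.get("input_modulated", False),
            )
            for i, r in enumerate(d["reactions"])
        ]
        return cls(species, reactions, input_monotone=d.get("input_monotone", False))


# ------------------------------------------------------------------ operations
def total_propensity(
    net: ReactionNetwork, state: SystemState | np.ndarray, input_value: float, t=None
):
    """Total propensity ``a0`` and the per-channel vector.

    ``a0 = sum_j a_j[X, I]``; the vector is what channel selection uses.
    Raises :class:`PropensityError` (naming the channel) if any propensity is
    negative or non-finite.
    """
    if isinstance(state, SystemState):
        x, tt = state.x, state.t
    else:
        x, tt = np.asarray(state), 0.0
    if t is not None:
        tt = t
    a = net.propensities(x, input_value, tt)
    return float(a.sum()), a


def apply_reaction(
    state: SystemState, net: ReactionNetwork, j: int
) -> SystemState:
    """Fire channel ``j`` (0-based): ``X <- X + nu_j``; time unchanged."""
    if not 0 <= j < net.n_reactions:
        raise InvalidParameterError(
            f"channel index {j} out of range 0..{net.n_reactions - 1}"
        )
    x_new = state.x + net.S[j]
    if (x_new < 0).any():
        raise ConsistencyError(
            f"firing channel {j} ({net.reactions[j].name!r}) from state "
            f"{state.x} would produce negative copy numbers — the channel's "
            "propensity should have been zero in this state"
        )
    return SystemState(x=x_new, t=state.t)
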