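"""Shipped model fixtures.

The workhorse benchmark is the two-stage gene-expression model

    0 --k(t)--> M,   M --ks--> M + P,   M --kdm--> 0,   P --kdp--> 0,

with a time-varying transcription propensity k(t) supplied as the exogenous
input: mRNA (M) is transcribed at rate k(t), translated into protein (P) at
rate ks per mRNA, and both degrade first-order.  All propensities are
nondecreasing in the input, so the network declares itself input-monotone and
the tight supremum bound strategy applies.

Also provided: birth–death and pure-birth networks (used as analytically
solvable oracles) and a small bistable-expression toy for exercising the
cell-fate pipeline end to end.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .exceptions import InvalidParameterError
from .network import Reaction, ReactionNetwork

__all__ = [
    "TwoStageParams",
    "build_two_stage_model",
    "build_birth_death",
    "build_pure_birth",
    "build_competence_toy",
]


@dataclasses.dataclass(frozen=True)
class TwoStageParams:
    """Rates of the two-stage gene-expression model (all per hour).

    ks : translation rate per mRNA; kdm / kdp : mRNA / protein degradation
    rates.  The transcription rate k(t) is carried by the input trajectory,
    so it is not a field here.
    """

    ks: float
    kdm: float
    kdp: float

    def __post_init__(self):
        for name in ("ks", "kdm", "kdp"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise InvalidParameterError(f"{name} must be > 0, got {v}")


def build_two_stage_model(params: TwoStageParams) -> ReactionNetwork:
    """Two-stage gene expression with input-carried transcription rate.

    Species ``("mRNA", "protein")``; channels (in order): transcription with
    propensity I(t), translation ks*M, mRNA decay kdm*M, protein decay kdp*P.
    """
    species = ["mRNA", "protein"]
    rxns = [
        Reaction.mass_action(
            "transcription", 1.0, {}, {"mRNA": 1}, species, input_scaled=True
        ),
        Reaction.mass_action(
            "translation", params.ks, {"mRNA": 1}, {"mRNA": 1, "protein": 1}, species
        ),
        Reaction.mass_action("mrna_decay", params.kdm, {"mRNA": 1}, {}, species),
        Reaction.mass_action("protein_decay", params.kdp, {"protein": 1}, {}, species),
    ]
    return ReactionNetwork(species, rxns, input_monotone=True)


def build_birth_death(
    birth_rate: float | None = None, death_rate: float = 1.0, input_birth: bool = False
) -> ReactionNetwork:
    """Birth–death process 0 -> X -> 0.

    With constant birth rate k and death rate kd the stationary law is
    Poisson(k/kd).  With ``input_birth=True`` the birth propensity is the
    input value I(t) (a doubly stochastic / nonhomogeneous birth process).
    """
    species = ["X"]
    if input_birth:
        birth = Reaction.mass_action(
            "birth", 1.0, {}, {"X": 1}, species, input_scaled=True
        )
    else:
        if birth_rate is None:
            raise InvalidParameterError("birth_rate required when input_birth=False")
        birth = Reaction.mass_action("birth", birth_rate, {}, {"X": 1}, species)
    death = Reaction.mass_action("death", death_rate, {"X": 1}, {}, species)
    return ReactionNetwork(species, [birth, death], input_monotone=True)


def build_pure_birth(birth_rate: float | None = None, input_birth: bool = True):
    """Pure-birth (counting) process; with input-carried rate the event count
    over [0, T] is Poisson with mean the integral of the input."""
    species = ["N"]
    if input_birth:
        birth = Reaction.mass_action(
            "birth", 1.0, {}, {"N": 1}, species, input_scaled=True
        )
    else:
        if birth_rate is None:
            raise InvalidParameterError("birth_rate required when input_birth=False")
        birth = Reaction.mass_action("birth", birth_rate, {}, {"N": 1}, species)
    return ReactionNetwork(species, [birth], input_monotone=True)


def build_competence_toy(
    k_on: float = 0.05,
    k_off: float = 2.0,
    k_prod: float = 200.0,
    k_deg: float = 2.0,
) -> ReactionNetwork:
    """Minimal bistable-expression toy for the cell-fate pipeline.

    A two-state promoter whose activation propensity is proportional to the
    (abundance-scaled) input — a stand-in for an activated quorum-sensing
    transcription factor — drives bursty expression of a master regulator
    ("ComK"-like):

        G_off --k_on*I--> G_on,  G_on --k_off--> G_off,
        G_on --k_prod--> G_on + K,  K --k_deg--> 0.

    ``k_on`` is per hour per input molecule-unit; with an input of order 1000
    molecules, activation is rare but sensitive to input fluctuations, giving
    a heterogeneous, input-dependent differentiation race.  This toy is a
    synthetic illustration: it is *not* the full wild-type competence network
    (whose reaction table must be supplied by the user via the network
    config).
    """
    species = ["G_off", "G_on", "ComK"]
    scale = 1e-3  # express k_on per 1000 input molecules
    rxns = [
        Reaction.mass_action(
            "activation",
            k_on * scale,
            {"G_off": 1},
            {"G_on": 1},
            species,
            input_scaled=True,
        ),
        Reaction.mass_action("deactivation", k_off, {"G_on": 1}, {"G_off": 1}, species),
        Reaction.mass_action(
            "expression", k_prod, {"G_on": 1}, {"G_on": 1, "ComK": 1}, species
        ),
        Reaction.mass_action("decay", k_deg, {"ComK": 1}, {}, species),
    ]
    return ReactionNetwork(species, rxns, input_monotone=True)
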