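"""Random-utility choice model for smoking alternatives.

Each decision cycle an agent compares four alternatives — remain a
non-user, smoke conventional cigarettes (CC) only, use e-cigarettes (EC)
only, or use both ("dual") — and keeps the one with the highest utility.
Utility combines an intrinsic taste for each product, habituation to the
currently used product, use-frequency reinforcement, and social influence
proportional to the product's prevalence among the agent's close friends
and in the whole population. Social influence is amplified by the agent's
dynamic "openness" to smoking, itself raised by perceived prevalence; a
one-way "crossover" coupling lets e-cigarette prevalence additionally
raise the attractiveness of conventional smoking.

Unobserved taste heterogeneity is modelled with i.i.d. Gumbel shocks per
alternative per decision, so choice probabilities follow the multinomial
logit ``softmax(U / tasteScale)`` — the closed form used as a test oracle.
With ``tasteScale = 0`` the choice is a deterministic argmax.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict, replace
from typing import Mapping

import numpy as np

from .population import AgentProfile, SmokingState, USES_CC, USES_EC

__all__ = [
    "UtilityParameters",
    "SocialSignals",
    "peer_prevalence",
    "population_prevalence",
    "dynamic_openness",
    "alternative_utilities",
    "choose_state",
]

SCENARIO_RANGE = (0.0, 0.3)


@dataclass
class UtilityParameters:
    """Weights of the smoking-choice utility model.

    Utility units are on the scale of the Gumbel shock (``tasteScale = 1``
    means one utility unit ≈ one shock standard scale). Defaults are the
    packaged calibration against the 2011–2014 NYTS prevalence trajectory.

    Parameters
    ----------
    muCC, muEC
        Intrinsic taste for each product (typically negative: most
        teenagers do not initiate absent social influence).
    eta
        Habituation bonus for a product currently used.
    phi
        Additional utility per unit 30-day use-frequency of the product.
    wPeer, wSoc
        Social-influence weight per unit prevalence among close friends /
        in the whole population.
    alphaPeerMix
        Peer share of perceived exposure when updating openness, in [0, 1].
    gammaOpen
        Openness response to perceived exposure (dimensionless).
    thetaCC, thetaEC
        Exogenous scenario offsets added to openness, on the [0, 1]
        openness scale; study scenarios use 0–0.3.
    crossover
        One-way EC→CC coupling strength χ: e-cigarette exposure raises
        openness to conventional smoking and adds EC social utility to the
        CC alternative. 0 means the two products influence independently.
    kappaDual
        Interaction in the utility of running both products at once:
        positive is a cost of dual use, negative a complementarity (for a
        current user of one product, dependence raises the marginal
        attraction of the other).
    tasteScale
        Scale of the per-alternative Gumbel shock; 0 gives deterministic
        argmax choice.
    crossoverOpennessChannel, crossoverUtilityChannel
        Enable/disable the two channels through which χ acts.
    """

    muCC: float = -10.731
    muEC: float = -7.422
    eta: float = 11.732
    phi: float = 1.017
    wPeer: float = 3.974
    wSoc: float = 3.48
    alphaPeerMix: float = 0.407
    gammaOpen: float = 2.996
    thetaCC: float = 0.0
    thetaEC: float = 0.0
    crossover: float = 0.0
    kappaDual: float = -1.75
    tasteScale: float = 1.0
    crossoverOpennessChannel: bool = True
    crossoverUtilityChannel: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.alphaPeerMix <= 1.0:
            raise ValueError(f"alphaPeerMix {self.alphaPeerMix} outside [0, 1]")
        if self.tasteScale < 0:
            raise ValueError("tasteScale must be >= 0")
        lo, hi = SCENARIO_RANGE
        for name in ("thetaCC", "thetaEC", "crossover"):
            v = getattr(self, name)
            if not lo <= v <= hi:
                warnings.warn(
                    f"{name}={v} outside the study scenario range [{lo}, {hi}]",
                    stacklevel=2,
                )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "UtilityParameters":
        return cls(**dict(d))

    def with_scenario(
        self, thetaCC: float, thetaEC: float, crossover: float
    ) -> "UtilityParameters":
        """Copy with scenario knobs replaced (other weights untouched)."""
        return replace(self, thetaCC=thetaCC, thetaEC=thetaEC, crossover=crossover)


@dataclass(frozen=True)
class SocialSignals:
    """Prevalence signals an agent perceives: close friends and society."""

    peerCC: float
    peerEC: float
    popCC: float
    popEC: float

    def __post_init__(self) -> None:
        for name in ("peerCC", "peerEC", "popCC", "popEC"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} {v} outside [0, 1]")


def peer_prevalence(
    agent_id: int,
    network,
    states: Mapping[int, SmokingState],
) -> tuple[float, float]:
    """Fraction of the agent's close friends currently using CC / EC.

    Both fractions are 0 for an agent with no close friends.
    """
    if agent_id not in network.closeFriends and agent_id not in set(network.nodes):
        raise KeyError(f"unknown agentId {agent_id}")
    friends = network.closeFriends.get(agent_id, [])
    if not friends:
        return 0.0, 0.0
    cc = sum(1 for f in friends if USES_CC[states[f]])
    ec = sum(1 for f in friends if USES_EC[states[f]])
    return cc / len(friends), ec / len(friends)


def population_prevalence(
    states: Mapping[int, SmokingState] | np.ndarray,
) -> tuple[float, float, np.ndarray]:
    """Whole-population CC and EC prevalence plus the 4-state fractions.

    Dual users count toward both product prevalences.
    """
    if isinstance(states, Mapping):
        arr = np.fromiter((int(s) for s in states.values()), dtype=np.int64)
    else:
        arr = np.asarray(states, dtype=np.int64)
    if arr.size == 0:
        raise ValueError("empty state map")
    fractions = np.bincount(arr, minlength=4) / arr.size
    pop_cc = float(USES_CC[arr].mean())
    pop_ec = float(USES_EC[arr].mean())
    return pop_cc, pop_ec, fractions


def _clamp01(x: float) -> float:
    return min(1.0, max(0.0, x))


def dynamic_openness(
    agent: AgentProfile, signals: SocialSignals, params: UtilityParameters
) -> tuple[float, float]:
    """Current openness toward CC and EC, in [0, 1].

    Perceived exposure blends peer and societal prevalence,
    ``E_X = α·peer_X + (1−α)·pop_X``; openness is the base survey-derived
    level plus the scenario offset plus ``γ·E_X``, clamped to [0, 1]. The
    crossover acts one way: EC exposure also raises CC openness by ``χ·E_EC``.
    """
    a = params.alphaPeerMix
    e_cc = a * signals.peerCC + (1 - a) * signals.popCC
    e_ec = a * signals.peerEC + (1 - a) * signals.popEC
    chi = params.crossover if params.crossoverOpennessChannel else 0.0
    o_cc = _clamp01(
        agent.baseOpennessCC + params.thetaCC + params.gammaOpen * e_cc + chi * e_ec
    )
    o_ec = _clamp01(agent.baseOpennessEC + params.thetaEC + params.gammaOpen * e_ec)
    return o_cc, o_ec


def alternative_utilities(
    agent: AgentProfile,
    signals: SocialSignals,
    params: UtilityParameters,
    openness: tuple[float, float] | None = None,
) -> np.ndarray:
    """Utility of the four alternatives, ordered as :class:`SmokingState`.

    ``U(NONE) = 0`` is the identifying normalisation. Each product's value
    sums intrinsic taste, habituation if currently used, frequency
    reinforcement, and openness-amplified social influence; the CC side
    additionally receives the crossover share of EC social influence.
    ``U(DUAL)`` is the sum of both product values minus the dual-use cost.
    """
    if openness is None:
        openness = dynamic_openness(agent, signals, params)
    o_cc, o_ec = openness
    social_cc = params.wPeer * signals.peerCC + params.wSoc * signals.popCC
    social_ec = params.wPeer * signals.peerEC + params.wSoc * signals.popEC
    v_cc = (
        params.muCC
        + params.eta * USES_CC[agent.state]
        + params.phi * agent.freqCC
        + social_cc * (1.0 + o_cc)
    )
    if params.crossoverUtilityChannel:
        v_cc += params.crossover * social_ec
    v_ec = (
        params.muEC
        + params.eta * USES_EC[agent.state]
        + params.phi * agent.freqEC
        + social_ec * (1.0 + o_ec)
    )
    return np.array([0.0, v_cc, v_ec, v_cc + v_ec - params.kappaDual])


def choose_state(
    utilities: np.ndarray, tasteScale: float, rng: np.random.Generator
) -> SmokingState:
    """Pick the highest-utility alternative under Gumbel taste shocks.

    With ``tasteScale > 0`` this realises multinomial-logit choice with
    probabilities ``softmax(U / tasteScale)``; with ``tasteScale = 0`` it is
    a deterministic argmax, ties broken in state order NONE < CC_ONLY <
    EC_ONLY < DUAL.
    """
    u = np.asarray(utilities, dtype=float)
    if u.shape != (4,) or not np.all(np.isfinite(u)):
        raise ValueError("utilities must be 4 finite numbers")
    if tasteScale > 0:
        u = u + tasteScale * rng.gumbel(size=4)
    return SmokingState(int(np.argmax(u)))
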