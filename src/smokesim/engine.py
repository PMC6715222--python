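"""Decision-cycle engine: synchronous updates, replicates, aggregation.

One replicate builds a fresh synthetic population and friendship network
from its own seed, then advances the agents through monthly decision
cycles (12 per calendar year by default, matching the survey's 30-day
"current use" window). Updates are synchronous: every agent evaluates the
same lagged social environment (the previous cycle's states), all choices
are drawn, and the revised states are fed back as the next cycle's
environment. Scenario results are means and SDs over seeded replicates.

The per-agent arithmetic is identical to the scalar functions in
:mod:`smokesim.utility`; the engine runs a vectorised numpy equivalent
(equivalence is exercised in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network import SocialNetwork, assign_close_friends, build_scale_free
from .population import (
    AgentProfile,
    PopulationMarginals,
    SmokingState,
    USES_CC,
    USES_EC,
    generate_population_arrays,
)
from .utility import UtilityParameters

__all__ = [
    "ScenarioSpec",
    "TrajectoryResult",
    "ScenarioResult",
    "step_cycle",
    "run_replicate",
    "run_scenario",
]

FREQ_STEP = 0.25  # habituation gain in use-frequency per cycle of continued use


@dataclass
class ScenarioSpec:
    """Everything needed to run one scenario end to end."""

    marginals: PopulationMarginals
    params: UtilityParameters
    nAgents: int = 3000
    attachmentM: int = 2
    cyclesPerYear: int = 12
    startYear: int = 2011
    endYear: int = 2014
    nReplicates: int = 100
    baseSeed: int = 0

    def __post_init__(self) -> None:
        if self.nReplicates < 1:
            raise ValueError("nReplicates must be >= 1")
        if self.endYear < self.startYear:
            raise ValueError("endYear must be >= startYear")

    @property
    def nCycles(self) -> int:
        return self.cyclesPerYear * (self.endYear - self.startYear)

    @property
    def years(self) -> list[int]:
        return list(range(self.startYear, self.endYear + 1))


@dataclass
class TrajectoryResult:
    """State-fraction trajectory of one replicate.

    ``perCycle`` has one row per cycle including the initial state
    (``nCycles + 1`` rows); ``perYear`` samples the survey anniversaries
    (cycle 0, cyclesPerYear, 2·cyclesPerYear, ...). Columns are the four
    state fractions in :class:`SmokingState` order.
    """

    replicateId: int
    years: list[int]
    perCycle: np.ndarray
    perYear: np.ndarray

    @property
    def popCC(self) -> np.ndarray:
        """Per-cycle prevalence of any conventional-cigarette use."""
        return self.perCycle[:, 1] + self.perCycle[:, 3]

    @property
    def popEC(self) -> np.ndarray:
        """Per-cycle prevalence of any e-cigarette use."""
        return self.perCycle[:, 2] + self.perCycle[:, 3]


@dataclass
class ScenarioResult:
    """Replicate-averaged trajectory for one scenario."""

    spec: ScenarioSpec
    years: list[int]
    perCycleMean: np.ndarray
    perCycleSD: np.ndarray
    perYearMean: np.ndarray
    perYearSD: np.ndarray
    perYearReplicates: np.ndarray  # (nReplicates, nYears, 4)

    @property
    def horizonMean(self) -> np.ndarray:
        """Mean state fractions at the final survey anniversary."""
        return self.perYearMean[-1]

    def year_product_means(self) -> pd.DataFrame:
        """Tidy per-year table of mean CC-any / EC-any prevalence."""
        cc = self.perYearMean[:, 1] + self.perYearMean[:, 3]
        ec = self.perYearMean[:, 2] + self.perYearMean[:, 3]
        return pd.DataFrame({"year": self.years, "ccPrev": cc, "ecPrev": ec})

    def to_frame(self, scenario_id: str = "scenario") -> pd.DataFrame:
        """Tidy per-cycle CSV table (mean and sd rows)."""
        rows = []
        cpy = self.spec.cyclesPerYear
        for label, table in (("mean", self.perCycleMean), ("sd", self.perCycleSD)):
            for cycle in range(table.shape[0]):
                frac = table[cycle]
                rows.append(
                    {
                        "scenarioId": scenario_id,
                        "replicateId": label,
                        "year": self.spec.startYear + cycle // cpy,
                        "cycle": cycle,
                        "fracNone": frac[0],
                        "fracCCOnly": frac[1],
                        "fracECOnly": frac[2],
                        "fracDual": frac[3],
                        "popCC": frac[1] + frac[3],
                        "popEC": frac[2] + frac[3],
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class _SimArrays:
    """Compiled per-agent arrays the vectorised stepper works on."""

    state: np.ndarray  # int8 (n,)
    freqCC: np.ndarray
    freqEC: np.ndarray
    baseOCC: np.ndarray
    baseOEC: np.ndarray
    cfIdx: np.ndarray  # (n, 4) close-friend indices, -1 padded
    cfCount: np.ndarray  # (n,)


def _step_arrays(
    sim: _SimArrays, params: UtilityParameters, rng: np.random.Generator
) -> None:
    """Advance all agents one synchronous decision cycle, in place."""
    state = sim.state
    n = state.size
    uses_cc = USES_CC[state]
    uses_ec = USES_EC[state]
    pop_cc = uses_cc.mean()
    pop_ec = uses_ec.mean()

    mask = sim.cfIdx >= 0
    friend_state = state[np.where(mask, sim.cfIdx, 0)]
    denom = np.maximum(sim.cfCount, 1)
    peer_cc = (USES_CC[friend_state] & mask).sum(axis=1) / denom
    peer_ec = (USES_EC[friend_state] & mask).sum(axis=1) / denom
    peer_cc[sim.cfCount == 0] = 0.0
    peer_ec[sim.cfCount == 0] = 0.0

    a = params.alphaPeerMix
    e_cc = a * peer_cc + (1 - a) * pop_cc
    e_ec = a * peer_ec + (1 - a) * pop_ec
    chi_open = params.crossover if params.crossoverOpennessChannel else 0.0
    o_cc = np.clip(
        sim.baseOCC + params.thetaCC + params.gammaOpen * e_cc + chi_open * e_ec, 0, 1
    )
    o_ec = np.clip(sim.baseOEC + params.thetaEC + params.gammaOpen * e_ec, 0, 1)

    social_cc = params.wPeer * peer_cc + params.wSoc * pop_cc
    social_ec = params.wPeer * peer_ec + params.wSoc * pop_ec
    v_cc = (
        params.muCC
        + params.eta * uses_cc
        + params.phi * sim.freqCC
        + social_cc * (1.0 + o_cc)
    )
    if params.crossoverUtilityChannel:
        v_cc = v_cc + params.crossover * social_ec
    v_ec = (
        params.muEC
        + params.eta * uses_ec
        + params.phi * sim.freqEC
        + social_ec * (1.0 + o_ec)
    )
    utilities = np.empty((n, 4))
    utilities[:, 0] = 0.0
    utilities[:, 1] = v_cc
    utilities[:, 2] = v_ec
    utilities[:, 3] = v_cc + v_ec - params.kappaDual
    if params.tasteScale > 0:
        utilities += params.tasteScale * rng.gumbel(size=(n, 4))
    new_state = np.argmax(utilities, axis=1).astype(np.int8)

    sim.state = new_state
    sim.freqCC = np.where(
        USES_CC[new_state], np.minimum(1.0, sim.freqCC + FREQ_STEP), 0.0
    )
    sim.freqEC = np.where(
        USES_EC[new_state], np.minimum(1.0, sim.freqEC + FREQ_STEP), 0.0
    )


def step_cycle(
    states: Mapping[int, SmokingState],
    profiles: Sequence[AgentProfile],
    network: SocialNetwork,
    params: UtilityParameters,
    rng: np.random.Generator,
    freqCC: Mapping[int, float] | None = None,
    freqEC: Mapping[int, float] | None = None,
) -> dict[int, SmokingState]:
    """One synchronous decision cycle over a profile/network population.

    All agents' social signals are computed from the pre-step states; every
    agent then draws a choice. Returns the full new state map (agents in
    agentId order). Frequencies default to each profile's initial values.
    """
    n = len(profiles)
    ordered = sorted(profiles, key=lambda p: p.agentId)
    cf_idx, cf_count = network.close_friend_arrays()
    sim = _SimArrays(
        state=np.array([int(states[p.agentId]) for p in ordered], dtype=np.int8),
        freqCC=np.array(
            [freqCC[p.agentId] if freqCC else p.freqCC for p in ordered], dtype=float
        ),
        freqEC=np.array(
            [freqEC[p.agentId] if freqEC else p.freqEC for p in ordered], dtype=float
        ),
        baseOCC=np.array([p.baseOpennessCC for p in ordered]),
        baseOEC=np.array([p.baseOpennessEC for p in ordered]),
        cfIdx=cf_idx,
        cfCount=cf_count,
    )
    _step_arrays(sim, params, rng)
    return {p.agentId: SmokingState(int(s)) for p, s in zip(ordered, sim.state)}


def _fractions(state: np.ndarray) -> np.ndarray:
    return np.bincount(state, minlength=4) / state.size


def _build_replicate(spec: ScenarioSpec, seed: int) -> _SimArrays:
    ss = np.random.SeedSequence(seed)
    pop_seed, net_seed, assign_seed = ss.spawn(3)
    arrays = generate_population_arrays(spec.nAgents, spec.marginals, pop_seed)
    net_int = int(net_seed.generate_state(1)[0] % (2**31))
    network = build_scale_free(spec.nAgents, spec.attachmentM, net_int)
    # close-friend designation needs states + friend counts only
    profiles_min = [
        AgentProfile(
            agentId=i,
            age=float(arrays["age"][i]),
            state=SmokingState(int(arrays["state"][i])),
            numSmokingFriends=int(arrays["numSmokingFriends"][i]),
            baseOpennessCC=float(arrays["baseOpennessCC"][i]),
            baseOpennessEC=float(arrays["baseOpennessEC"][i]),
            freqCC=float(arrays["freqCC"][i]),
            freqEC=float(arrays["freqEC"][i]),
        )
        for i in range(spec.nAgents)
    ]
    network = assign_close_friends(network, profiles_min, assign_seed)
    cf_idx, cf_count = network.close_friend_arrays()
    return _SimArrays(
        state=arrays["state"].copy(),
        freqCC=arrays["freqCC"].copy(),
        freqEC=arrays["freqEC"].copy(),
        baseOCC=arrays["baseOpennessCC"],
        baseOEC=arrays["baseOpennessEC"],
        cfIdx=cf_idx,
        cfCount=cf_count,
    )


def run_replicate(spec: ScenarioSpec, replicateId: int) -> TrajectoryResult:
    """Run one seeded replicate: fresh population + network, all cycles.

    The replicate seed is ``baseSeed + replicateId``; population, network
    topology, close-friend assignment and choice shocks each consume an
    independent stream spawned from it.
    """
    seed = spec.baseSeed + replicateId
    ss = np.random.SeedSequence(seed)
    _, _, _, choice_seed = ss.spawn(4)
    sim = _build_replicate(spec, seed)
    rng = np.random.default_rng(choice_seed)

    n_cycles = spec.nCycles
    per_cycle = np.empty((n_cycles + 1, 4))
    per_cycle[0] = _fractions(sim.state)
    for cycle in range(1, n_cycles + 1):
        _step_arrays(sim, spec.params, rng)
        per_cycle[cycle] = _fractions(sim.state)
    anniversaries = np.arange(0, n_cycles + 1, spec.cyclesPerYear)
    return TrajectoryResult(
        replicateId=replicateId,
        years=spec.years,
        perCycle=per_cycle,
        perYear=per_cycle[anniversaries],
    )


def run_scenario(spec: ScenarioSpec) -> ScenarioResult:
    """Run all replicates of a scenario and aggregate.

    Replicates use seeds ``baseSeed + 0 .. baseSeed + nReplicates − 1``;
    aggregation iterates replicates in id order so results are bit-stable.
    """
    per_cycle = np.empty((spec.nReplicates, spec.nCycles + 1, 4))
    per_year = np.empty((spec.nReplicates, len(spec.years), 4))
    for rep in range(spec.nReplicates):
        traj = run_replicate(spec, rep)
        per_cycle[rep] = traj.perCycle
        per_year[rep] = traj.perYear
    return ScenarioResult(
        spec=spec,
        years=spec.years,
        perCycleMean=per_cycle.mean(axis=0),
        perCycleSD=per_cycle.std(axis=0, ddof=0),
        perYearMean=per_year.mean(axis=0),
        perYearSD=per_year.std(axis=0, ddof=0),
        perYearReplicates=per_year,
    )
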