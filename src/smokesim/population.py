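"""Agent state and synthetic initial populations.

Agents are US high-school students characterised by age, current smoking
state (conventional cigarettes, e-cigarettes, both, or neither), the number
of their four closest friends who smoke, an attitudinal "openness" toward
each product on [0, 1], and the fraction of the last 30 days on which they
used each product.

Initial populations are drawn from marginal distributions emulating the
2011 National Youth Tobacco Survey (NYTS); packaged defaults live in
``smokesim/data/marginals_2011.yaml`` and every entry is overridable.
Attributes are drawn independently of each other by default (the joint
structure of the survey microdata is not reproduced); use-frequency is
drawn conditional on the smoking state, and is zero exactly for products
the agent does not currently use.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SmokingState",
    "AgentProfile",
    "PopulationMarginals",
    "uses_cc",
    "uses_ec",
    "generate_profiles",
    "generate_population_arrays",
    "load_profiles",
    "write_profiles",
    "profiles_to_frame",
]


class SmokingState(enum.IntEnum):
    """Current (last 30 days) smoking state of one agent."""

    NONE = 0
    CC_ONLY = 1
    EC_ONLY = 2
    DUAL = 3


#: boolean lookup tables indexed by ``SmokingState`` value
USES_CC = np.array([False, True, False, True])
USES_EC = np.array([False, False, True, True])

STATE_NAMES = [s.name for s in SmokingState]


def uses_cc(state: SmokingState | int) -> bool:
    """True if the state involves current conventional-cigarette use."""
    return bool(USES_CC[int(state)])


def uses_ec(state: SmokingState | int) -> bool:
    """True if the state involves current e-cigarette use."""
    return bool(USES_EC[int(state)])


class MarginalsError(ValueError):
    """A marginal distribution failed validation."""


class ProfileParseError(ValueError):
    """A profile table could not be parsed; message cites the offending row."""


@dataclass(frozen=True)
class AgentProfile:
    """One teenager's fixed attributes and current smoking state.

    ``baseOpennessCC``/``baseOpennessEC`` are the survey-derived openness
    levels fixed at initialisation; dynamic openness (base plus social
    exposure and scenario offsets) is computed each cycle, never stored.
    """

    agentId: int
    age: float
    state: SmokingState
    numSmokingFriends: int
    baseOpennessCC: float
    baseOpennessEC: float
    freqCC: float
    freqEC: float

    def __post_init__(self) -> None:
        if self.agentId < 0:
            raise ValueError(f"agentId must be >= 0, got {self.agentId}")
        if not 13 <= self.age <= 19:
            raise ValueError(f"age {self.age} outside [13, 19]")
        if self.numSmokingFriends not in (0, 1, 2, 3, 4):
            raise ValueError(
                f"numSmokingFriends {self.numSmokingFriends} outside 0..4"
            )
        for name in ("baseOpennessCC", "baseOpennessEC", "freqCC", "freqEC"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} {v} outside [0, 1]")
        if self.freqCC > 0 and not uses_cc(self.state):
            raise ValueError("freqCC > 0 but state does not use CC")
        if self.freqEC > 0 and not uses_ec(self.state):
            raise ValueError("freqEC > 0 but state does not use EC")


def _check_probs(name: str, probs: np.ndarray, size: int | None = None) -> np.ndarray:
    probs = np.asarray(probs, dtype=float)
    if size is not None and probs.shape != (size,):
        raise MarginalsError(f"{name}: expected {size} entries, got {probs.shape}")
    if np.any(probs < 0):
        raise MarginalsError(f"{name}: negative probability")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise MarginalsError(f"{name}: probabilities sum to {probs.sum()!r}, not 1")
    return probs


def _check_dist(name: str, dist: dict) -> dict:
    """Validate a named-distribution block ({kind: ..., ...})."""
    if not isinstance(dist, dict) or "kind" not in dist:
        raise MarginalsError(f"{name}: expected a mapping with a 'kind' key")
    kind = dist["kind"]
    if kind == "survey_items":
        _check_probs(f"{name}.itemProbs", np.asarray(dist["itemProbs"]), 4)
    elif kind == "discrete":
        values = np.asarray(dist["values"], dtype=float)
        probs = _check_probs(f"{name}.probs", np.asarray(dist["probs"]))
        if values.shape != probs.shape:
            raise MarginalsError(f"{name}: values/probs length mismatch")
        if np.any((values < 0) | (values > 1)):
            raise MarginalsError(f"{name}: values outside [0, 1]")
    elif kind == "beta":
        if dist["a"] <= 0 or dist["b"] <= 0:
            raise MarginalsError(f"{name}: beta parameters must be positive")
    else:
        raise MarginalsError(f"{name}: unknown distribution kind {kind!r}")
    return dist


def _sample_dist(dist: dict, rng: np.random.Generator, size: int) -> np.ndarray:
    kind = dist["kind"]
    if kind == "survey_items":
        # two 4-point survey items scored {0, 1/3, 2/3, 1}, averaged
        scores = np.array([0.0, 1 / 3, 2 / 3, 1.0])
        p = np.asarray(dist["itemProbs"], dtype=float)
        a = scores[rng.choice(4, size=size, p=p)]
        b = scores[rng.choice(4, size=size, p=p)]
        return (a + b) / 2.0
    if kind == "discrete":
        values = np.asarray(dist["values"], dtype=float)
        p = np.asarray(dist["probs"], dtype=float)
        return values[rng.choice(len(values), size=size, p=p)]
    if kind == "beta":
        return rng.beta(dist["a"], dist["b"], size=size)
    raise MarginalsError(f"unknown distribution kind {kind!r}")


def _dist_support(dist: dict) -> tuple[np.ndarray, np.ndarray]:
    """Discrete support (values, probs) of a [0,1] distribution.

    ``survey_items`` is the average of two i.i.d. 4-point items, giving a
    7-point support; ``beta`` is discretised on a fine grid for quantile
    mapping.
    """
    kind = dist["kind"]
    if kind == "survey_items":
        scores = np.array([0.0, 1 / 3, 2 / 3, 1.0])
        p = np.asarray(dist["itemProbs"], dtype=float)
        pairs: dict[float, float] = {}
        for i in range(4):
            for j in range(4):
                v = (scores[i] + scores[j]) / 2.0
                pairs[round(v, 12)] = pairs.get(round(v, 12), 0.0) + p[i] * p[j]
        values = np.array(sorted(pairs))
        return values, np.array([pairs[v] for v in values])
    if kind == "discrete":
        values = np.asarray(dist["values"], dtype=float)
        probs = np.asarray(dist["probs"], dtype=float)
        order = np.argsort(values)
        return values[order], probs[order]
    if kind == "beta":
        from scipy.stats import beta as beta_dist

        grid = np.linspace(0, 1, 201)
        cdf = beta_dist.cdf(grid, dist["a"], dist["b"])
        probs = np.diff(np.concatenate([[0.0], cdf]))
        return grid, probs / probs.sum()
    raise MarginalsError(f"unknown distribution kind {kind!r}")


def _quantile_map(u: np.ndarray, values: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Map uniforms to a discrete distribution by inverse CDF."""
    edges = np.cumsum(probs)
    edges[-1] = 1.0  # guard rounding
    idx = np.searchsorted(edges, u, side="right")
    return values[np.minimum(idx, len(values) - 1)]


#: state order by "smoking severity" used for the copula quantile mapping
SEVERITY_ORDER = np.array(
    [SmokingState.NONE, SmokingState.EC_ONLY, SmokingState.CC_ONLY, SmokingState.DUAL],
    dtype=np.int8,
)


def _copula_correlation(copula: dict) -> np.ndarray:
    r_sf = float(copula.get("rhoStateFriends", 0.0))
    r_so = float(copula.get("rhoStateOpenness", 0.0))
    r_fo = float(copula.get("rhoFriendsOpenness", 0.0))
    corr = np.array([[1.0, r_sf, r_so], [r_sf, 1.0, r_fo], [r_so, r_fo, 1.0]])
    if np.any(np.abs(corr) > 1):
        raise MarginalsError("copula correlations must be in [-1, 1]")
    if np.linalg.eigvalsh(corr).min() < -1e-10:
        raise MarginalsError("copula correlation matrix is not positive semidefinite")
    return corr


@dataclass
class PopulationMarginals:
    """Marginal distributions from which initial agent profiles are drawn.

    Parameters
    ----------
    stateProbs
        Probability of each :class:`SmokingState`, ordered NONE, CC_ONLY,
        EC_ONLY, DUAL.
    friendCountProbs
        Probability of reporting 0..4 of the four closest friends smoking.
    opennessCCDist, opennessECDist
        Named distribution on [0, 1] for base openness toward each product
        (kinds: ``survey_items``, ``discrete``, ``beta``).
    freqUseDist
        Distribution of the 30-day use-day fraction, applied per used
        product conditional on the smoking state.
    ageProbs
        Probability of each integer age 13..19.
    copula
        Optional Gaussian rank-correlation copula coupling smoking state,
        smoking-friend count and openness while preserving every marginal
        (keys ``rhoStateFriends``, ``rhoStateOpenness``,
        ``rhoFriendsOpenness``). ``None`` gives fully independent draws.
        When the copula is active, base openness toward the two products
        shares one latent attitude (a single "openness to smoking"
        construct), so the per-agent CC and EC openness are rank-identical.
    """

    stateProbs: np.ndarray
    friendCountProbs: np.ndarray
    opennessCCDist: dict
    opennessECDist: dict
    freqUseDist: dict
    ageProbs: np.ndarray = field(
        default_factory=lambda: np.array([0.02, 0.20, 0.21, 0.21, 0.20, 0.14, 0.02])
    )
    copula: dict | None = None

    def __post_init__(self) -> None:
        self.stateProbs = _check_probs("stateProbs", self.stateProbs, 4)
        self.friendCountProbs = _check_probs("friendCountProbs", self.friendCountProbs, 5)
        self.ageProbs = _check_probs("ageProbs", self.ageProbs, 7)
        _check_dist("opennessCCDist", self.opennessCCDist)
        _check_dist("opennessECDist", self.opennessECDist)
        _check_dist("freqUseDist", self.freqUseDist)
        if self.copula is not None:
            _copula_correlation(self.copula)

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationMarginals":
        state_probs = d["stateProbs"]
        if isinstance(state_probs, dict):
            state_probs = [state_probs[name] for name in STATE_NAMES]
        kwargs = dict(
            stateProbs=np.asarray(state_probs, dtype=float),
            friendCountProbs=np.asarray(d["friendCountProbs"], dtype=float),
            opennessCCDist=d["opennessCCDist"],
            opennessECDist=d.get("opennessECDist", d["opennessCCDist"]),
            freqUseDist=d["freqUseDist"],
            copula=d.get("copula"),
        )
        if "ageProbs" in d:
            kwargs["ageProbs"] = np.asarray(d["ageProbs"], dtype=float)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "stateProbs": {n: float(p) for n, p in zip(STATE_NAMES, self.stateProbs)},
            "friendCountProbs": [float(p) for p in self.friendCountProbs],
            "opennessCCDist": self.opennessCCDist,
            "opennessECDist": self.opennessECDist,
            "freqUseDist": self.freqUseDist,
            "ageProbs": [float(p) for p in self.ageProbs],
            "copula": self.copula,
        }


def generate_population_arrays(
    n: int, marginals: PopulationMarginals, seed: int | np.random.SeedSequence
) -> dict[str, np.ndarray]:
    """Draw an initial population as flat numpy arrays (engine fast path).

    Returns a dict with keys ``state``, ``age``, ``numSmokingFriends``,
    ``baseOpennessCC``, ``baseOpennessEC``, ``freqCC``, ``freqEC``.
    Deterministic given (n, marginals, seed); each attribute is drawn as a
    single vectorised pass, so agent i's draw does not depend on how many
    other agents exist before it in iteration order.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    age = (13 + rng.choice(7, size=n, p=marginals.ageProbs)).astype(float)
    if marginals.copula is None:
        state = rng.choice(4, size=n, p=marginals.stateProbs).astype(np.int8)
        nfriends = rng.choice(5, size=n, p=marginals.friendCountProbs).astype(np.int8)
        o_cc = _sample_dist(marginals.opennessCCDist, rng, n)
        o_ec = _sample_dist(marginals.opennessECDist, rng, n)
    else:
        from scipy.stats import norm

        corr = _copula_correlation(marginals.copula)
        z = rng.multivariate_normal(
            np.zeros(3), corr, size=n, method="cholesky"
        )
        u = norm.cdf(z)
        state = SEVERITY_ORDER[
            np.searchsorted(
                np.cumsum(marginals.stateProbs[SEVERITY_ORDER]).clip(max=1.0),
                u[:, 0],
                side="right",
            ).clip(max=3)
        ]
        nfriends = _quantile_map(
            u[:, 1], np.arange(5), marginals.friendCountProbs
        ).astype(np.int8)
        occ_vals, occ_probs = _dist_support(marginals.opennessCCDist)
        oec_vals, oec_probs = _dist_support(marginals.opennessECDist)
        # one latent attitude drives openness toward both products
        o_cc = _quantile_map(u[:, 2], occ_vals, occ_probs)
        o_ec = _quantile_map(u[:, 2], oec_vals, oec_probs)
    freq_cc = np.where(USES_CC[state], _sample_dist(marginals.freqUseDist, rng, n), 0.0)
    freq_ec = np.where(USES_EC[state], _sample_dist(marginals.freqUseDist, rng, n), 0.0)
    return {
        "state": state,
        "age": age,
        "numSmokingFriends": nfriends,
        "baseOpennessCC": o_cc,
        "baseOpennessEC": o_ec,
        "freqCC": freq_cc,
        "freqEC": freq_ec,
    }


def generate_profiles(
    n: int, marginals: PopulationMarginals, seed: int
) -> list[AgentProfile]:
    """Generate ``n`` synthetic agent profiles from the stated marginals.

    Attributes are independent draws except use-frequency, which is drawn
    conditional on the smoking state (zero for unused products). Identical
    (n, marginals, seed) yield identical output.
    """
    arrays = generate_population_arrays(n, marginals, seed)
    return [
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
        for i in range(n)
    ]


PROFILE_COLUMNS = [
    "agentId",
    "age",
    "state",
    "numSmokingFriends",
    "baseOpennessCC",
    "baseOpennessEC",
    "freqCC",
    "freqEC",
]


def profiles_to_frame(profiles: Sequence[AgentProfile]) -> pd.DataFrame:
    """Tabulate profiles with the state serialised as its enumeration name."""
    return pd.DataFrame(
        {
            "agentId": [p.agentId for p in profiles],
            "age": [p.age for p in profiles],
            "state": [p.state.name for p in profiles],
            "numSmokingFriends": [p.numSmokingFriends for p in profiles],
            "baseOpennessCC": [p.baseOpennessCC for p in profiles],
            "baseOpennessEC": [p.baseOpennessEC for p in profiles],
            "freqCC": [p.freqCC for p in profiles],
            "freqEC": [p.freqEC for p in profiles],
        },
        columns=PROFILE_COLUMNS,
    )


def write_profiles(profiles: Sequence[AgentProfile], path) -> None:
    # %.17g preserves doubles exactly across the round trip
    profiles_to_frame(profiles).to_csv(path, index=False, float_format="%.17g")


def population_summary(profiles: Sequence[AgentProfile]) -> dict:
    """Empirical marginals of a profile list (echoed by the CLI)."""
    states = np.array([int(p.state) for p in profiles])
    nf = np.array([p.numSmokingFriends for p in profiles])
    return {
        "n": len(profiles),
        "stateFractions": {
            name: float((states == i).mean()) for i, name in enumerate(STATE_NAMES)
        },
        "popCC": float(USES_CC[states].mean()),
        "popEC": float(USES_EC[states].mean()),
        "meanSmokingFriends": float(nf.mean()),
        "meanBaseOpennessCC": float(np.mean([p.baseOpennessCC for p in profiles])),
        "meanBaseOpennessEC": float(np.mean([p.baseOpennessEC for p in profiles])),
    }


def load_profiles(path) -> list[AgentProfile]:
    """Load and validate a profile CSV; errors cite the offending data row.

    Row numbers in error messages are 1-based data rows (header excluded).
    Row order is preserved and agentId uniqueness is enforced.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ProfileParseError(f"missing column(s): {', '.join(missing)}")
    profiles: list[AgentProfile] = []
    seen: set[int] = set()
    for idx, rec in enumerate(df.itertuples(index=False), start=1):
        try:
            state = SmokingState[str(rec.state)]
        except KeyError:
            raise ProfileParseError(
                f"row {idx}: unknown state {rec.state!r}"
            ) from None
        try:
            profile = AgentProfile(
                agentId=int(rec.agentId),
                age=float(rec.age),
                state=state,
                numSmokingFriends=int(rec.numSmokingFriends),
                baseOpennessCC=float(rec.baseOpennessCC),
                baseOpennessEC=float(rec.baseOpennessEC),
                freqCC=float(rec.freqCC),
                freqEC=float(rec.freqEC),
            )
        except (ValueError, TypeError) as exc:
            raise ProfileParseError(f"row {idx}: {exc}") from None
        if profile.agentId in seen:
            raise ProfileParseError(f"row {idx}: duplicate agentId {profile.agentId}")
        seen.add(profile.agentId)
        profiles.append(profile)
    return profiles
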