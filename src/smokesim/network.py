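"""Scale-free friendship network and close-friend designation.

The friendship graph is built by preferential attachment (Barabási–Albert),
so the degree distribution is heavy-tailed: a few highly connected hubs and
many low-degree agents. Each agent then designates up to four neighbours as
"close friends", chosen so that the number of designated friends who smoke
conventional cigarettes matches the agent's survey response to "How many of
your four closest friends smoke cigarettes?" whenever the neighbourhood
composition permits. The graph is static for the whole simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .population import AgentProfile, SmokingState, USES_CC

__all__ = [
    "SocialNetwork",
    "build_scale_free",
    "assign_close_friends",
    "write_network",
    "read_network",
]

MAX_CLOSE_FRIENDS = 4


@dataclass
class SocialNetwork:
    """Undirected friendship graph plus per-agent close-friend designations.

    ``closeFriends`` maps each agent to an ordered list of at most four
    neighbour ids; it is empty until :func:`assign_close_friends` runs.
    ``closeFriendDiscrepancy`` records, per agent, the absolute difference
    between the requested and achieved number of smoking close friends.
    """

    graph: nx.Graph
    closeFriends: dict[int, list[int]] = field(default_factory=dict)
    closeFriendDiscrepancy: dict[int, int] = field(default_factory=dict)

    @property
    def nodes(self) -> list[int]:
        return sorted(self.graph.nodes)

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbours(self, agent_id: int) -> list[int]:
        return sorted(self.graph.neighbors(agent_id))

    def degree(self, agent_id: int) -> int:
        return self.graph.degree(agent_id)

    def edge_hash(self) -> int:
        """Order-independent hash of the edge set (topology fingerprint)."""
        return hash(frozenset(frozenset(e) for e in self.graph.edges))

    def close_friend_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Close friends as an (n, 4) index array padded with -1, plus counts."""
        n = self.graph.number_of_nodes()
        idx = np.full((n, MAX_CLOSE_FRIENDS), -1, dtype=np.int64)
        count = np.zeros(n, dtype=np.int64)
        for i in range(n):
            friends = self.closeFriends.get(i, [])
            count[i] = len(friends)
            idx[i, : len(friends)] = friends
        return idx, count


def build_scale_free(n: int, m: int, seed: int) -> SocialNetwork:
    """Build a preferential-attachment friendship graph on ``n`` agents.

    Each arriving agent attaches to ``m`` existing agents with probability
    proportional to degree, giving exactly ``m * (n - m)`` edges, a connected
    graph, and a heavy-tailed degree distribution. Deterministic given seed.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 1 <= m < n:
        raise ValueError(f"attachment count m={m} must satisfy 1 <= m < n={n}")
    graph = nx.barabasi_albert_graph(n, m, seed=int(seed))
    return SocialNetwork(graph=graph)


def assign_close_friends(
    network: SocialNetwork,
    profiles: Sequence[AgentProfile],
    seed: int | np.random.SeedSequence,
) -> SocialNetwork:
    """Designate up to four close friends per agent, matching smoker counts.

    For each agent, ``min(4, degree)`` neighbours are designated close
    friends, choosing smoking (conventional-cigarette-using) neighbours so
    their count equals the agent's reported ``numSmokingFriends`` whenever
    the neighbourhood composition allows; otherwise the achievable extreme
    is used and the per-agent shortfall recorded. Designations are
    independent across agents, so each agent's greedy choice is optimal;
    the edge set is never modified.
    """
    if len(profiles) < network.graph.number_of_nodes():
        raise ValueError("profiles must cover all network nodes")
    state_by_id = {p.agentId: p.state for p in profiles}
    target_by_id = {p.agentId: p.numSmokingFriends for p in profiles}
    rng = np.random.default_rng(seed)
    close: dict[int, list[int]] = {}
    disc: dict[int, int] = {}
    for i in network.nodes:
        nbrs = network.neighbours(i)
        smokers = [j for j in nbrs if USES_CC[state_by_id[j]]]
        others = [j for j in nbrs if not USES_CC[state_by_id[j]]]
        rng.shuffle(smokers)
        rng.shuffle(others)
        k = min(MAX_CLOSE_FRIENDS, len(nbrs))
        target = min(target_by_id[i], k)
        n_smoke = min(target, len(smokers))
        n_other = min(k - n_smoke, len(others))
        # neighbourhood may force extra smokers to fill the close set
        n_smoke_extra = k - n_smoke - n_other
        chosen = smokers[: n_smoke + n_smoke_extra] + others[:n_other]
        close[i] = chosen
        disc[i] = abs((n_smoke + n_smoke_extra) - target_by_id[i])
    return SocialNetwork(
        graph=network.graph, closeFriends=close, closeFriendDiscrepancy=disc
    )


def mean_absolute_discrepancy(network: SocialNetwork) -> float:
    """Population mean of |requested − achieved| smoking close friends."""
    if not network.closeFriendDiscrepancy:
        raise ValueError("close friends have not been assigned")
    return float(np.mean(list(network.closeFriendDiscrepancy.values())))


def write_network(network: SocialNetwork, edge_path, close_path=None) -> None:
    """Write the edge list (tab-separated) and optionally the close-friend CSV."""
    with open(edge_path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in network.graph.edges):
            fh.write(f"{u}\t{v}\n")
    if close_path is not None:
        rows = []
        for i in network.nodes:
            friends = network.closeFriends.get(i, [])
            rows.append(
                [i] + friends + [""] * (MAX_CLOSE_FRIENDS - len(friends))
            )
        pd.DataFrame(
            rows, columns=["agentId", "friend1", "friend2", "friend3", "friend4"]
        ).to_csv(close_path, index=False)


def read_network(edge_path, close_path=None) -> SocialNetwork:
    graph = nx.Graph()
    with open(edge_path) as fh:
        for line in fh:
            if line.strip():
                u, v = line.split("\t")
                graph.add_edge(int(u), int(v))
    network = SocialNetwork(graph=graph)
    if close_path is not None:
        df = pd.read_csv(close_path)
        close = {}
        for rec in df.itertuples(index=False):
            friends = [
                int(f)
                for f in (rec.friend1, rec.friend2, rec.friend3, rec.friend4)
                if pd.notna(f) and f != ""
            ]
            close[int(rec.agentId)] = friends
        network.closeFriends = close
    return network
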