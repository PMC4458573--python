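"""Dense-module extraction via clustering-coefficient vertex weighting.

An MCODE-style procedure: each node is weighted by its clustering
coefficient Ci = 2n / (Ki (Ki - 1)) (Ki neighbors, n edges among them); the
highest-weight unassigned node seeds a module that grows outward, admitting
a neighbor j whenever W_j / W_seed exceeds a ratio cutoff. Assigned nodes
are removed from further seeding and expansion (hard partition), and
modules failing a minimum induced degree or size are dropped.

The weight here is Ci itself; the originally published MCODE scales the
coefficient by the node's highest k-core, which this procedure deliberately
does not do (see docs/methods.md).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Mapping

import networkx as nx

from .model import CoexpressionNetwork


@dataclass(frozen=True)
class VertexWeight:
    node: str
    ki: int  # neighborhood size (degree)
    n_edges: int  # edges among the Ki neighbors
    ci: float  # 2*n / (Ki*(Ki-1)), 0 when Ki < 2

    @property
    def weight(self) -> float:
        return self.ci


@dataclass(frozen=True)
class ModuleConfig:
    weight_ratio_min: float = 0.1
    min_degree: int = 2
    min_nodes: int = 6  # "node count > 5"

    def __post_init__(self) -> None:
        if not (0.0 < self.weight_ratio_min < 1.0):
            raise ValueError("weight_ratio_min must be in (0, 1)")
        if self.min_nodes < 1:
            raise ValueError("min_nodes must be >= 1")


@dataclass(frozen=True)
class Module:
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    seed: str
    score: float  # mean vertex weight over the module


def vertex_weights(network: CoexpressionNetwork) -> dict[str, VertexWeight]:
    g = network.graph
    out: dict[str, VertexWeight] = {}
    for node in g.nodes:
        nbrs = list(g.neighbors(node))
        ki = len(nbrs)
        n_edges = sum(
            1
            for i in range(ki)
            for j in range(i + 1, ki)
            if g.has_edge(nbrs[i], nbrs[j])
        )
        ci = 2.0 * n_edges / (ki * (ki - 1)) if ki >= 2 else 0.0
        out[node] = VertexWeight(node=node, ki=ki, n_edges=n_edges, ci=ci)
    return out


def expand_module(
    network: CoexpressionNetwork,
    weights: Mapping[str, VertexWeight],
    seed: str,
    config: ModuleConfig | None = None,
    allowed: set[str] | None = None,
) -> Module:
    """Grow a module outward from ``seed`` by the weight-ratio rule.

    Breadth-first from the seed; a neighbor joins iff its weight divided by
    the seed's exceeds ``weight_ratio_min``; joined nodes' neighbors are
    examined in turn, each node visited once. ``allowed`` restricts the
    search (used by find_modules to exclude already-assigned nodes).
    """
    config = config or ModuleConfig()
    g = network.graph
    if seed not in g:
        raise KeyError(f"seed {seed!r} not in network")
    w_seed = weights[seed].weight
    members = {seed}
    if w_seed > 0.0:
        visited = {seed}
        queue = deque([seed])
        while queue:
            node = queue.popleft()
            for nbr in sorted(g.neighbors(node)):
                if nbr in visited or (allowed is not None and nbr not in allowed):
                    continue
                visited.add(nbr)
                if weights[nbr].weight / w_seed > config.weight_ratio_min:
                    members.add(nbr)
                    queue.append(nbr)
    sub = g.subgraph(members)
    return Module(
        nodes=frozenset(members),
        edges=frozenset((min(u, v), max(u, v)) for u, v in sub.edges),
        seed=seed,
        score=sum(weights[n].weight for n in members) / len(members),
    )


def find_modules(
    network: CoexpressionNetwork, config: ModuleConfig | None = None
) -> list[Module]:
    """Iterative seed-expansion over the whole network, then post-filtering.

    Seeds are picked by decreasing weight (ties by id); expansion only sees
    unassigned nodes, and module members are deleted from the search
    afterwards. Modules are kept when the induced minimum degree reaches
    ``min_degree`` and the node count reaches ``min_nodes``; sorted by size
    descending, ties by smallest member id.
    """
    config = config or ModuleConfig()
    weights = vertex_weights(network)
    unassigned = set(network.graph.nodes)
    raw: list[Module] = []
    while unassigned:
        seed = max(unassigned, key=lambda n: (weights[n].weight, _NegStr(n)))
        if weights[seed].weight <= 0.0:
            break  # remaining nodes cannot anchor a dense region
        module = expand_module(network, weights, seed, config, allowed=unassigned)
        unassigned -= module.nodes
        raw.append(module)
    kept = []
    for m in raw:
        if len(m.nodes) < config.min_nodes:
            continue
        sub = network.graph.subgraph(m.nodes)
        if min(dict(sub.degree).values()) < config.min_degree:
            continue
        kept.append(m)
    kept.sort(key=lambda m: (-len(m.nodes), min(m.nodes)))
    return kept


class _NegStr:
    """Orders strings descending inside a max(); lexicographic tie-break."""

    __slots__ = ("s",)

    def __init__(self, s: str) -> None:
        self.s = s

    def __lt__(self, other: "_NegStr") -> bool:
        return self.s > other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _NegStr) and self.s == other.s
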