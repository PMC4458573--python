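"""Pearson co-expression networks over an expression compendium.

Edges connect gene pairs whose Pearson correlation across the compendium
arrays reaches a threshold; the working threshold (0.83 by default elsewhere
in the pipeline) can be picked by sweeping a grid and scoring each candidate
network by how many GO terms its node set enriches. Nodes are genes with at
least one retained edge, so a network can hold fewer nodes than input genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .go_enrichment import classic_enrichment
from .model import CompendiumMatrix, CoexpressionNetwork, OntologyDag

DEFAULT_GRID: tuple[float, ...] = tuple(round(0.70 + 0.01 * i, 2) for i in range(21))


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt((xc * xc).sum()))
    sy = float(np.sqrt((yc * yc).sum()))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance: correlation undefined")
    return float((xc * yc).sum() / (sx * sy))


def _corr_matrix(matrix: CompendiumMatrix, genes: list[str]) -> np.ndarray:
    sub = matrix.submatrix(genes).to_numpy()
    if sub.shape[1] < 3:
        raise ValueError("need at least 3 arrays for correlation")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.corrcoef(sub)  # zero-variance rows yield NaN, never an edge


def build_network(
    matrix: CompendiumMatrix, genes: Iterable[str], threshold: float
) -> CoexpressionNetwork:
    """Edges where r >= threshold; genes without any edge are not nodes."""
    genes = sorted(set(genes))
    g = nx.Graph()
    if len(genes) >= 2:
        corr = _corr_matrix(matrix, genes)
        ii, jj = np.where(np.triu(corr >= threshold, k=1))
        for i, j in zip(ii.tolist(), jj.tolist()):
            g.add_edge(genes[i], genes[j], weight=float(corr[i, j]))
    return CoexpressionNetwork(g, threshold)


@dataclass(frozen=True)
class SweepResult:
    thresholds: tuple[float, ...]
    scores: tuple[int, ...]
    chosen: float


def select_threshold(
    matrix: CompendiumMatrix,
    genes: Iterable[str],
    dag: OntologyDag,
    grid: Sequence[float] = DEFAULT_GRID,
    sweep_alpha: float = 1e-3,
    statistic: str = "count",
) -> SweepResult:
    """Pick the threshold whose network shows the best GO enrichment.

    Per grid value: build the network, run classic enrichment of its node
    set against the full input gene set, and score it. ``statistic="count"``
    (default) counts terms with p < sweep_alpha; ``"min_p"`` ranks by the
    smallest p-value. Ties break toward the largest threshold.
    """
    if not len(grid):
        raise ValueError("empty threshold grid")
    if statistic not in {"count", "min_p"}:
        raise ValueError(f"unknown sweep statistic {statistic!r}")
    genes = sorted(set(genes))
    thresholds = tuple(float(t) for t in grid)
    raw_scores: list[float] = []
    counts: list[int] = []
    any_nonempty = False
    for t in thresholds:
        net = build_network(matrix, genes, t)
        if not net.nodes:
            counts.append(0)
            raw_scores.append(0.0)
            continue
        any_nonempty = True
        results = classic_enrichment(dag, net.nodes, genes)
        n_sig = sum(1 for r in results if r.p_classic < sweep_alpha)
        counts.append(n_sig)
        if statistic == "count":
            raw_scores.append(float(n_sig))
        else:
            best = min((r.p_classic for r in results), default=1.0)
            raw_scores.append(-best)  # larger is better
    if not any_nonempty:
        raise ValueError(
            "every network in the sweep is empty; try a lower threshold grid"
        )
    best_score = max(raw_scores)
    chosen = max(t for t, s in zip(thresholds, raw_scores) if s == best_score)
    return SweepResult(thresholds=thresholds, scores=tuple(counts), chosen=chosen)


def connected_components(network: CoexpressionNetwork) -> list[set[str]]:
    """Components sorted by size descending, then smallest member id."""
    comps = [set(c) for c in nx.connected_components(network.graph)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def bait_prey_network(
    matrix: CompendiumMatrix,
    baits: Iterable[str],
    preys: Iterable[str],
    threshold: float,
) -> CoexpressionNetwork:
    """Co-expression network keeping only edges that touch a bait.

    All bait-bait, bait-prey and prey-prey correlations are computed at the
    threshold, then every prey-prey edge is discarded and nodes left
    isolated are dropped.
    """
    baits, preys = set(baits), set(preys)
    if baits & preys:
        raise ValueError(f"bait/prey sets overlap: {sorted(baits & preys)[:5]}")
    net = build_network(matrix, baits | preys, threshold)
    g = net.graph
    g.remove_edges_from(
        [(u, v) for u, v in g.edges if u in preys and v in preys]
    )
    g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])
    return CoexpressionNetwork(g, threshold)
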