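"""Domain containers shared across the pipeline.

Coordinate convention: all genomic intervals are 1-based inclusive (the GFF3
convention); BED-like output written by :mod:`roothair.io_formats` converts to
0-based half-open at the boundary. Motif-hit coordinates are 1-based and local
to the scanned region sequence, with start > end flagging a minus-orientation
match (the read-out printed 5'->3' on the minus strand).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "DiffRecord",
    "DiffTable",
    "GeneModel",
    "CompendiumMatrix",
    "OntologyDag",
    "MotifHit",
    "CoexpressionNetwork",
]


def _log2_ratio(rpkm_rh: float, rpkm_nrh: float) -> float:
    """log2(NRH/RH) with the inf convention used throughout.

    RH-enriched genes come out negative; a gene silent in NRH maps to -inf
    and a gene silent in RH maps to +inf ("inf" rows of the novel-transcript
    table). Both zero is undefined.
    """
    if rpkm_rh < 0 or rpkm_nrh < 0:
        raise ValueError("RPKM values must be non-negative")
    if rpkm_rh == 0 and rpkm_nrh == 0:
        raise ValueError("log2 fold change undefined when both RPKM are 0")
    if rpkm_rh == 0:
        return math.inf
    if rpkm_nrh == 0:
        return -math.inf
    return math.log2(rpkm_nrh / rpkm_rh)


@dataclass(frozen=True)
class DiffRecord:
    """One gene's two-condition abundance from a Cuffdiff-style table."""

    gene_id: str
    annotation: str
    rpkm_rh: float
    rpkm_nrh: float
    q_value: float
    status: str = "OK"

    def __post_init__(self) -> None:
        if self.rpkm_rh < 0 or self.rpkm_nrh < 0:
            raise ValueError(f"{self.gene_id}: negative RPKM")
        if not (0.0 <= self.q_value <= 1.0):
            raise ValueError(f"{self.gene_id}: q-value {self.q_value} outside [0,1]")

    @property
    def log2fc(self) -> float:
        """Derived log2(RPKM_NRH / RPKM_RH); ±inf when one side is 0."""
        return _log2_ratio(self.rpkm_rh, self.rpkm_nrh)


class DiffTable:
    """Ordered collection of :class:`DiffRecord` with unique gene ids."""

    def __init__(
        self,
        rows: Iterable[DiffRecord],
        condition_names: tuple[str, str] = ("RH", "NRH"),
    ) -> None:
        self.rows: list[DiffRecord] = list(rows)
        self.condition_names = tuple(condition_names)
        seen: set[str] = set()
        for r in self.rows:
            if r.gene_id in seen:
                raise ValueError(f"duplicate gene id: {r.gene_id}")
            seen.add(r.gene_id)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[DiffRecord]:
        return iter(self.rows)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DiffTable):
            return NotImplemented
        return (
            self.rows == other.rows and self.condition_names == other.condition_names
        )

    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.rows]

    def get(self, gene_id: str) -> DiffRecord:
        for r in self.rows:
            if r.gene_id == gene_id:
                return r
        raise KeyError(gene_id)


@dataclass
class GeneModel:
    """Exon/CDS structure of one transcript on a chromosome.

    ``exons`` and ``cds_segments`` are lists of [start, end] 1-based inclusive
    genomic intervals, stored sorted by start. ``start_codon_pos`` is the
    genomic coordinate of the first translated base: min CDS start on the +
    strand, max CDS end on the - strand.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_segments: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.transcript_id}: unknown strand {self.strand!r}")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        self.cds_segments = sorted((int(a), int(b)) for a, b in self.cds_segments)
        for a, b in self.exons + self.cds_segments:
            if a > b:
                raise ValueError(f"{self.transcript_id}: inverted interval {a}-{b}")
        for i in range(1, len(self.exons)):
            if self.exons[i][0] <= self.exons[i - 1][1]:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        for c0, c1 in self.cds_segments:
            if not any(a <= c0 and c1 <= b for a, b in self.exons):
                raise ValueError(
                    f"{self.transcript_id}: CDS {c0}-{c1} outside exon bounds"
                )

    @property
    def start_codon_pos(self) -> int:
        if not self.cds_segments:
            raise ValueError(f"{self.transcript_id}: no CDS")
        if self.strand == "+":
            return self.cds_segments[0][0]
        return self.cds_segments[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between sorted exons, genomic order (not transcription order)."""
        out = []
        for i in range(1, len(self.exons)):
            out.append((self.exons[i - 1][1] + 1, self.exons[i][0] - 1))
        return out

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])


class CompendiumMatrix:
    """Gene x array expression matrix (log-scale intensities).

    Thin wrapper over a pandas DataFrame (index = gene ids, columns = array
    ids) enforcing the no-missing-values contract.
    """

    def __init__(self, values: pd.DataFrame) -> None:
        if values.isna().any().any():
            raise ValueError("compendium matrix contains missing values")
        if values.index.has_duplicates:
            raise ValueError("duplicate gene ids in compendium")
        self.values = values.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def arrays(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_arrays(self) -> int:
        return self.values.shape[1]

    def submatrix(self, genes: Sequence[str]) -> pd.DataFrame:
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from compendium: {missing[:5]}")
        return self.values.loc[list(genes)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CompendiumMatrix):
            return NotImplemented
        return self.values.equals(other.values)


class OntologyDag:
    """GO-style DAG (is_a edges only) plus gene->terms annotations.

    ``graph`` stores directed child -> parent edges. After construction call
    :meth:`propagate_annotations` to close annotations under the true-path
    rule (a gene annotated to a term is annotated to all of its ancestors).
    """

    def __init__(
        self,
        terms: Mapping[str, str],
        edges: Iterable[tuple[str, str]],
        annotations: Mapping[str, Iterable[str]] | None = None,
    ) -> None:
        self.names: dict[str, str] = dict(terms)
        self.graph = nx.DiGraph()
        self.graph.add_nodes_from(self.names)
        for child, parent in edges:
            if child not in self.names or parent not in self.names:
                raise ValueError(f"edge references unknown term: {child}->{parent}")
            self.graph.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("ontology contains a cycle")
        self.annotations: dict[str, set[str]] = {
            g: set(ts) for g, ts in (annotations or {}).items()
        }
        for g, ts in self.annotations.items():
            unknown = ts - set(self.names)
            if unknown:
                raise ValueError(f"gene {g} annotated to unknown terms {unknown}")

    @property
    def terms(self) -> list[str]:
        return list(self.names)

    def ancestors(self, term: str) -> set[str]:
        """Strict ancestors (all terms reachable via is_a)."""
        return set(nx.descendants(self.graph, term))

    def roots(self) -> list[str]:
        return [t for t in self.graph.nodes if self.graph.out_degree(t) == 0]

    def depths(self) -> dict[str, int]:
        """Longest-path depth from a root, per term (roots are depth 0)."""
        depth: dict[str, int] = {}
        # parents come after children in child->parent topological order,
        # so walk it reversed: parents first.
        for term in reversed(list(nx.topological_sort(self.graph))):
            parents = list(self.graph.successors(term))
            depth[term] = 0 if not parents else 1 + max(depth[p] for p in parents)
        return depth

    def propagate_annotations(self) -> None:
        for gene, ts in self.annotations.items():
            closed = set(ts)
            for t in ts:
                closed |= self.ancestors(t)
            self.annotations[gene] = closed

    def genes_per_term(self, population: Iterable[str] | None = None) -> dict[str, set[str]]:
        pop = set(population) if population is not None else None
        out: dict[str, set[str]] = {t: set() for t in self.names}
        for gene, ts in self.annotations.items():
            if pop is not None and gene not in pop:
                continue
            for t in ts:
                out[t].add(gene)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OntologyDag):
            return NotImplemented
        return (
            self.names == other.names
            and set(self.graph.edges) == set(other.graph.edges)
            and self.annotations == other.annotations
        )


@dataclass(frozen=True)
class MotifHit:
    """A consensus match inside one region of one gene.

    start/end are 1-based local coordinates in the region sequence; start >
    end marks a minus-orientation match. matched_seq is the region-strand
    text of the footprint read 5'->3'; for minus-orientation hits its
    reverse complement is what fits the consensus.
    """

    gene_id: str
    region: str  # promoter | intron | cds
    region_index: int  # intron ordinal in transcription order; 0 otherwise
    start: int
    end: int
    orientation: str  # + | -
    matched_seq: str

    def __post_init__(self) -> None:
        if self.region not in {"promoter", "intron", "cds"}:
            raise ValueError(f"unknown region class {self.region!r}")
        if self.orientation not in {"+", "-"}:
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if abs(self.start - self.end) + 1 != len(self.matched_seq):
            raise ValueError("coordinate span disagrees with matched_seq length")
        if (self.orientation == "-") != (self.start > self.end):
            raise ValueError("descending coordinates iff minus orientation")


class CoexpressionNetwork:
    """Undirected Pearson co-expression graph at a fixed threshold.

    Nodes are genes with at least one retained edge; edge attribute
    ``weight`` is the Pearson r.
    """

    def __init__(self, graph: nx.Graph, threshold: float) -> None:
        for u, v, d in graph.edges(data=True):
            if u == v:
                raise ValueError("self-edge in co-expression network")
            if "weight" not in d:
                raise ValueError("edge missing weight")
        self.graph = graph
        self.threshold = float(threshold)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str, float]]:
        return {
            (min(u, v), max(u, v), float(d["weight"]))
            for u, v, d in self.graph.edges(data=True)
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoexpressionNetwork):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and {(u, v): round(w, 9) for u, v, w in self.edges}
            == {(u, v): round(w, 9) for u, v, w in other.edges}
        )
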