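"""Readers and writers for every external representation the pipeline touches.

Formats: FASTA, GFF3 (TAIR dialect), OBO subset (is_a only), and a family of
UTF-8 tab-delimited tables ("." for missing values). Genomic coordinates are
1-based inclusive internally; the BED-like motif-hit output is written
0-based half-open. Every writer/reader pair round-trips.
"""

from __future__ import annotations

import logging
import math
import os
from typing import Iterable, Mapping, Sequence

import gffutils
import obonet
import pandas as pd
from Bio import SeqIO

from .model import (
    CompendiumMatrix,
    CoexpressionNetwork,
    DiffRecord,
    DiffTable,
    GeneModel,
    MotifHit,
    OntologyDag,
)

import networkx as nx

logger = logging.getLogger(__name__)

# Canonical field -> accepted header names. First entry is what our own
# writer emits; the rest cover Cuffdiff's gene_exp.diff vocabulary.
_DIFF_COLUMNS: dict[str, tuple[str, ...]] = {
    "gene_id": ("gene_id", "test_id", "tracking_id"),
    "annotation": ("annotation", "gene"),
    "rpkm_rh": ("rpkm_rh", "value_1"),
    "rpkm_nrh": ("rpkm_nrh", "value_2"),
    "q_value": ("q_value",),
    "status": ("status",),
}
_OPTIONAL_DIFF_FIELDS = {"annotation", "status"}


def _parse_float(cell: str, what: str) -> float:
    try:
        return float(cell)
    except (TypeError, ValueError):
        raise ValueError(f"malformed numeric cell {cell!r} in column {what}") from None


def read_diff_table(
    path: str | os.PathLike,
    columns: Mapping[str, str] | None = None,
    condition_names: tuple[str, str] = ("RH", "NRH"),
) -> DiffTable:
    """Read a Cuffdiff-style per-gene differential-expression table.

    ``columns`` optionally maps canonical field names (gene_id, annotation,
    rpkm_rh, rpkm_nrh, q_value, status) to the header names actually present.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    header = list(df.columns)
    resolved: dict[str, str | None] = {}
    for field, candidates in _DIFF_COLUMNS.items():
        if columns and field in columns:
            name = columns[field]
            if name not in header:
                raise ValueError(f"missing required column: {name}")
            resolved[field] = name
            continue
        name = next((c for c in candidates if c in header), None)
        if name is None and field not in _OPTIONAL_DIFF_FIELDS:
            raise ValueError(f"missing required column: {field}")
        resolved[field] = name

    rows = []
    for _, raw in df.iterrows():
        rows.append(
            DiffRecord(
                gene_id=raw[resolved["gene_id"]],
                annotation=raw[resolved["annotation"]] if resolved["annotation"] else "",
                rpkm_rh=_parse_float(raw[resolved["rpkm_rh"]], "rpkm_rh"),
                rpkm_nrh=_parse_float(raw[resolved["rpkm_nrh"]], "rpkm_nrh"),
                q_value=_parse_float(raw[resolved["q_value"]], "q_value"),
                status=raw[resolved["status"]] if resolved["status"] else "OK",
            )
        )
    return DiffTable(rows, condition_names)


def write_diff_table(table: DiffTable, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tannotation\trpkm_rh\trpkm_nrh\tq_value\tstatus\n")
        for r in table:
            fh.write(
                f"{r.gene_id}\t{r.annotation}\t{r.rpkm_rh!r}\t{r.rpkm_nrh!r}"
                f"\t{r.q_value!r}\t{r.status}\n"
            )


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """FASTA -> {chrom: uppercase sequence}, record order preserved."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA header: {rec.id}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features into one GeneModel per mRNA."""
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA", order_by="start"):
        parents = mrna.attributes.get("Parent", [])
        gene_id = parents[0] if parents else mrna.id
        exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
        models.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=mrna.id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                cds_segments=cds,
            )
        )
    return models


def write_gff3(models: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """TAIR-dialect GFF3 with gene, mRNA, exon and CDS features."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            s, e = m.span
            fh.write(
                f"{m.chrom}\troothair\tgene\t{s}\t{e}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            fh.write(
                f"{m.chrom}\troothair\tmRNA\t{s}\t{e}\t.\t{m.strand}\t.\t"
                f"ID={m.transcript_id};Parent={m.gene_id}\n"
            )
            for a, b in m.exons:
                fh.write(
                    f"{m.chrom}\troothair\texon\t{a}\t{b}\t.\t{m.strand}\t.\t"
                    f"Parent={m.transcript_id}\n"
                )
            for a, b in m.cds_segments:
                fh.write(
                    f"{m.chrom}\troothair\tCDS\t{a}\t{b}\t.\t{m.strand}\t0\t"
                    f"Parent={m.transcript_id}\n"
                )


def read_compendium(path: str | os.PathLike) -> CompendiumMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CompendiumMatrix(df)


def write_compendium(matrix: CompendiumMatrix, path: str | os.PathLike) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")


# ---------------------------------------------------------------------------
# OBO ontology + annotations


def read_obo(path: str | os.PathLike) -> OntologyDag:
    """Load an OBO subset; only is_a edges are kept (others logged)."""
    g = obonet.read_obo(str(path))
    terms = {t: data.get("name", t) for t, data in g.nodes(data=True)}
    edges = []
    for child, parent, key in g.edges(keys=True):
        if key == "is_a":
            edges.append((child, parent))
        else:
            logger.warning("ignoring non-is_a relation %s -[%s]-> %s", child, key, parent)
    return OntologyDag(terms, edges)


def write_obo(dag: OntologyDag, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: roothair-synthetic\n")
        for term in dag.terms:
            fh.write(f"\n[Term]\nid: {term}\nname: {dag.names[term]}\n")
            for parent in sorted(dag.graph.successors(term)):
                fh.write(f"is_a: {parent} ! {dag.names[parent]}\n")


def read_annotations(path: str | os.PathLike) -> dict[str, set[str]]:
    """Two-column gene<TAB>term table -> gene -> set of terms."""
    ann: dict[str, set[str]] = {}
    df = pd.read_csv(path, sep="\t", dtype=str)
    for gene, term in zip(df["gene"], df["term"]):
        ann.setdefault(gene, set()).add(term)
    return ann


def write_annotations(annotations: Mapping[str, Iterable[str]], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tterm\n")
        for gene in sorted(annotations):
            for term in sorted(annotations[gene]):
                fh.write(f"{gene}\t{term}\n")


def load_ontology(obo_path: str | os.PathLike, annot_path: str | os.PathLike) -> OntologyDag:
    """OBO + annotation table, with annotations closed under the true-path rule."""
    dag = read_obo(obo_path)
    dag.annotations = {g: set(ts) for g, ts in read_annotations(annot_path).items()}
    for g, ts in dag.annotations.items():
        unknown = ts - set(dag.names)
        if unknown:
            raise ValueError(f"gene {g} annotated to unknown terms {sorted(unknown)}")
    dag.propagate_annotations()
    return dag


# ---------------------------------------------------------------------------
# Motif hits (BED-like: 0-based half-open on disk)

_HITS_HEADER = "gene_id\tregion\tregion_index\tbed_start\tbed_end\torientation\tmatched_seq"


def write_hits(hits: Sequence[MotifHit], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_HITS_HEADER + "\n")
        for h in hits:
            lo, hi = min(h.start, h.end), max(h.start, h.end)
            fh.write(
                f"{h.gene_id}\t{h.region}\t{h.region_index}\t{lo - 1}\t{hi}\t"
                f"{h.orientation}\t{h.matched_seq}\n"
            )


def read_hits(path: str | os.PathLike) -> list[MotifHit]:
    out: list[MotifHit] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header != _HITS_HEADER:
            raise ValueError(f"unexpected hits header: {header!r}")
        for line in fh:
            gene, region, idx, b0, b1, orient, seq = line.rstrip("\n").split("\t")
            lo, hi = int(b0) + 1, int(b1)
            start, end = (lo, hi) if orient == "+" else (hi, lo)
            out.append(MotifHit(gene, region, int(idx), start, end, orient, seq))
    return out


# ---------------------------------------------------------------------------
# Networks (edge-list TSV + node-attribute TSV)


def write_network(
    network: CoexpressionNetwork,
    edge_path: str | os.PathLike,
    node_path: str | os.PathLike | None = None,
) -> None:
    if node_path is None:
        node_path = str(edge_path) + ".nodes"
    with open(edge_path, "w", encoding="utf-8") as fh:
        fh.write(f"# threshold={network.threshold!r}\n")
        fh.write("gene_a\tgene_b\tweight\n")
        for u, v, w in sorted(network.edges):
            fh.write(f"{u}\t{v}\t{w!r}\n")
    with open(node_path, "w", encoding="utf-8") as fh:
        fh.write("gene\tdegree\n")
        for n in sorted(network.graph.nodes):
            fh.write(f"{n}\t{network.graph.degree(n)}\n")


def read_network(edge_path: str | os.PathLike) -> CoexpressionNetwork:
    g = nx.Graph()
    with open(edge_path, encoding="utf-8") as fh:
        first = fh.readline().strip()
        if not first.startswith("# threshold="):
            raise ValueError("edge list missing threshold header line")
        threshold = float(first.split("=", 1)[1])
        fh.readline()  # column header
        for line in fh:
            u, v, w = line.rstrip("\n").split("\t")
            g.add_edge(u, v, weight=float(w))
    return CoexpressionNetwork(g, threshold)


# ---------------------------------------------------------------------------
# Enrichment tables


def write_enrichment(results: Sequence, path: str | os.PathLike) -> None:
    """Write EnrichmentResult rows sorted ascending by p (elim if present)."""

    def sort_key(r):
        p = r.p_elim if r.p_elim is not None else r.p_classic
        return (p, r.term)

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term\tname\tstudy_hit\tstudy_size\tpop_hit\tpop_size\tp_classic\tp_elim\n")
        for r in sorted(results, key=sort_key):
            p_elim = "." if r.p_elim is None else repr(r.p_elim)
            fh.write(
                f"{r.term}\t{r.name}\t{r.study_hit}\t{r.study_size}\t{r.pop_hit}\t"
                f"{r.pop_size}\t{r.p_classic!r}\t{p_elim}\n"
            )


def read_enrichment(path: str | os.PathLike) -> list:
    from .go_enrichment import EnrichmentResult

    out = []
    df = pd.read_csv(path, sep="\t", dtype=str)
    for _, row in df.iterrows():
        out.append(
            EnrichmentResult(
                term=row["term"],
                name=row["name"],
                study_hit=int(row["study_hit"]),
                study_size=int(row["study_size"]),
                pop_hit=int(row["pop_hit"]),
                pop_size=int(row["pop_size"]),
                p_classic=float(row["p_classic"]),
                p_elim=None if row["p_elim"] == "." else float(row["p_elim"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Plain gene sets


def read_gene_set(path: str | os.PathLike) -> set[str]:
    with open(path, encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gene_set(genes: Iterable[str], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")
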