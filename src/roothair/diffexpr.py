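"""Differential-expression metrics and filtering rules.

The three-predicate filter mirrors the Cuffdiff-downstream selection used for
root-hair (RH) vs non-root-hair (NRH) comparisons: q-value below 0.05, fold
change above two-fold, and RPKM above one in at least one condition — all
strict inequalities. Fold changes follow the NRH/RH ratio convention, so
RH-enriched genes carry negative log2 fold changes and genes silent in NRH
map to -inf.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .model import CompendiumMatrix, DiffTable, GeneModel, _log2_ratio


@dataclass(frozen=True)
class DeCriteria:
    """Thresholds of the differential-expression filter (all strict)."""

    q_max: float = 0.05
    min_fold: float = 2.0
    min_rpkm_either: float = 1.0
    require_status_ok: bool = True

    def __post_init__(self) -> None:
        if self.q_max <= 0 or self.min_fold <= 0 or self.min_rpkm_either <= 0:
            raise ValueError("DE criteria must be positive")


def compute_rpkm(read_count: int, gene_length_bp: int, total_mapped_reads: int) -> float:
    """Reads Per Kilobase of transcript per Million mapped reads.

    RPKM = 10^9 * C / (L * N) for C reads on a gene of L bp in a library of
    N mapped reads.
    """
    if gene_length_bp <= 0:
        raise ValueError("gene length must be positive")
    if total_mapped_reads <= 0:
        raise ValueError("library size must be positive")
    if read_count < 0:
        raise ValueError("read count must be non-negative")
    return 1e9 * read_count / (gene_length_bp * total_mapped_reads)


def log2_fold_change(rpkm_rh: float, rpkm_nrh: float) -> float:
    """log2(RPKM_NRH / RPKM_RH); +inf if RH is 0, -inf if NRH is 0."""
    return _log2_ratio(rpkm_rh, rpkm_nrh)


def _passes(record, criteria: DeCriteria) -> bool:
    if criteria.require_status_ok and record.status != "OK":
        return False
    if not (record.q_value < criteria.q_max):
        return False
    lfc = record.log2fc
    if not (abs(lfc) > math.log2(criteria.min_fold)):  # inf passes
        return False
    return max(record.rpkm_rh, record.rpkm_nrh) > criteria.min_rpkm_either


def filter_de(table: DiffTable, criteria: DeCriteria | None = None) -> dict[str, set[str]]:
    """Partition genes passing the three-predicate filter by direction.

    Returns ``{"up_in_rh": ..., "up_in_nrh": ...}``; negative log2(NRH/RH)
    means higher in root hairs.
    """
    criteria = criteria or DeCriteria()
    up_in_rh: set[str] = set()
    up_in_nrh: set[str] = set()
    for rec in table:
        if not _passes(rec, criteria):
            continue
        if rec.log2fc < 0:
            up_in_rh.add(rec.gene_id)
        else:
            up_in_nrh.add(rec.gene_id)
    return {"up_in_rh": up_in_rh, "up_in_nrh": up_in_nrh}


def rh_only_genes(table: DiffTable, min_rpkm: float = 1.0) -> set[str]:
    """Genes detected only in root hairs: RPKM_NRH exactly 0, RPKM_RH >= min."""
    return {
        r.gene_id for r in table if r.rpkm_nrh == 0.0 and r.rpkm_rh >= min_rpkm
    }


def overlap_stats(set_a: Iterable[str], set_b: Iterable[str]) -> dict[str, float | int | None]:
    """Overlap counts plus integer percentages (round half away from zero)."""
    a, b = set(set_a), set(set_b)
    n_overlap = len(a & b)

    def pct(num: int, den: int) -> int | None:
        if den == 0:
            return None
        return int(math.floor(100.0 * num / den + 0.5))

    return {
        "n_a": len(a),
        "n_b": len(b),
        "n_overlap": n_overlap,
        "pct_of_a": pct(n_overlap, len(a)),
        "pct_of_b": pct(n_overlap, len(b)),
    }


def flag_novel_loci(
    merged_models: Sequence[GeneModel], reference_models: Sequence[GeneModel]
) -> set[str]:
    """Gene ids of merged loci overlapping no reference gene span.

    Strand-agnostic any-overlap rule on exonic spans, per chromosome; a
    single shared base already disqualifies a locus from being novel.
    """
    ref_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for m in reference_models:
        ref_by_chrom.setdefault(m.chrom, []).append(m.span)
    for spans in ref_by_chrom.values():
        spans.sort()
    novel: set[str] = set()
    for m in merged_models:
        s, e = m.span
        spans = ref_by_chrom.get(m.chrom, [])
        if not any(a <= e and s <= b for a, b in spans):
            novel.add(m.gene_id)
    return novel


def cluster_expression_patterns(
    genes: Iterable[str], matrix: CompendiumMatrix, k: int
) -> dict[str, int]:
    """Group genes by expression pattern across the compendium arrays.

    Hierarchical agglomeration with distance 1 - Pearson r and average
    linkage, cut into k groups. Constant-expression genes cannot enter the
    correlation distance and are dropped with a warning.
    """
    genes = sorted(set(genes))
    sub = matrix.submatrix(genes)
    variances = sub.var(axis=1, ddof=0)
    constant = list(variances.index[variances == 0.0])
    if constant:
        warnings.warn(
            f"excluding {len(constant)} constant-expression gene(s) from clustering",
            stacklevel=2,
        )
        sub = sub.drop(index=constant)
    kept = list(sub.index)
    if k > len(kept):
        raise ValueError(f"k={k} exceeds the {len(kept)} clusterable genes")
    if k == len(kept):
        return {g: i + 1 for i, g in enumerate(kept)}
    dist = pdist(sub.to_numpy(), metric="correlation")  # 1 - Pearson r
    dist = np.clip(dist, 0.0, None)  # guard tiny negative rounding
    labels = fcluster(linkage(dist, method="average"), t=k, criterion="maxclust")
    return {g: int(lbl) for g, lbl in zip(kept, labels)}
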