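"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emulates one of the study's inputs at desk scale: a
Cuffdiff-style differential table with a planted DE fraction and root-hair-
only genes, a root-array expression compendium with latent-factor co-
expression modules, a genome + gene models with Root Hair Regulatory
Element (RHE) instances planted at recorded positions, and a small GO-style
DAG with one planted enriched term. A single global seed fans out to
per-generator child seeds by fixed offsets, so each stage is reproducible
on its own.

What the generators emulate — and what they do not — is discussed in
docs/methods.md; in brief, abundances are log-normal (median 3 RPKM,
sigma 1.5 in natural log units, spanning roughly 0.01-5000 RPKM like real
root-hair data), q-values are drawn consistently with the truth labels
rather than computed from counts, and array intensities are Gaussian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import CompendiumMatrix, DiffRecord, DiffTable, GeneModel, MotifHit, OntologyDag
from .motif_scan import (
    IUPAC_CODES,
    RHE_CONSENSUS,
    IupacConsensus,
    parse_consensus,
    revcomp,
    scan_region,
)

# fixed per-generator seed offsets (global seed + offset, kept below 2^31)
_OFF_DIFF = 101
_OFF_COMPENDIUM = 202
_OFF_GENOME = 303
_OFF_GO = 404


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic study; defaults are the standing conditions."""

    seed: int = 0
    n_genes: int = 5000
    de_fraction: float = 0.2
    effect_log2_range: tuple[float, float] = (1.2, 8.0)
    rh_only_count: int = 61
    n_arrays: int = 300
    module_specs: tuple[tuple[int, float], ...] = ((20, 0.95), (9, 0.95))
    noise_sd: float = 1.0
    genome_len: int = 60_000
    n_gene_models: int = 4
    n_planted_motifs: tuple[int, int, int] = (1, 1, 1)  # promoter, intron, cds
    dag_terms: int = 50
    enriched_term_fold: float = 5.0
    enriched_term_size: int = 30
    consensus: str = RHE_CONSENSUS

    def __post_init__(self) -> None:
        if self.n_genes < 0 or self.rh_only_count < 0 or self.n_arrays < 0:
            raise ValueError("counts must be non-negative")
        if not (0.0 <= self.de_fraction <= 1.0):
            raise ValueError("de_fraction must be in [0,1]")
        for _, strength in self.module_specs:
            if not (0.0 <= strength <= 1.0):
                raise ValueError("latent_strength must be in [0,1]")
        if self.effect_log2_range[0] < 1.0:
            raise ValueError("planted effects must be at least 1 log2 unit")

    def rng(self, offset: int) -> np.random.Generator:
        return np.random.default_rng((self.seed + offset) % (2**31))


@dataclass
class TruthSet:
    """Planted ground truth; only the fields a given generator fills."""

    de_genes: dict[str, float] = field(default_factory=dict)  # signed log2 effect
    rh_only_genes: set[str] = field(default_factory=set)
    planted_hits: list[MotifHit] = field(default_factory=list)
    true_modules: list[set[str]] = field(default_factory=list)
    enriched_terms: set[str] = field(default_factory=set)


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# Differential table


def gen_diff_table(config: SyntheticConfig) -> tuple[DiffTable, TruthSet]:
    """Cuffdiff-style table with planted DE genes and RH-only genes.

    Non-DE genes sit within one log2 unit of parity with q >= 0.05; DE genes
    carry effects drawn from ``effect_log2_range`` (both signs), q < 0.05
    and at least one condition above 1 RPKM. RH-only genes are the planted
    DE genes with RPKM_NRH exactly 0.
    """
    rng = config.rng(_OFF_DIFF)
    n_de = int(round(config.de_fraction * config.n_genes))
    if n_de < config.rh_only_count:
        raise ValueError(
            f"rh_only_count={config.rh_only_count} exceeds planted DE count {n_de}"
        )
    genes = _gene_ids(config.n_genes)
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    de_set = [genes[i] for i in sorted(de_idx)]
    rh_only = set(de_set[: config.rh_only_count])

    truth = TruthSet()
    lo, hi = config.effect_log2_range
    rows: list[DiffRecord] = []
    de_lookup = set(de_set)
    for g in genes:
        base = float(rng.lognormal(mean=math.log(3.0), sigma=1.5))
        if g in rh_only:
            rpkm_rh = max(base, 1.5)
            rpkm_nrh = 0.0
            q = float(rng.uniform(0.0, 0.05))
            truth.de_genes[g] = -math.inf
            truth.rh_only_genes.add(g)
        elif g in de_lookup:
            base = max(base, 1.2)
            effect = float(rng.uniform(lo, hi)) * (1.0 if rng.random() < 0.5 else -1.0)
            rpkm_rh = base
            rpkm_nrh = base * 2.0**effect
            q = float(rng.uniform(0.0, 0.05))
            truth.de_genes[g] = effect
        else:
            delta = float(rng.uniform(-0.95, 0.95))
            rpkm_rh = base
            rpkm_nrh = base * 2.0**delta
            q = float(rng.uniform(0.05, 1.0))
        rows.append(
            DiffRecord(
                gene_id=g,
                annotation="synthetic gene",
                rpkm_rh=rpkm_rh,
                rpkm_nrh=rpkm_nrh,
                q_value=q,
                status="OK",
            )
        )
    return DiffTable(rows), truth


# ---------------------------------------------------------------------------
# Expression compendium


def gen_compendium(
    config: SyntheticConfig, genes: Sequence[str] | None = None
) -> tuple[CompendiumMatrix, TruthSet]:
    """Gene x array matrix with latent-factor co-expression modules.

    Module members follow x = s*z + sqrt(1 - s^2)*eps with a shared
    standard-normal latent z per array and independent standard-normal eps,
    giving expected pairwise Pearson r of s^2. Background genes are
    independent noise of scale ``noise_sd``.
    """
    rng = config.rng(_OFF_COMPENDIUM)
    if genes is None:
        genes = _gene_ids(config.n_genes)
    genes = list(genes)
    sizes = [size for size, _ in config.module_specs]
    if sum(sizes) > len(genes):
        raise ValueError(
            f"module sizes sum to {sum(sizes)} but only {len(genes)} genes available"
        )
    member_idx = rng.choice(len(genes), size=sum(sizes), replace=False)
    truth = TruthSet()
    values = rng.normal(0.0, config.noise_sd, size=(len(genes), config.n_arrays))
    cursor = 0
    for size, strength in config.module_specs:
        idx = member_idx[cursor : cursor + size]
        cursor += size
        z = rng.normal(0.0, 1.0, size=config.n_arrays)
        eps = rng.normal(0.0, 1.0, size=(size, config.n_arrays))
        values[idx, :] = strength * z + math.sqrt(1.0 - strength**2) * eps
        truth.true_modules.append({genes[i] for i in idx})
    arrays = [f"A{j:04d}" for j in range(1, config.n_arrays + 1)]
    df = pd.DataFrame(values, index=genes, columns=arrays)
    return CompendiumMatrix(df), truth


# ---------------------------------------------------------------------------
# Genome with planted RHE instances

_EXON_LENS = (500, 400, 450)
_INTRON_LENS = (300, 350)
_SPACER = 500
_PROMOTER = 3000


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _clean_seq(rng: np.random.Generator, n: int, consensus: IupacConsensus) -> str:
    """Random sequence guaranteed free of consensus matches."""
    for _ in range(200):
        seq = _random_seq(rng, n)
        if not scan_region(seq, consensus):
            return seq
    raise RuntimeError("could not draw a motif-free background sequence")


def _realize(rng: np.random.Generator, consensus: IupacConsensus, length: int) -> str:
    letters = consensus.letters(length)
    return "".join(
        sorted(IUPAC_CODES[c])[rng.integers(0, len(IUPAC_CODES[c]))] for c in letters
    )


def _plant(
    rng: np.random.Generator,
    seq: str,
    count: int,
    consensus: IupacConsensus,
    windows: list[tuple[int, int]] | None = None,
) -> tuple[str, list[tuple[int, int, str, str]]]:
    """Plant ``count`` motif instances into ``seq`` at recorded positions.

    ``windows`` (0-based half-open) restricts eligible placements, used to
    keep spliced-CDS plantings inside a single exon. Returns the edited
    sequence and (start, end, orientation, matched_seq) records with the
    1-based local convention (start > end for minus orientation). Retries
    until re-scanning yields exactly the planted hits.
    """
    if count == 0:
        return seq, []
    max_len = max(consensus.expanded_lengths)
    if windows is None:
        windows = [(0, len(seq))]
    for _ in range(200):
        taken: list[tuple[int, int]] = []
        records: list[tuple[int, int, str, str]] = []
        chars = list(seq)
        ok = True
        for _k in range(count):
            placed = False
            for _try in range(200):
                w0, w1 = windows[rng.integers(0, len(windows))]
                if w1 - w0 < max_len:
                    continue
                length = int(rng.choice(sorted(consensus.expanded_lengths)))
                off = int(rng.integers(w0, w1 - length + 1))
                if any(off < t1 + 2 and t0 < off + length + 2 for t0, t1 in taken):
                    continue  # keep plantings separated
                motif = _realize(rng, consensus, length)
                orient = "+" if rng.random() < 0.5 else "-"
                text = motif if orient == "+" else revcomp(motif)
                chars[off : off + length] = list(text)
                taken.append((off, off + length))
                # matched_seq convention: the region-strand text as embedded
                if orient == "+":
                    records.append((off + 1, off + length, "+", text))
                else:
                    records.append((off + length, off + 1, "-", text))
                placed = True
                break
            if not placed:
                ok = False
                break
        if not ok:
            continue
        planted_seq = "".join(chars)
        found = {
            (h.start, h.end, h.orientation, h.matched_seq)
            for h in scan_region(planted_seq, consensus)
        }
        if found == set(records):
            return planted_seq, sorted(records)
    raise RuntimeError("could not plant motifs without spurious matches")


def gen_genome_with_motifs(
    config: SyntheticConfig,
) -> tuple[dict[str, str], list[GeneModel], TruthSet]:
    """Genome + gene models with RHE instances planted in known regions.

    Each gene model has three exons (CDS spanning all exonic bases) and two
    introns, a motif-free 3000-bp promoter window upstream of the start
    codon, and ``n_planted_motifs`` = (promoter, intron, cds) planted
    instances per gene; strands alternate. Background sequence is rejection
    sampled so the only matches in scanned regions are the planted ones.
    """
    rng = config.rng(_OFF_GENOME)
    consensus = parse_consensus(config.consensus)
    n_genes = config.n_gene_models
    gene_len = sum(_EXON_LENS) + sum(_INTRON_LENS)
    needed = _SPACER + n_genes * (_PROMOTER + gene_len + _SPACER)
    if config.genome_len < needed:
        raise ValueError(
            f"genome_len={config.genome_len} too short for {n_genes} gene models "
            f"(need >= {needed})"
        )
    n_prom, n_intron, n_cds = config.n_planted_motifs
    truth = TruthSet()
    models: list[GeneModel] = []
    chrom_parts: list[str] = [_random_seq(rng, _SPACER)]
    cursor = _SPACER  # 0-based genomic offset of the next contig

    # spliced-CDS coordinates of each exon (0-based half-open windows)
    cds_windows = []
    acc = 0
    for el in _EXON_LENS:
        cds_windows.append((acc, acc + el))
        acc += el

    for gi in range(n_genes):
        gene_id = f"G{gi + 1:05d}"
        strand = "+" if gi % 2 == 0 else "-"
        promoter, prom_rec = _plant(
            rng, _clean_seq(rng, _PROMOTER, consensus), n_prom, consensus
        )
        introns = [_clean_seq(rng, il, consensus) for il in _INTRON_LENS]
        per_intron = [0] * len(introns)
        for k in range(n_intron):
            per_intron[k % len(introns)] += 1
        intron_recs: list[list[tuple[int, int, str, str]]] = []
        for which, cnt in enumerate(per_intron):
            introns[which], recs = _plant(rng, introns[which], cnt, consensus)
            intron_recs.append(recs)
        spliced, cds_rec = _plant(
            rng,
            "".join(
                _clean_seq(rng, el, consensus) for el in _EXON_LENS
            ),
            n_cds,
            consensus,
            windows=cds_windows,
        )
        exon_seqs = [spliced[a:b] for a, b in cds_windows]

        # contig in coding orientation: promoter, then exons/introns
        contig = promoter
        exon_local: list[tuple[int, int]] = []  # 1-based within contig
        pos = len(promoter)
        for j, es in enumerate(exon_seqs):
            exon_local.append((pos + 1, pos + len(es)))
            contig += es
            pos += len(es)
            if j < len(introns):
                contig += introns[j]
                pos += len(introns[j])
        clen = len(contig)
        g0 = cursor  # 0-based genomic start of contig
        if strand == "+":
            chrom_parts.append(contig)
            exons = [(g0 + a, g0 + b) for a, b in exon_local]
        else:
            chrom_parts.append(revcomp(contig))
            # contig coordinate t (1-based) -> genomic g0 + clen - t + 1
            exons = sorted((g0 + clen - b + 1, g0 + clen - a + 1) for a, b in exon_local)
        cursor += clen
        chrom_parts.append(_random_seq(rng, _SPACER))
        cursor += _SPACER
        models.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=gene_id + ".1",
                chrom="chr1",
                strand=strand,
                exons=exons,
                cds_segments=exons,
            )
        )
        for s, e, o, m in prom_rec:
            truth.planted_hits.append(MotifHit(gene_id, "promoter", 0, s, e, o, m))
        for widx, recs in enumerate(intron_recs, start=1):
            for s, e, o, m in recs:
                truth.planted_hits.append(MotifHit(gene_id, "intron", widx, s, e, o, m))
        for s, e, o, m in cds_rec:
            truth.planted_hits.append(MotifHit(gene_id, "cds", 0, s, e, o, m))

    if cursor < config.genome_len:
        chrom_parts.append(_random_seq(rng, config.genome_len - cursor))
    genome = {"chr1": "".join(chrom_parts)}
    return genome, models, truth


# ---------------------------------------------------------------------------
# Ontology


def gen_go(
    config: SyntheticConfig,
    study_genes: Sequence[str],
    population: Sequence[str],
) -> tuple[OntologyDag, TruthSet]:
    """Random is_a DAG with one term enriched in ``study_genes``.

    Every non-root term gets 1-2 parents among earlier (shallower) terms;
    leaf terms receive random gene annotations which are then propagated to
    ancestors (true-path rule). One designated leaf overlaps the study set
    ``enriched_term_fold``-fold above the null expectation.
    """
    rng = config.rng(_OFF_GO)
    study = list(dict.fromkeys(study_genes))
    pop = list(dict.fromkeys(population))
    if not set(study) <= set(pop):
        raise ValueError("study genes must be a subset of the population")
    n_terms = config.dag_terms
    if n_terms < 1:
        raise ValueError("need at least one term")
    term_ids = [f"T{i:04d}" for i in range(n_terms)]
    names = {t: ("root" if i == 0 else f"synthetic process {i}") for i, t in enumerate(term_ids)}
    edges: list[tuple[str, str]] = []
    for i in range(1, n_terms):
        n_par = 1 + int(rng.random() < 0.4)
        parents = rng.choice(i, size=min(n_par, i), replace=False)
        for p in parents:
            edges.append((term_ids[i], term_ids[int(p)]))

    truth = TruthSet()
    annotations: dict[str, set[str]] = {}

    def annotate(term: str, genes: Sequence[str]) -> None:
        for g in genes:
            annotations.setdefault(g, set()).add(term)

    if n_terms == 1:
        annotate(term_ids[0], pop)
        dag = OntologyDag(names, edges, annotations)
        dag.propagate_annotations()
        return dag, truth

    parents = {p for _, p in edges}
    leaves = [t for t in term_ids[1:] if t not in parents] or [term_ids[-1]]
    planted = leaves[int(rng.integers(0, len(leaves)))]

    N, M = len(pop), len(study)
    K = min(config.enriched_term_size, max(2, N // 2))
    x = int(round(config.enriched_term_fold * K * M / N))
    if x < 1 or x > min(K, M) or (K - x) > (N - M):
        raise ValueError(
            f"planted enrichment impossible: fold={config.enriched_term_fold}, "
            f"K={K}, study={M}, population={N} gives x={x}"
        )
    study_arr = np.array(study)
    non_study = np.array(sorted(set(pop) - set(study)))
    picked = list(study_arr[rng.choice(M, size=x, replace=False)])
    picked += list(non_study[rng.choice(len(non_study), size=K - x, replace=False)])
    annotate(planted, picked)
    truth.enriched_terms = {planted}

    pop_arr = np.array(pop)
    for leaf in leaves:
        if leaf == planted:
            continue
        size = int(rng.integers(5, min(31, N + 1)))
        annotate(leaf, list(pop_arr[rng.choice(N, size=size, replace=False)]))

    dag = OntologyDag(names, edges, annotations)
    dag.propagate_annotations()
    return dag, truth


# ---------------------------------------------------------------------------
# Whole-study orchestration


@dataclass
class SyntheticDataset:
    diff_table: DiffTable
    compendium: CompendiumMatrix
    genome: dict[str, str]
    gene_models: list[GeneModel]
    ontology: OntologyDag
    truth: TruthSet


def gen_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """All pipeline inputs wired together on shared gene ids.

    The compendium covers the planted RH-up-regulated genes (modules drawn
    from them), the ontology population is the planted DE set, and the study
    set of the planted enriched term is the union of true modules — so the
    DE filter, network, module and enrichment stages can each recover their
    piece of the truth.
    """
    diff, truth = gen_diff_table(config)
    up_in_rh = sorted(g for g, e in truth.de_genes.items() if e < 0)
    comp_cfg = config
    compendium, comp_truth = gen_compendium(comp_cfg, genes=up_in_rh)
    truth.true_modules = comp_truth.true_modules
    genome, models, motif_truth = gen_genome_with_motifs(config)
    truth.planted_hits = motif_truth.planted_hits
    module_union = sorted(set().union(*truth.true_modules)) if truth.true_modules else []
    dag, go_truth = gen_go(config, module_union, sorted(truth.de_genes))
    truth.enriched_terms = go_truth.enriched_terms
    return SyntheticDataset(
        diff_table=diff,
        compendium=compendium,
        genome=genome,
        gene_models=models,
        ontology=dag,
        truth=truth,
    )
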