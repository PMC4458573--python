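"""Hypergeometric GO-term enrichment: classic and elim variants.

Classic scoring tests every term independently with the one-sided
hypergeometric upper tail. The elim variant walks the DAG from the most
specific terms upward; whenever a term is significant at ``alpha_elim`` its
annotated genes are removed from all ancestor terms before those are
tested, so generic parents are not dragged into significance by one strong
child. P-values are reported raw (no multiple-testing correction), matching
how such screens are conventionally summarized.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Iterable

from .model import OntologyDag


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    name: str
    study_hit: int  # x: study genes annotated to the term
    study_size: int  # M
    pop_hit: int  # K: population genes annotated to the term
    pop_size: int  # N
    p_classic: float
    p_elim: float | None = None


@dataclass(frozen=True)
class ElimConfig:
    """alpha_elim triggers gene removal; report_alpha only filters output."""

    alpha_elim: float = 0.01
    report_alpha: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha_elim < 1.0):
            raise ValueError("alpha_elim must be in [0, 1)")
        if not (0.0 < self.report_alpha <= 1.0):
            raise ValueError("report_alpha must be in (0, 1]")


def hypergeom_upper(x: int, M: int, K: int, N: int) -> float:
    """P[X >= x] for X ~ Hypergeometric(N, K, M), exact.

    Drawing M study genes from a population of N containing K term-annotated
    genes; integer arithmetic throughout, converted to float at the end.
    """
    if not (0 <= x <= M <= N and 0 <= K <= N):
        raise ValueError(f"impossible counts: x={x} M={M} K={K} N={N}")
    if x > min(M, K):
        raise ValueError(f"x={x} exceeds min(M={M}, K={K})")
    if x == 0:
        return 1.0
    numer = sum(comb(K, k) * comb(N - K, M - k) for k in range(x, min(M, K) + 1))
    return float(Fraction(numer, comb(N, M)))


def _check_inputs(dag: OntologyDag, study: set[str], population: set[str]) -> None:
    if not study:
        raise ValueError("empty study set")
    if not study <= population:
        raise ValueError("study set must be a subset of the population")


def classic_enrichment(
    dag: OntologyDag, study: Iterable[str], population: Iterable[str]
) -> list[EnrichmentResult]:
    """One result per term with at least one study hit, sorted by p then id.

    Annotations must already be closed under the true-path rule (loaders in
    io_formats do this).
    """
    study, population = set(study), set(population)
    _check_inputs(dag, study, population)
    term_genes = dag.genes_per_term(population)
    N, M = len(population), len(study)
    out: list[EnrichmentResult] = []
    for term in dag.terms:
        genes = term_genes[term]
        x = len(genes & study)
        if x == 0:
            continue
        p = hypergeom_upper(x, M, len(genes), N)
        out.append(
            EnrichmentResult(term, dag.names[term], x, M, len(genes), N, p_classic=p)
        )
    out.sort(key=lambda r: (r.p_classic, r.term))
    return out


def elim_enrichment(
    dag: OntologyDag,
    study: Iterable[str],
    population: Iterable[str],
    config: ElimConfig | None = None,
) -> list[EnrichmentResult]:
    """elim-style enrichment: most specific terms first, removal upward.

    Terms are processed by decreasing longest-path depth from the root (ties
    by id). A term significant at ``alpha_elim`` has its currently annotated
    genes removed from every strict ancestor before that ancestor is tested.
    Both the classic and the elim p-value are reported per term.
    """
    config = config or ElimConfig()
    study, population = set(study), set(population)
    _check_inputs(dag, study, population)
    original = dag.genes_per_term(population)
    current = {t: set(g) for t, g in original.items()}
    depths = dag.depths()
    order = sorted(dag.terms, key=lambda t: (-depths[t], t))
    N, M = len(population), len(study)
    out: list[EnrichmentResult] = []
    for term in order:
        genes_now = current[term]
        x_now = len(genes_now & study)
        p_elim = hypergeom_upper(x_now, M, len(genes_now), N) if genes_now else 1.0
        x_orig = len(original[term] & study)
        if x_orig == 0 and x_now == 0:
            continue
        p_classic = hypergeom_upper(x_orig, M, len(original[term]), N)
        out.append(
            EnrichmentResult(
                term,
                dag.names[term],
                x_now,
                M,
                len(genes_now),
                N,
                p_classic=p_classic,
                p_elim=p_elim,
            )
        )
        if p_elim < config.alpha_elim:
            for anc in dag.ancestors(term):
                current[anc] -= genes_now
    out = [r for r in out if r.p_elim <= config.report_alpha]
    out.sort(key=lambda r: (r.p_elim, r.term))
    return out
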