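# Methods

This note records the models, conventions and numerical choices behind the
toolkit, and what the synthetic benchmarks do and do not demonstrate.

## Differential expression

Input is a Cuffdiff-style per-gene table: RPKM in the two conditions (RH =
root hair cells, NRH = all other root tissue), an FDR-adjusted q-value, and
a test status. RPKM is `1e9 * C / (L * N)` for `C` reads on a gene of `L`
bp in a library of `N` mapped reads. The fold change is
`log2(RPKM_NRH / RPKM_RH)`: RH-enriched genes are negative; when exactly
one RPKM is zero the value is ±infinity (a gene silent in NRH is `-inf`),
and both-zero is undefined and rejected.

The DE filter applies three predicates, all **strict** inequalities per the
wording they implement ("less than", "greater than", "more than"):
`q < 0.05`, fold change `> 2` (i.e. `|log2fc| > 1`, with ±inf passing), and
`max(RPKM_RH, RPKM_NRH) > 1`. Records whose Cuffdiff status is not `OK`
are excluded by default (`DeCriteria.require_status_ok`); whether the
original screens did this is not documented, so it is a configurable
choice. The sign of the fold change partitions DE genes into `up_in_rh`
(negative) and `up_in_nrh`. "RH-only" genes are defined by
`RPKM_NRH == 0.0` exactly — consistent with the `inf` fold-change
convention — plus an `RPKM_RH >= 1` guard mirroring the abundance rule.

Overlap percentages are rounded to the nearest integer, half away from
zero. Published roundings of such ratios are internally inconsistent
(77.86% appears as "seventy-seven percent" while 76.72% appears as "77%"),
so the convention here is the package's own and is applied uniformly.

Novel-locus flagging declares a merged locus novel when its exonic span
overlaps no reference gene span on the same chromosome (strand-agnostic,
any-overlap: one shared base disqualifies). Expression-pattern clustering
uses hierarchical agglomeration with distance `1 − Pearson r` and average
linkage, cut to `k` groups; zero-variance genes are dropped with a warning
because correlation distance is undefined for them.

## RHE motif scanning

The consensus is a degenerate IUPAC string with at most one parenthesized
optional base; `WHHDTGNNN(N)KCACGWH` expands to a 16-mer and a 17-mer, and
both are scanned. Matching is per-position set membership; a sequence `N`
(assembly gap) matches only a consensus `N`, on the grounds that a gap is
not evidence for any base.

Regions are extracted in coding orientation: the promoter is the
`promoter_len` (default 3000) bases 5' of the **start codon** — the
translation start, not the transcription start — truncated at the
chromosome edge; each intron is scanned separately, numbered in
transcription order; the CDS is the spliced concatenation of CDS segments
in translation order, so a match straddling an exon–intron junction in
genomic space is *not* a CDS hit. Hit coordinates are 1-based and local to
the extracted region sequence.

Both strands are scanned. A minus-orientation hit is a window whose
reverse complement fits the consensus; it is reported with descending
start/end and with `matched_seq` equal to the region-strand text of the
footprint — the convention used in published hit tables, where
descending-coordinate rows print patterns that fit the consensus only
after reverse complement. Hits are unique per (orientation, leftmost
position, length); overlapping hits and both length variants are all
reported. The published tables do not state their coordinate origin;
coordinates here are window-local, so only spans and patterns, not
absolute positions, are comparable to them.

The scanner is regex-based (per-position character classes with a
lookahead for overlapping matches); tests compare it against an
independent naive per-position matcher on random sequences, and against
planted instances with recorded positions.

## Co-expression networks

Pearson correlations are computed on the compendium as loaded — it is
assumed to be normalized upstream (e.g. RMA for array compendia); no
re-normalization is applied. An edge joins two genes when `r >= t`; a gene
is a node only if it keeps at least one edge, which is why a network can
report fewer nodes than input genes. At least 3 arrays are required;
zero-variance genes never form edges.

Threshold selection sweeps a grid (default 0.70–0.90, step 0.01 — the
published procedure names only the range, so the step is a package
choice) and scores each candidate network by the number of GO terms
enriched below `sweep_alpha = 1e-3` among its nodes (classic test, node
set vs the full input set). "Best enrichment" is qualitative in the
source procedure; the count statistic is the default operationalization
and a minimum-p alternative is available behind a flag. Ties break toward
the **largest** threshold. If every network in the grid is empty the sweep
errors and advises a lower grid.

Bait–prey networks compute all edges at the threshold over baits ∪ preys,
then delete every prey–prey edge and drop isolated nodes, so every
retained prey has at least one bait neighbor. Connected components are
reported sorted by size, then smallest member id, for determinism.

## Module mining

Each node gets weight `Ci = 2n / (Ki (Ki − 1))` (its clustering
coefficient; 0 when the degree is below 2). The highest-weight unassigned
node (ties by id) seeds a module; expansion is breadth-first and a
neighbor joins when `W_j / W_seed > 0.1`; each node is visited once and
expansion sees only unassigned nodes. Assigned nodes are removed from
later seeding and expansion — a hard partition, following the
delete-after-search description of the original procedure. Modules with
fewer than 6 nodes ("node count > 5") or induced minimum degree below 2
are dropped; the minimum-degree value is not documented in the source
procedure, so 2 is a package default and configurable.

Deliberate divergence: the originally published MCODE weights nodes by
the k-core-scaled clustering coefficient and supports fluff/haircut
post-processing and a depth limit. This implementation uses `Ci` itself
as the weight, imposes no depth limit, and does no post-processing,
matching the simpler procedure it re-implements.

## GO enrichment

The test is the exact one-sided hypergeometric upper tail
`P[X >= x]` for `x` study hits among `K` term-annotated genes, study size
`M`, population `N`, computed with integer arithmetic (`math.comb`) and
converted to float once — no normal or saddlepoint approximation.
Annotations are closed under the true-path rule at load time.

The elim variant orders terms by longest-path depth from the root
(deepest first, ties by id) and, whenever a term's current p-value falls
below `alpha_elim` (default 0.01, the conventional default of the
reference implementation; the source analyses state only reporting
cutoffs), removes that term's currently annotated genes from all strict
ancestors before those are tested. Both p-values are reported per term;
`alpha_elim = 0` reduces elim to classic exactly. P-values are raw — no
multiple-testing correction — matching how these screens are reported.

## Synthetic data

One global seed fans out to fixed per-generator offsets, so each stage is
reproducible in isolation and the whole dataset is byte-stable.

- **Diff table**: baseline abundance is log-normal with median 3 RPKM and
  sigma 1.5 (natural-log units), spanning roughly 0.01–5000 RPKM — the
  dynamic range seen in real RH/NRH tables. Non-DE genes sit within one
  log2 unit of parity with `q ~ U(0.05, 1)`; DE genes (default 20% of
  genes) draw signed effects from 1.2–8 log2 units with `q ~ U(0, 0.05)`
  and a baseline floor keeping one condition above 1 RPKM; RH-only genes
  (default 61) have `RPKM_NRH = 0`. q-values are *drawn consistently with
  the truth labels*, not computed from counts — the negative-binomial test
  that produces them is upstream and out of scope — so the benchmark
  validates the filter, not the test.
- **Compendium**: module members follow `x = s·z + sqrt(1−s²)·ε` with a
  shared standard-normal latent `z` per array, giving expected pairwise
  `r = s²` (0.9025 at the default `s = 0.95`, comfortably above the 0.83
  working threshold at 300 arrays); background genes are independent
  Gaussian noise. Defaults plant modules of 20 and 9 genes, the module
  sizes of the scenario the mining stage is expected to reproduce.
- **Genome**: gene models have three exons (CDS spanning all exonic
  bases), two introns, alternating strands, and a 3000-bp motif-free
  promoter window; background region sequences are rejection-sampled to be
  consensus-free and planted RHE instances (random length variant,
  orientation and degenerate-position bases) are re-scanned so the
  recorded truth is exactly the region's hit set. CDS plantings are
  confined to single exons so spliced-scan positions are well defined.
- **Ontology**: a random DAG (each non-root term takes 1–2 parents among
  earlier terms); leaf terms get random annotations, propagated to
  ancestors; one leaf is planted to overlap the study set
  `enriched_term_fold`-fold (default 5×) above expectation. The generator
  errors when the requested fold is combinatorially impossible.

What passing these benchmarks does **not** show: recovery of
dataset-dependent published counts (5409 DE genes, 61 RH-only, 201
promoter RHE hits, specific module memberships), which depend on the real
sequencing data and the 300-array compendium; robustness to unnormalized
or heavy-tailed compendia; or calibration of q-values. Problem sizes used
by the test suite and acceptance script (5000-gene diff tables, 500-gene
compendia with 300 arrays, 4 gene models, 50-term ontologies, 100
enrichment replicates) are the package's chosen desk-scale study
conditions.

## Numerical choices and degenerate inputs

- All genomic intervals are 1-based inclusive internally (GFF3
  convention); BED-like hit output is 0-based half-open on disk.
- Strict inequalities throughout the DE filter; network edges use `>=`
  ("equal to or greater than" the threshold).
- Percentage rounding: nearest integer, half away from zero.
- Hypergeometric p-values are exact rationals converted to float.
- Correlation of a zero-variance vector is an error in `pearson`, a
  silent non-edge in matrix form, and an exclusion-with-warning in
  clustering.
- Determinism: seed ties in module mining break lexicographically;
  component and module orderings are (size, then smallest id); floats are
  serialized with `repr` so written artifacts are byte-stable.
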