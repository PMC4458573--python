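"""Degenerate IUPAC consensus scanning over gene-model regions.

Built for the Root Hair Regulatory Element (RHE) consensus
``WHHDTGNNN(N)KCACGWH`` — a 16/17-bp degenerate element with one optional N —
but any IUPAC consensus with at most one parenthesized optional base works.
Scanning covers the promoter (a fixed window upstream of the start codon on
the coding strand), each intron separately, and the spliced CDS, on both
strands. Minus-orientation hits are reported with descending start/end; the
stored pattern is the region-strand text of the footprint read 5'->3' (its
reverse complement is what fits the consensus), matching how such hits are
conventionally tabulated.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

from .model import GeneModel, MotifHit

RHE_CONSENSUS = "WHHDTGNNN(N)KCACGWH"

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_SEQ_ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _allowed(letter: str) -> frozenset[str]:
    """Sequence characters a consensus letter accepts.

    An assembled-gap 'N' in the sequence matches only a consensus 'N'
    (conservative: a gap is not evidence for any specific base).
    """
    bases = IUPAC_CODES[letter]
    return bases | {"N"} if letter == "N" else bases


@dataclass(frozen=True)
class IupacConsensus:
    """A degenerate consensus with at most one optional base."""

    raw: str
    letters_short: tuple[str, ...]
    letters_long: tuple[str, ...] | None

    @property
    def expanded_lengths(self) -> set[int]:
        lengths = {len(self.letters_short)}
        if self.letters_long is not None:
            lengths.add(len(self.letters_long))
        return lengths

    def letters(self, length: int) -> tuple[str, ...]:
        for cand in (self.letters_short, self.letters_long):
            if cand is not None and len(cand) == length:
                return cand
        raise ValueError(f"consensus {self.raw!r} has no length-{length} variant")

    def regex(self, length: int, orientation: str = "+") -> re.Pattern[str]:
        """Overlap-capable regex; "-" matches where revcomp(text) fits."""
        letters = self.letters(length)
        if orientation == "-":
            letters = tuple(c.translate(_IUPAC_COMPLEMENT) for c in reversed(letters))
        classes = "".join(f"[{''.join(sorted(_allowed(c)))}]" for c in letters)
        return re.compile(f"(?=({classes}))")  # lookahead: overlapping matches


def parse_consensus(raw: str) -> IupacConsensus:
    """Parse e.g. "WHHDTGNNN(N)KCACGWH" -> 16/17-bp consensus."""
    letters: list[str] = []
    optional_at: int | None = None
    optional_letter: str | None = None
    i = 0
    while i < len(raw):
        ch = raw[i]
        if ch == "(":
            if optional_at is not None:
                raise ValueError("at most one optional group allowed")
            j = raw.find(")", i)
            if j != i + 2 or raw[i + 1] not in IUPAC_CODES:
                raise ValueError(f"malformed optional group in {raw!r}")
            optional_at = len(letters)
            optional_letter = raw[i + 1]
            i = j + 1
            continue
        if ch == ")":
            raise ValueError(f"unbalanced parenthesis in {raw!r}")
        if ch not in IUPAC_CODES:
            raise ValueError(f"unknown IUPAC letter {ch!r} in {raw!r}")
        letters.append(ch)
        i += 1
    if not letters:
        raise ValueError("empty consensus")
    short = tuple(letters)
    long: tuple[str, ...] | None = None
    if optional_at is not None:
        long = tuple(letters[:optional_at] + [optional_letter] + letters[optional_at:])
    return IupacConsensus(raw=raw, letters_short=short, letters_long=long)


def match_at(seq: str, pos: int, consensus: IupacConsensus, length: int) -> bool:
    """True iff seq[pos : pos+length] (0-based) fits the consensus variant."""
    if pos < 0 or pos + length > len(seq):
        raise ValueError("window extends beyond sequence")
    letters = consensus.letters(length)
    return all(seq[pos + k] in _allowed(letters[k]) for k in range(length))


class RegionHit(NamedTuple):
    """A match within one region sequence (1-based local coordinates)."""

    start: int
    end: int
    orientation: str
    matched_seq: str


def scan_region(
    seq: str, consensus: IupacConsensus, both_strands: bool = True
) -> list[RegionHit]:
    """All consensus matches in one region sequence.

    Forward hits have ascending start/end. Reverse hits are windows whose
    reverse complement fits the consensus; they are reported with start >
    end and matched_seq equal to the region-strand text of the footprint
    (read 5'->3' as it sits in the region). Both length variants are
    scanned; overlapping hits are all reported, one hit per (orientation,
    leftmost position, length).
    """
    seq = seq.upper()
    bad = set(seq) - _SEQ_ALPHABET
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    n = len(seq)
    hits: list[RegionHit] = []
    for length in sorted(consensus.expanded_lengths):
        if length > n:
            continue
        for m in consensus.regex(length).finditer(seq):
            i = m.start()
            hits.append(RegionHit(i + 1, i + length, "+", m.group(1)))
        if both_strands:
            for m in consensus.regex(length, "-").finditer(seq):
                i = m.start()
                hits.append(RegionHit(i + length, i + 1, "-", m.group(1)))
    hits.sort(key=lambda h: (min(h.start, h.end), h.orientation, len(h.matched_seq)))
    return hits


@dataclass(frozen=True)
class RegionSpec:
    """Which regions to scan and how far the promoter window reaches."""

    promoter_len: int = 3000
    regions: tuple[str, ...] = ("promoter", "intron", "cds")

    def __post_init__(self) -> None:
        if self.promoter_len <= 0:
            raise ValueError("promoter_len must be positive")
        unknown = set(self.regions) - {"promoter", "intron", "cds"}
        if unknown:
            raise ValueError(f"unknown region classes: {sorted(unknown)}")


def extract_regions(
    gene: GeneModel, genome: Mapping[str, str], spec: RegionSpec
) -> dict[tuple[str, int], str]:
    """Region sequences in coding orientation, keyed by (class, index).

    Promoter: ``promoter_len`` bases 5' of the start codon on the coding
    strand, truncated at the chromosome edge. Introns: one sequence each, in
    transcription order (index starts at 1). CDS: spliced concatenation of
    CDS segments in translation order.
    """
    if gene.chrom not in genome:
        raise KeyError(f"chromosome {gene.chrom!r} absent from genome")
    chrom_seq = genome[gene.chrom].upper()
    L = len(chrom_seq)
    sc = gene.start_codon_pos
    out: dict[tuple[str, int], str] = {}
    if "promoter" in spec.regions:
        if gene.strand == "+":
            lo = max(1, sc - spec.promoter_len)
            out[("promoter", 0)] = chrom_seq[lo - 1 : sc - 1]
        else:
            hi = min(L, sc + spec.promoter_len)
            out[("promoter", 0)] = revcomp(chrom_seq[sc : hi])
    if "intron" in spec.regions:
        introns = gene.introns
        if gene.strand == "-":
            introns = list(reversed(introns))
        for idx, (a, b) in enumerate(introns, start=1):
            s = chrom_seq[a - 1 : b]
            out[("intron", idx)] = s if gene.strand == "+" else revcomp(s)
    if "cds" in spec.regions and gene.cds_segments:
        segs = gene.cds_segments
        if gene.strand == "+":
            spliced = "".join(chrom_seq[a - 1 : b] for a, b in segs)
        else:
            spliced = "".join(revcomp(chrom_seq[a - 1 : b]) for a, b in reversed(segs))
        out[("cds", 0)] = spliced
    return out


def scan_gene(
    gene: GeneModel,
    genome: Mapping[str, str],
    consensus: IupacConsensus,
    spec: RegionSpec | None = None,
) -> list[MotifHit]:
    """Scan one gene's promoter, introns and spliced CDS for the consensus."""
    spec = spec or RegionSpec()
    hits: list[MotifHit] = []
    for (region, idx), seq in extract_regions(gene, genome, spec).items():
        for rh in scan_region(seq, consensus):
            hits.append(
                MotifHit(
                    gene_id=gene.gene_id,
                    region=region,
                    region_index=idx,
                    start=rh.start,
                    end=rh.end,
                    orientation=rh.orientation,
                    matched_seq=rh.matched_seq,
                )
            )
    return hits


_LABELS = {
    frozenset({"promoter"}): "promoter-only",
    frozenset({"intron"}): "intron-only",
    frozenset({"cds"}): "cds-only",
    frozenset({"promoter", "intron"}): "promoter+intron",
    frozenset({"promoter", "cds"}): "promoter+cds",
    frozenset({"intron", "cds"}): "intron+cds",
    frozenset({"promoter", "intron", "cds"}): "all-three",
}


def classify_genes(hits: Sequence[MotifHit]) -> dict[str, dict]:
    """Per-gene region-combination summary; genes without hits are absent."""
    by_gene: dict[str, Counter] = {}
    for h in hits:
        by_gene.setdefault(h.gene_id, Counter())[h.region] += 1
    return {
        gene: {"regions": counts, "label": _LABELS[frozenset(counts)]}
        for gene, counts in by_gene.items()
    }
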