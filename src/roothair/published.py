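"""Published reference values for the Arabidopsis RH/NRH comparison.

Small tables bundled with the package: the 100 genes most up-regulated in
root hairs with their RPKM values and log2(NRH/RH) fold changes, the
reported RHE matches by region with coordinates and hit patterns, the 14
differentially expressed previously unannotated transcripts, and the
headline overlap counts. These serve as worked-arithmetic anchors: the
pipeline's fold-change and percentage routines must reproduce the printed
columns from the printed inputs.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: headline overlap counts reported for the RH/NRH comparison
OVERLAP_COUNTS = {
    # up-regulated genes from the earlier array/BLAT analysis recovered here
    "prev_up_total": 635,
    "prev_up_recovered": 580,
    # newly identified up-regulated genes entering the 0.83 network
    "new_up_total": 2172,
    "new_up_in_network": 264,
    # earlier DE list vs the re-analysis DE list
    "prev_de_total": 1617,
    "de_total": 5409,
    "de_overlap": 1259,
}


def _path(name: str):
    return resources.files("roothair.data").joinpath(name)


def up100_table() -> pd.DataFrame:
    """100 most RH-up-regulated genes: RPKM pair + printed log2(NRH/RH)."""
    with resources.as_file(_path("rh_up100.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def rhe_hit_table() -> pd.DataFrame:
    """Reported RHE matches (promoter/intron/CDS) with coordinates and RPKMs.

    Coordinates are as printed: 1-based, start > end for minus-orientation
    matches; patterns are the 5'->3' read-out in match orientation.
    """
    with resources.as_file(_path("rhe_hits.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def rhe_extra_patterns() -> list[str]:
    """Additional promoter RHE patterns reported as enriched (prose only)."""
    with resources.as_file(_path("rhe_extra_patterns.txt")) as p:
        return [ln.strip() for ln in p.read_text().splitlines() if ln.strip()]


def all_rhe_patterns() -> list[str]:
    """Every distinct published RHE hit pattern (table rows + prose)."""
    table = list(rhe_hit_table()["pattern"])
    return sorted(set(table) | set(rhe_extra_patterns()))


def novel_transcript_table() -> pd.DataFrame:
    """14 DE previously unannotated transcripts; 'inf' marks RH RPKM of 0."""
    with resources.as_file(_path("novel_transcripts.tsv")) as p:
        return pd.read_csv(p, sep="\t")
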