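"""Comparison of called TSSs against previously published reference TSSs.

A small curated table of TSSs mapped in *Methylorubrum* strains by
dRNA-seq, nuclease S1 protection, primer extension and run-off
transcription ships with the package (``data/reference_tss.tsv``), with
their −35/−10 promoter boxes and spacer lengths, so positional offsets and
5'UTR differences between methods can be computed offline.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import List, Optional, Sequence, Tuple

import pandas as pd

from .core import TssCall, reverse_complement

METHODS = ("dRNA-seq", "nuclease S1", "primer extension", "run-off")

# the canonical sigma-70 spacer is ~17 nt, varying between 15 and 20
TYPICAL_SPACER_RANGE = (15, 20)


@dataclass
class ReferenceTss:
    gene: str
    strain: str
    method: str
    promoter: str = ""
    replicon: Optional[str] = None
    position: Optional[int] = None
    strand: Optional[str] = None
    utr_length: Optional[int] = None
    minus35: Optional[str] = None
    minus10: Optional[str] = None
    spacer: Optional[int] = None
    comment: str = ""

    def __post_init__(self):
        if self.position is None and self.utr_length is None:
            raise ValueError(
                f"reference {self.gene}/{self.promoter}: need a position or a 5'UTR length"
            )


def load_reference_table(path: Optional[str] = None) -> List[ReferenceTss]:
    """Load the packaged reference TSV (or a user-provided one)."""
    if path is None:
        src = resources.files("tssatlas.data").joinpath("reference_tss.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t", keep_default_na=False)
    else:
        df = pd.read_csv(path, sep="\t", keep_default_na=False)

    def _opt_int(v) -> Optional[int]:
        return None if v == "" else int(v)

    def _opt_str(v) -> Optional[str]:
        return None if v == "" else str(v)

    out = []
    for r in df.itertuples():
        out.append(
            ReferenceTss(
                gene=str(r.gene),
                strain=str(r.strain),
                method=str(r.method),
                promoter=str(getattr(r, "promoter", "")),
                replicon=_opt_str(getattr(r, "replicon", "")),
                position=_opt_int(getattr(r, "position", "")),
                strand=_opt_str(getattr(r, "strand", "")),
                utr_length=_opt_int(getattr(r, "utr_length", "")),
                minus35=_opt_str(getattr(r, "minus35", "")),
                minus10=_opt_str(getattr(r, "minus10", "")),
                spacer=_opt_int(getattr(r, "spacer", "")),
                comment=str(getattr(r, "comment", "")),
            )
        )
    return out


def find_reference(
    refs: Sequence[ReferenceTss],
    gene: str,
    method: Optional[str] = None,
    strain: Optional[str] = None,
    promoter: Optional[str] = None,
) -> ReferenceTss:
    """The unique reference row matching the given selectors."""
    hits = [
        r
        for r in refs
        if r.gene == gene
        and (method is None or r.method == method)
        and (strain is None or strain in r.strain)
        and (promoter is None or r.promoter == promoter)
    ]
    if len(hits) != 1:
        raise ValueError(
            f"expected exactly one reference for {gene}/{method}/{strain}/{promoter}, "
            f"found {len(hits)}"
        )
    return hits[0]


def match_reference(
    calls: Sequence[TssCall],
    references: Sequence[ReferenceTss],
    tolerance: int = 5,
) -> pd.DataFrame:
    """Match each positioned reference to the nearest call within tolerance.

    Offsets are signed (call − reference).  Two calls equidistant from a
    reference resolve to the 5'-most one, with the tie flagged.  References
    without a matching call are reported as unmatched rows.
    """
    rows = []
    for ref in references:
        if ref.position is None:
            continue
        nearby = [
            c
            for c in calls
            if (ref.replicon is None or c.replicon == ref.replicon)
            and (ref.strand is None or c.strand == ref.strand)
            and abs(c.position - ref.position) <= tolerance
        ]
        row = {
            "gene": ref.gene,
            "promoter": ref.promoter,
            "method": ref.method,
            "strain": ref.strain,
            "ref_position": ref.position,
            "call_position": pd.NA,
            "offset": pd.NA,
            "matched": False,
            "tie": False,
        }
        if nearby:
            dmin = min(abs(c.position - ref.position) for c in nearby)
            best = [c for c in nearby if abs(c.position - ref.position) == dmin]
            tie = len(best) > 1
            strand = ref.strand or best[0].strand
            chosen = (
                min(best, key=lambda c: c.position)
                if strand == "+"
                else max(best, key=lambda c: c.position)
            )
            row.update(
                call_position=chosen.position,
                offset=chosen.position - ref.position,
                matched=True,
                tie=tie,
            )
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "promoter",
            "method",
            "strain",
            "ref_position",
            "call_position",
            "offset",
            "matched",
            "tie",
        ],
    )


def utr_offset(a: ReferenceTss, b: ReferenceTss) -> int:
    """Signed 5'UTR difference a − b between two mappings of the same gene."""
    if a.gene != b.gene:
        raise ValueError(f"cannot compare UTRs across genes {a.gene!r} and {b.gene!r}")
    if a.utr_length is None or b.utr_length is None:
        raise ValueError(f"both references for {a.gene!r} need a 5'UTR length")
    return a.utr_length - b.utr_length


def spacer_length(sequence: str, minus35: str, minus10: str) -> int:
    """Nucleotides strictly between the −35 box end and the −10 box start.

    Both boxes must occur in the sequence in order and without overlap; the
    nearest in-order pair (smallest spacer) is used.
    """
    seq, b35, b10 = sequence.upper(), minus35.upper(), minus10.upper()
    starts35 = _occurrences(seq, b35)
    starts10 = _occurrences(seq, b10)
    if not starts35 or not starts10:
        missing = []
        if not starts35:
            missing.append(f"-35 box {minus35!r}")
        if not starts10:
            missing.append(f"-10 box {minus10!r}")
        raise ValueError(f"box not found in sequence: {', '.join(missing)}")
    spacers = [
        j - (i + len(b35))
        for i in starts35
        for j in starts10
        if j >= i + len(b35)
    ]
    if not spacers:
        raise ValueError("boxes occur only overlapping or out of order")
    return min(spacers)


def _occurrences(seq: str, sub: str) -> List[int]:
    out, i = [], seq.find(sub)
    while i != -1:
        out.append(i)
        i = seq.find(sub, i + 1)
    return out


def spacer_is_typical(spacer: int) -> bool:
    """True for a spacer within the canonical 15–20 nt range."""
    lo, hi = TYPICAL_SPACER_RANGE
    return lo <= spacer <= hi
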