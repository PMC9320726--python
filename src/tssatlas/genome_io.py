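"""Readers and writers for the standard formats the pipeline touches.

FASTA goes through Biopython, SAM/BAM through pysam, tables through pandas.
GFF3 and bedGraph are simple column formats handled here directly, with the
coordinate conventions converted at this boundary: internally everything is
1-based inclusive, bedGraph files are 0-based half-open per the standard.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    AnnotatedTss,
    EndProfile,
    Feature,
    FeatureTable,
    GenomeSet,
    TssCall,
)


class ParseError(ValueError):
    """Malformed input file; the message carries the file and line number."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> GenomeSet:
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq)
    return GenomeSet(records)


def write_fasta(genome: GenomeSet, path: str) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF_TYPE_MAP = {"gene": "gene", "CDS": "gene", "tRNA": "tRNA"}


def _parse_gff_attributes(text: str) -> Dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str, genome: Optional[GenomeSet] = None) -> FeatureTable:
    """Read gene/tRNA features from a GFF3 file.

    ``gene`` and ``CDS`` rows are typed ``gene``; ``tRNA`` rows are typed
    ``tRNA``; all other feature types are ignored.  When the same locus tag
    appears as both a ``gene`` and a ``CDS`` row only the first is kept.
    """
    feats: List[Feature] = []
    seen_tags = set()
    lengths = genome.lengths if genome is not None else None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            replicon, _src, ftype, start_s, end_s, _score, strand, _frame, attrs = cols
            if ftype not in _GFF_TYPE_MAP:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates")
            if end < start:
                raise ParseError(f"{path}:{lineno}: end {end} < start {start}")
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
            if lengths is not None:
                if replicon not in lengths:
                    raise ParseError(f"{path}:{lineno}: unknown replicon {replicon!r}")
                if end > lengths[replicon]:
                    raise ParseError(
                        f"{path}:{lineno}: coordinate {end} outside replicon "
                        f"{replicon!r} (length {lengths[replicon]})"
                    )
            a = _parse_gff_attributes(attrs)
            tag = a.get("locus_tag") or a.get("ID") or f"{replicon}:{start}-{end}"
            if tag in seen_tags:
                continue
            seen_tags.add(tag)
            feats.append(
                Feature(
                    replicon=replicon,
                    start=start,
                    end=end,
                    strand=strand,
                    type=_GFF_TYPE_MAP[ftype],
                    locus_tag=tag,
                )
            )
    return FeatureTable(feats)


def write_gff3(features: FeatureTable, path: str, source: str = "tssatlas") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.locus_tag};locus_tag={f.locus_tag}"
            fh.write(
                f"{f.replicon}\t{source}\t{f.type}\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# SAM/BAM -> 5'-end profiles
# ---------------------------------------------------------------------------

def alignments_to_end_profile(
    path: str,
    library_kind: str,
    condition: str = "",
    replicate: str = "",
    clip_aware: bool = False,
) -> Dict[Tuple[str, str], EndProfile]:
    """Count the 5'-most genomic base of each primary mapped alignment.

    Forward-strand alignments contribute at their leftmost reference
    position, reverse-strand ones at their rightmost.  Secondary,
    supplementary and unmapped records are ignored.  With ``clip_aware``
    the position is shifted outward by the length of the terminal soft clip
    so the read's true 5' end (rather than the aligned start) is counted.
    """
    profiles: Dict[Tuple[str, str], EndProfile] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        if af.header.nreferences == 0:
            raise ParseError(f"{path}: missing sequence header (@SQ lines)")
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            replicon = read.reference_name
            strand = "-" if read.is_reverse else "+"
            if read.is_reverse:
                pos = read.reference_end  # pysam reference_end is exclusive -> 1-based inclusive
                if clip_aware and read.cigartuples and read.cigartuples[-1][0] == 4:
                    pos += read.cigartuples[-1][1]
            else:
                pos = read.reference_start + 1
                if clip_aware and read.cigartuples and read.cigartuples[0][0] == 4:
                    pos -= read.cigartuples[0][1]
            if pos < 1:
                continue
            key = (replicon, strand)
            if key not in profiles:
                profiles[key] = EndProfile(
                    replicon=replicon,
                    strand=strand,
                    library_kind=library_kind,
                    condition=condition,
                    replicate=replicate,
                )
            profiles[key].add(pos, 1)
    return profiles


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def _read_bedgraph(path: str) -> Dict[str, Dict[int, int]]:
    """Parse one bedGraph file into {replicon: {1-based position: count}}."""
    intervals: Dict[str, List[Tuple[int, int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            cols = line.split()
            if len(cols) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(cols)}")
            chrom, s0, e0, val = cols
            try:
                start0, end0 = int(s0), int(e0)
                value = float(val)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: malformed numeric field")
            if value < 0:
                raise ParseError(f"{path}:{lineno}: negative count {value}")
            if value != int(value):
                raise ParseError(f"{path}:{lineno}: non-integer count {value}")
            if end0 <= start0 or start0 < 0:
                raise ParseError(f"{path}:{lineno}: invalid interval [{start0}, {end0})")
            intervals.setdefault(chrom, []).append((start0, end0, int(value)))
    out: Dict[str, Dict[int, int]] = {}
    for chrom, ivals in intervals.items():
        ivals.sort()
        prev_end = -1
        counts: Dict[int, int] = {}
        for start0, end0, value in ivals:
            if start0 < prev_end:
                raise ParseError(f"{path}: overlapping intervals on {chrom} at {start0}")
            prev_end = end0
            if value > 0:
                for p0 in range(start0, end0):
                    counts[p0 + 1] = value
        out[chrom] = counts
    return out


def read_bedgraph_pair(
    fwd_path: str,
    rev_path: str,
    library_kind: str,
    condition: str = "",
    replicate: str = "",
) -> Dict[Tuple[str, str], EndProfile]:
    """Read one library's strand-specific bedGraph pair (forward, reverse)."""
    profiles: Dict[Tuple[str, str], EndProfile] = {}
    for path, strand in ((fwd_path, "+"), (rev_path, "-")):
        for replicon, counts in _read_bedgraph(path).items():
            profiles[(replicon, strand)] = EndProfile(
                replicon=replicon,
                strand=strand,
                counts=counts,
                library_kind=library_kind,
                condition=condition,
                replicate=replicate,
            )
    return profiles


def write_bedgraph_pair(
    profiles: Iterable[EndProfile], fwd_path: str, rev_path: str
) -> None:
    """Write profiles as a strand pair of bedGraph files (one line per position)."""
    by_strand: Dict[str, List[EndProfile]] = {"+": [], "-": []}
    for p in profiles:
        by_strand[p.strand].append(p)
    for path, strand in ((fwd_path, "+"), (rev_path, "-")):
        with open(path, "w") as fh:
            for prof in sorted(by_strand[strand], key=lambda p: p.replicon):
                for pos in prof.positions():
                    fh.write(f"{prof.replicon}\t{pos - 1}\t{pos}\t{prof.counts[pos]}\n")


# ---------------------------------------------------------------------------
# TSS call tables
# ---------------------------------------------------------------------------

_CALL_COLUMNS = [
    "replicon",
    "position",
    "strand",
    "k_plus",
    "k_minus",
    "p_value",
    "condition",
    "replicate_support",
]


def write_calls(calls: Sequence[TssCall], path: str) -> None:
    df = pd.DataFrame(
        [
            {
                "replicon": c.replicon,
                "position": c.position,
                "strand": c.strand,
                "k_plus": c.k_plus,
                "k_minus": c.k_minus,
                "p_value": c.p_value,
                "condition": c.condition,
                "replicate_support": c.replicate_support,
            }
            for c in calls
        ],
        columns=_CALL_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_calls(path: str) -> List[TssCall]:
    df = pd.read_csv(path, sep="\t", dtype={"condition": str}, keep_default_na=False)
    return [
        TssCall(
            replicon=str(r.replicon),
            position=int(r.position),
            strand=str(r.strand),
            k_plus=int(r.k_plus),
            k_minus=int(r.k_minus),
            p_value=float(r.p_value),
            condition=str(r.condition),
            replicate_support=int(r.replicate_support),
        )
        for r in df.itertuples()
    ]


_TSS_COLUMNS = [
    "replicon",
    "position",
    "strand",
    "classes",
    "gene",
    "utr_length",
    "leaderless",
    "k_plus",
    "k_minus",
    "p_value",
    "conditions_detected",
]


def write_tss_outputs(
    annotated: Sequence[AnnotatedTss], tsv_path: str, gff3_path: Optional[str] = None
) -> None:
    """Write the annotated TSS table (TSV, stable column order) and a GFF3 track."""
    rows = []
    for a in annotated:
        c = a.call
        gene = ";".join(f"{lab}:{g}" for lab, g in sorted(a.linked_genes.items()))
        rows.append(
            {
                "replicon": c.replicon,
                "position": c.position,
                "strand": c.strand,
                "classes": ",".join(a.labels),
                "gene": gene,
                "utr_length": "" if a.utr_length is None else a.utr_length,
                "leaderless": "" if a.leaderless is None else a.leaderless,
                "k_plus": c.k_plus,
                "k_minus": c.k_minus,
                "p_value": c.p_value,
                "conditions_detected": ",".join(a.conditions_detected),
            }
        )
    pd.DataFrame(rows, columns=_TSS_COLUMNS).to_csv(tsv_path, sep="\t", index=False)
    if gff3_path is not None:
        with open(gff3_path, "w") as fh:
            fh.write("##gff-version 3\n")
            for a in annotated:
                c = a.call
                attrs = f"classes={','.join(a.labels)}"
                if a.utr_length is not None:
                    attrs += f";utr_length={a.utr_length}"
                fh.write(
                    f"{c.replicon}\ttssatlas\tTSS\t{c.position}\t{c.position}\t"
                    f"{c.p_value:.3g}\t{c.strand}\t.\t{attrs}\n"
                )


def read_tss_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)
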