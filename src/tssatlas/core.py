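"""Shared data containers for the TSS mapping pipeline.

Coordinate conventions
----------------------
All positions are 1-based and intervals are closed on both ends, matching
GFF3 and the way bacterial TSS positions are reported in the literature.
bedGraph's 0-based half-open convention is converted at the I/O boundary
(:mod:`tssatlas.genome_io`) and nowhere else.  Strand is ``"+"`` or ``"-"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Tuple

STRANDS = ("+", "-")
FEATURE_TYPES = ("gene", "tRNA")
LIBRARY_KINDS = ("plus_lib", "minus_lib")
TSS_LABELS = ("P", "I", "Ai", "Ad", "O")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSet:
    """Ordered collection of named replicon sequences.

    Sequences are stored uppercase; the alphabet is restricted to
    ``A, C, G, T, N``.  Replicon names must be unique.
    """

    def __init__(self, replicons: Mapping[str, str]):
        self._replicons: Dict[str, str] = {}
        for name, seq in replicons.items():
            if name in self._replicons:
                raise ValueError(f"duplicate replicon name: {name!r}")
            s = str(seq).upper()
            bad = set(s) - {"A", "C", "G", "T", "N"}
            if bad:
                raise ValueError(
                    f"replicon {name!r} contains invalid characters: {sorted(bad)}"
                )
            self._replicons[name] = s

    @property
    def names(self) -> List[str]:
        return list(self._replicons)

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self._replicons.items()}

    def __getitem__(self, name: str) -> str:
        return self._replicons[name]

    def __contains__(self, name: str) -> bool:
        return name in self._replicons

    def __len__(self) -> int:
        return len(self._replicons)

    def items(self) -> Iterator[Tuple[str, str]]:
        return iter(self._replicons.items())

    def subsequence(self, replicon: str, start: int, end: int, strand: str = "+") -> str:
        """1-based inclusive subsequence; minus strand returns the reverse complement."""
        seq = self._replicons[replicon]
        if not (1 <= start <= end <= len(seq)):
            raise ValueError(
                f"interval [{start}, {end}] outside replicon {replicon!r} "
                f"(length {len(seq)})"
            )
        if strand not in STRANDS:
            raise ValueError(f"unknown strand {strand!r}")
        sub = seq[start - 1 : end]
        return reverse_complement(sub) if strand == "-" else sub

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeSet) and self._replicons == other._replicons


@dataclass(frozen=True)
class Feature:
    """A stranded annotation interval (gene or tRNA), 1-based inclusive."""

    replicon: str
    start: int
    end: int
    strand: str
    type: str = "gene"
    locus_tag: str = ""

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}] for {self.locus_tag!r}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r} for {self.locus_tag!r}")
        if self.type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.type!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def five_prime(self) -> int:
        """Position of the feature's 5'-most base (start codon side for genes)."""
        return self.start if self.strand == "+" else self.end


class FeatureTable:
    """Collection of :class:`Feature` records with unique locus tags."""

    def __init__(self, records: Iterable[Feature] = ()):
        self.records: List[Feature] = list(records)
        tags = [f.locus_tag for f in self.records if f.locus_tag]
        if len(tags) != len(set(tags)):
            seen, dup = set(), set()
            for t in tags:
                (dup if t in seen else seen).add(t)
            raise ValueError(f"duplicate locus tags: {sorted(dup)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Feature]:
        return iter(self.records)

    def genes(self) -> List[Feature]:
        return [f for f in self.records if f.type == "gene"]

    def trnas(self) -> List[Feature]:
        return [f for f in self.records if f.type == "tRNA"]

    def by_replicon(self, replicon: str, strand: Optional[str] = None) -> List[Feature]:
        return [
            f
            for f in self.records
            if f.replicon == replicon and (strand is None or f.strand == strand)
        ]

    def validate_against(self, genome: GenomeSet) -> None:
        lengths = genome.lengths
        for f in self.records:
            if f.replicon not in lengths:
                raise ValueError(f"feature {f.locus_tag!r} on unknown replicon {f.replicon!r}")
            if f.end > lengths[f.replicon]:
                raise ValueError(
                    f"feature {f.locus_tag!r} ends at {f.end} beyond replicon "
                    f"{f.replicon!r} length {lengths[f.replicon]}"
                )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "replicon": f.replicon,
                    "start": f.start,
                    "end": f.end,
                    "strand": f.strand,
                    "type": f.type,
                    "locus_tag": f.locus_tag,
                }
                for f in self.records
            ],
            columns=["replicon", "start", "end", "strand", "type", "locus_tag"],
        )

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureTable) and self.records == other.records


@dataclass
class EndProfile:
    """Sparse per-position 5'-end read counts for one library on one strand.

    ``library_kind`` is ``"plus_lib"`` for the enriched (treated) library and
    ``"minus_lib"`` for the untreated control; these are the "+" and "−"
    banks of a dRNA-seq experiment.
    """

    replicon: str
    strand: str
    counts: Dict[int, int] = field(default_factory=dict)
    library_kind: str = "plus_lib"
    condition: str = ""
    replicate: str = ""

    def __post_init__(self):
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")
        if self.library_kind not in LIBRARY_KINDS:
            raise ValueError(f"unknown library kind {self.library_kind!r}")
        for pos, c in self.counts.items():
            if pos < 1:
                raise ValueError(f"position {pos} < 1 in profile")
            if not isinstance(c, (int,)) or c < 1:
                raise ValueError(f"stored count must be a positive integer, got {c!r} at {pos}")

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    def get(self, position: int) -> int:
        return self.counts.get(position, 0)

    def add(self, position: int, count: int) -> None:
        if count <= 0:
            return
        self.counts[position] = self.counts.get(position, 0) + int(count)

    def positions(self) -> List[int]:
        return sorted(self.counts)


@dataclass
class TssCall:
    """A called transcription start site with its differential test statistics."""

    replicon: str
    position: int
    strand: str
    k_plus: int
    k_minus: int
    p_value: float
    condition: str = ""
    replicate_support: int = 1

    @property
    def diff(self) -> int:
        return self.k_plus - self.k_minus

    def key(self) -> Tuple[str, str, int]:
        return (self.replicon, self.strand, self.position)


@dataclass
class AnnotatedTss:
    """A curated TSS with positional class labels, gene links and 5'UTR length.

    ``labels`` is a non-empty subset of ``("P", "I", "Ai", "Ad", "O")`` in
    canonical order; ``"O"`` never co-occurs with other labels.
    ``utr_length`` is present iff ``"P"`` is among the labels and
    ``leaderless`` means a 5'UTR of at most 9 nt.
    """

    call: TssCall
    labels: Tuple[str, ...]
    linked_genes: Dict[str, str] = field(default_factory=dict)
    utr_length: Optional[int] = None
    leaderless: Optional[bool] = None
    conditions_detected: Tuple[str, ...] = ()

    def __post_init__(self):
        if not self.labels:
            raise ValueError("AnnotatedTss needs at least one label")
        bad = set(self.labels) - set(TSS_LABELS)
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")
        if "O" in self.labels and len(self.labels) > 1:
            raise ValueError("orphan label is exclusive of all others")
        if ("P" in self.labels) != (self.utr_length is not None):
            raise ValueError("utr_length must be present iff the TSS is primary")

    @property
    def primary_label(self) -> str:
        """Single class under the exclusive precedence P > I > A > O."""
        for lab in ("P", "I", "Ai", "Ad", "O"):
            if lab in self.labels:
                return "A" if lab in ("Ai", "Ad") else lab
        raise AssertionError("unreachable")
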