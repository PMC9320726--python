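"""Positional classification of TSSs and 5'UTR analysis.

A TSS is classified relative to the gene annotation on its replicon:

* ``P`` (primary / gene TSS): a same-strand gene start lies within
  ``primary_window`` nt (default 250) downstream; offset 0 — the TSS on
  the first base of the start codon — is still primary, with a 5'UTR of 0
  (a leaderless transcript).
* ``I`` (internal): the TSS lies inside a same-strand gene body.
* ``Ai`` / ``Ad`` (antisense): the TSS lies inside an opposite-strand gene,
  or within ``antisense_margin`` nt (default 30) beyond either of its ends.
* ``O`` (orphan): none of the above; exclusive of all other labels.

Labels accumulate: a TSS inside gene A and within 250 nt of gene B's start
is ``{I, P}`` (the "IP" class).  The 5'UTR is the distance from the TSS to
the start codon of the linked gene; 0–9 nt flags a leaderless mRNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import AnnotatedTss, Feature, FeatureTable, GenomeSet, TssCall


@dataclass
class ClassParams:
    primary_window: int = 250
    antisense_margin: int = 30
    leaderless_max: int = 9
    utr_max: int = 250

    def __post_init__(self):
        for name in ("primary_window", "antisense_margin", "leaderless_max", "utr_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.leaderless_max >= self.utr_max:
            raise ValueError("leaderless_max must be < utr_max")


class InternalConsistencyError(ValueError):
    """Raised when a gene link contradicts the classification geometry."""


class _StrandIndex:
    """Vectorized per-(replicon, strand) arrays of gene intervals."""

    def __init__(self, feats: Sequence[Feature]):
        self.start = np.array([f.start for f in feats], dtype=np.int64)
        self.end = np.array([f.end for f in feats], dtype=np.int64)
        self.five = np.array([f.five_prime() for f in feats], dtype=np.int64)
        self.tags = [f.locus_tag for f in feats]


class FeatureIndex:
    def __init__(self, features: FeatureTable):
        self._tracks: Dict[Tuple[str, str], _StrandIndex] = {}
        by_track: Dict[Tuple[str, str], List[Feature]] = {}
        for f in features:
            by_track.setdefault((f.replicon, f.strand), []).append(f)
        for key, feats in by_track.items():
            self._tracks[key] = _StrandIndex(feats)

    def track(self, replicon: str, strand: str) -> Optional[_StrandIndex]:
        return self._tracks.get((replicon, strand))


def classify(
    tss: TssCall,
    features: FeatureTable,
    params: Optional[ClassParams] = None,
    index: Optional[FeatureIndex] = None,
) -> AnnotatedTss:
    """Assign positional class labels and, for primary TSSs, the 5'UTR."""
    params = params or ClassParams()
    index = index or FeatureIndex(features)
    p, s = tss.position, tss.strand
    anti = "-" if s == "+" else "+"

    labels: List[str] = []
    linked: Dict[str, str] = {}
    utr: Optional[int] = None

    sense = index.track(tss.replicon, s)
    if sense is not None:
        # primary: same-strand gene start 0..window downstream of the TSS
        offs = sense.five - p if s == "+" else p - sense.five
        ok = (offs >= 0) & (offs <= params.primary_window)
        if ok.any():
            cands = np.flatnonzero(ok)
            j = cands[np.argmin(offs[cands])]
            labels.append("P")
            linked["P"] = sense.tags[j]
            utr = int(offs[j])
        inside = (sense.start <= p) & (p <= sense.end)
        if inside.any():
            labels.append("I")
            linked["I"] = sense.tags[int(np.flatnonzero(inside)[0])]

    opp = index.track(tss.replicon, anti)
    if opp is not None:
        inside = (opp.start <= p) & (p <= opp.end)
        if inside.any():
            labels.append("Ai")
            linked["Ai"] = opp.tags[int(np.flatnonzero(inside)[0])]
        dist = np.where(p < opp.start, opp.start - p, p - opp.end)
        near = ~inside & (dist >= 1) & (dist <= params.antisense_margin)
        if near.any():
            cands = np.flatnonzero(near)
            j = cands[np.argmin(dist[cands])]
            labels.append("Ad")
            linked["Ad"] = opp.tags[j]

    if not labels:
        labels = ["O"]

    order = {"P": 0, "I": 1, "Ai": 2, "Ad": 3, "O": 4}
    labels.sort(key=order.__getitem__)
    leaderless = None if utr is None else utr <= params.leaderless_max
    return AnnotatedTss(
        call=tss,
        labels=tuple(labels),
        linked_genes=linked,
        utr_length=utr,
        leaderless=leaderless,
    )


def classify_all(
    calls: Sequence[TssCall],
    features: FeatureTable,
    params: Optional[ClassParams] = None,
) -> List[AnnotatedTss]:
    params = params or ClassParams()
    index = FeatureIndex(features)
    return [classify(c, features, params, index) for c in calls]


def compute_utr(tss: TssCall, gene: Feature, params: Optional[ClassParams] = None) -> int:
    """Distance from the TSS to the first base of the start codon.

    Plus strand: ``gene.start - tss.position``; minus strand:
    ``tss.position - gene.end``.  0 means the TSS coincides with the start
    codon (leaderless transcript).  A negative result means the TSS was
    mislinked and indicates a classification bug upstream.
    """
    params = params or ClassParams()
    if tss.strand != gene.strand:
        raise InternalConsistencyError(
            f"TSS strand {tss.strand} differs from gene {gene.locus_tag!r}"
        )
    length = gene.start - tss.position if tss.strand == "+" else tss.position - gene.end
    if length < 0:
        raise InternalConsistencyError(
            f"negative 5'UTR ({length}) for TSS {tss.position} vs gene {gene.locus_tag!r}"
        )
    return length


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize(
    annotated: Sequence[AnnotatedTss],
    genome: Optional[GenomeSet] = None,
    params: Optional[ClassParams] = None,
) -> Dict[str, object]:
    """Deterministic summary tables of a TSS set.

    Returns a dict with:

    * ``per_replicon`` — TSS counts per replicon;
    * ``class_counts`` — per-label tallies, both multi-label (a TSS counts
      once per label it carries) and exclusive under precedence
      P > I > A > O;
    * ``utr_hist`` — 5'UTR length histogram over primary TSSs;
    * ``utr_stats`` — mean, median, leaderless fraction and n.
    """
    params = params or ClassParams()
    replicons = list(genome.names) if genome is not None else sorted(
        {a.call.replicon for a in annotated}
    )
    per_rep = {r: 0 for r in replicons}
    for a in annotated:
        per_rep[a.call.replicon] = per_rep.get(a.call.replicon, 0) + 1
    per_replicon = pd.DataFrame(
        {"replicon": list(per_rep), "n_tss": list(per_rep.values())}
    )

    n = len(annotated)
    multi = {lab: 0 for lab in ("P", "I", "Ai", "Ad", "A", "O")}
    excl = {lab: 0 for lab in ("P", "I", "A", "O")}
    for a in annotated:
        for lab in a.labels:
            multi[lab] += 1
        if "Ai" in a.labels or "Ad" in a.labels:
            multi["A"] += 1
        excl[a.primary_label] += 1
    rows = []
    for lab in ("P", "I", "Ai", "Ad", "A", "O"):
        rows.append(
            {
                "label": lab,
                "count_multilabel": multi[lab],
                "frac_multilabel": multi[lab] / n if n else 0.0,
                "count_exclusive": excl.get(lab, 0) if lab in excl else np.nan,
                "frac_exclusive": (excl[lab] / n if n else 0.0) if lab in excl else np.nan,
            }
        )
    class_counts = pd.DataFrame(rows)

    utrs = np.array(
        [a.utr_length for a in annotated if a.utr_length is not None], dtype=np.int64
    )
    hist = pd.DataFrame(
        {
            "utr_length": np.arange(0, params.utr_max + 1),
            "count": np.bincount(utrs, minlength=params.utr_max + 1)
            if utrs.size
            else np.zeros(params.utr_max + 1, dtype=np.int64),
        }
    )
    utr_stats = {
        "n": int(utrs.size),
        "mean": float(utrs.mean()) if utrs.size else 0.0,
        "median": float(np.median(utrs)) if utrs.size else 0.0,
        "leaderless_fraction": float((utrs <= params.leaderless_max).mean())
        if utrs.size
        else 0.0,
    }
    return {
        "per_replicon": per_replicon,
        "class_counts": class_counts,
        "utr_hist": hist,
        "utr_stats": utr_stats,
    }
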