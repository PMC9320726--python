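"""Rule-based curation of raw TSS calls.

Three steps turn per-replicate call lists into a curated set: replicate
consolidation, resolution of clustered calls with similar read support
(several TSSs less than 10 nt apart usually reflect one biological start),
and removal of calls upstream of tRNA genes whose abundant, heavily
processed transcripts confound 5'-end mapping.  No step ever invents a
position: curated output is always a subset of the input positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .core import Feature, FeatureTable, TssCall


@dataclass
class CurationParams:
    cluster_window: int = 10
    similar_fold: float = 2.0
    require_replicate_support: str = "any"  # "any" (union) or "both"
    trna_upstream_window: int = 250

    def __post_init__(self):
        if self.cluster_window < 0:
            raise ValueError("cluster_window must be >= 0")
        if self.similar_fold < 1.0:
            raise ValueError("similar_fold must be >= 1")
        if self.require_replicate_support not in ("any", "both"):
            raise ValueError("require_replicate_support must be 'any' or 'both'")


def consolidate_replicates(
    calls_rep1: Sequence[TssCall],
    calls_rep2: Sequence[TssCall],
    params: Optional[CurationParams] = None,
) -> List[TssCall]:
    """Merge two replicates of the same condition into one call list.

    Calls at an identical (replicon, strand, position) are merged with
    summed counts, the smaller p-value, and replicate support 2.  Under the
    default ``any`` policy the union is kept; under ``both`` only calls
    supported within ``cluster_window`` nt in the other replicate survive.
    """
    params = params or CurationParams()
    conditions = {c.condition for c in calls_rep1} | {c.condition for c in calls_rep2}
    if len(conditions) > 1:
        raise ValueError(f"replicates span multiple conditions: {sorted(conditions)}")

    merged: Dict[Tuple[str, str, int], TssCall] = {}
    for call in list(calls_rep1) + list(calls_rep2):
        key = call.key()
        if key in merged:
            prev = merged[key]
            merged[key] = TssCall(
                replicon=call.replicon,
                position=call.position,
                strand=call.strand,
                k_plus=prev.k_plus + call.k_plus,
                k_minus=prev.k_minus + call.k_minus,
                p_value=min(prev.p_value, call.p_value),
                condition=call.condition,
                replicate_support=prev.replicate_support + call.replicate_support,
            )
        else:
            merged[key] = call

    out = sorted(merged.values(), key=lambda c: (c.replicon, c.strand, c.position))
    if params.require_replicate_support == "both":
        idx1 = _position_index(calls_rep1)
        idx2 = _position_index(calls_rep2)
        out = [
            c
            for c in out
            if _supported(c, idx1, params.cluster_window)
            and _supported(c, idx2, params.cluster_window)
        ]
    return out


def _position_index(calls: Sequence[TssCall]) -> Dict[Tuple[str, str], List[int]]:
    idx: Dict[Tuple[str, str], List[int]] = {}
    for c in calls:
        idx.setdefault((c.replicon, c.strand), []).append(c.position)
    for v in idx.values():
        v.sort()
    return idx


def _supported(
    call: TssCall, index: Dict[Tuple[str, str], List[int]], window: int
) -> bool:
    import bisect

    positions = index.get((call.replicon, call.strand), [])
    i = bisect.bisect_left(positions, call.position - window)
    return i < len(positions) and positions[i] <= call.position + window


def cluster_and_select(
    calls: Sequence[TssCall],
    other_condition_calls: Sequence[TssCall] = (),
    params: Optional[CurationParams] = None,
) -> List[TssCall]:
    """Resolve clusters of nearby calls with similar read numbers.

    Same-strand calls within ``cluster_window`` nt whose "+" counts are
    within ``similar_fold`` of one another form a cluster; exactly one call
    survives per cluster: members whose position recurs (within the window)
    in the other culture condition are preferred, then the largest "+"
    count, then the 5'-most position.  Calls whose read numbers differ by
    more than the fold gate are genuine alternative TSSs and all pass
    through, as do isolated calls.  The operation is idempotent.
    """
    params = params or CurationParams()
    other_idx = _position_index(other_condition_calls)

    by_track: Dict[Tuple[str, str], List[TssCall]] = {}
    for c in calls:
        by_track.setdefault((c.replicon, c.strand), []).append(c)

    out: List[TssCall] = []
    for track in sorted(by_track):
        members = sorted(by_track[track], key=lambda c: c.position)
        # transitively link adjacent calls that are close AND similar
        cluster: List[TssCall] = []
        for c in members:
            if cluster and _linked(cluster[-1], c, params):
                cluster.append(c)
            else:
                if cluster:
                    out.extend(_select(cluster, other_idx, params))
                cluster = [c]
        if cluster:
            out.extend(_select(cluster, other_idx, params))
    return sorted(out, key=lambda c: (c.replicon, c.strand, c.position))


def _linked(a: TssCall, b: TssCall, params: CurationParams) -> bool:
    if b.position - a.position > params.cluster_window:
        return False
    hi, lo = max(a.k_plus, b.k_plus), max(min(a.k_plus, b.k_plus), 1)
    return hi / lo <= params.similar_fold


def _nearest_distance(
    call: TssCall, index: Dict[Tuple[str, str], List[int]]
) -> float:
    positions = index.get((call.replicon, call.strand), [])
    if not positions:
        return float("inf")
    return min(abs(p - call.position) for p in positions)


def _select(
    cluster: List[TssCall],
    other_idx: Dict[Tuple[str, str], List[int]],
    params: CurationParams,
) -> List[TssCall]:
    if len(cluster) == 1:
        return cluster
    # prefer the member(s) closest to a call in the other condition, provided
    # they lie within the cluster window of one
    dists = [_nearest_distance(c, other_idx) for c in cluster]
    dmin = min(dists)
    matched = (
        [c for c, d in zip(cluster, dists) if d == dmin]
        if dmin <= params.cluster_window
        else []
    )
    pool = matched if matched else cluster
    best_k = max(c.k_plus for c in pool)
    best = [c for c in pool if c.k_plus == best_k]
    strand = cluster[0].strand
    chosen = min(best, key=lambda c: c.position) if strand == "+" else max(
        best, key=lambda c: c.position
    )
    return [chosen]


def filter_trna(
    calls: Sequence[TssCall],
    features: FeatureTable,
    params: Optional[CurationParams] = None,
) -> Tuple[List[TssCall], List[TssCall]]:
    """Split calls into (kept, removed) by proximity to downstream tRNAs.

    A call is removed iff a same-strand tRNA start lies within
    ``trna_upstream_window`` nt downstream of it — the same association
    rule used to link primary TSSs to genes.  The removed list is returned
    for the audit trail; kept + removed always equals the input.
    """
    params = params or CurationParams()
    trnas = features.trnas()
    starts: Dict[Tuple[str, str], List[int]] = {}
    for t in trnas:
        starts.setdefault((t.replicon, t.strand), []).append(t.five_prime())
    for v in starts.values():
        v.sort()

    import bisect

    kept: List[TssCall] = []
    removed: List[TssCall] = []
    w = params.trna_upstream_window
    for c in calls:
        pos_list = starts.get((c.replicon, c.strand), [])
        if c.strand == "+":
            lo, hi = c.position, c.position + w
        else:
            lo, hi = c.position - w, c.position
        i = bisect.bisect_left(pos_list, lo)
        hit = i < len(pos_list) and pos_list[i] <= hi
        (removed if hit else kept).append(c)
    return kept, removed
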