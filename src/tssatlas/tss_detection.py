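"""Position-wise Skellam differential test of "+" vs "−" 5'-end counts.

The dRNA-seq contrast compares an enriched library ("+", treated so that
only primary 5'-triphosphate ends survive) against an untreated control
("−").  Under the null, the read-start counts at a position are independent
Poisson variables with library-wide rates lambda_plus and lambda_minus, so
their difference follows a Skellam distribution.  A TSS is called where the
observed excess of "+" counts is improbable under that null.

Two safeguards accompany the test: a ``noise`` floor on the "+" count (the
minimal read support, default 10) and a minimum "+"/"−" fold enrichment
(default 2), the classic dRNA-seq discriminator between primary 5' ends and
processed sites.  Processed 5' ends appear with similar counts in both
libraries, so however deep their coverage they fail the fold gate even when
Poisson jitter makes their count difference nominally significant against
the genome-wide rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .core import EndProfile, TssCall


@dataclass
class DetectionParams:
    """Tuning knobs of the caller.

    noise: minimum "+" reads at a candidate position (default 10).
    merge: maximum distance in nt between adjacent significant positions
        fused into a single TSS (default 1).
    alpha: p-value threshold, applied to raw p-values without
        multiple-testing correction (default 0.01).
    rate_policy: "global_nonzero" (one rate per replicon/strand, averaged
        over positions with at least one read in either library) or
        "windowed" (same statistic inside a sliding window of ``window`` nt).
    min_fold: minimal k_plus/max(k_minus, 1) ratio for a call; ``None``
        disables the gate and leaves the pure Skellam rule.
    """

    noise: int = 10
    merge: int = 1
    alpha: float = 0.01
    rate_policy: str = "global_nonzero"
    window: int = 1000
    min_fold: Optional[float] = 2.0

    def __post_init__(self):
        if self.noise < 1:
            raise ValueError("noise must be >= 1")
        if self.merge < 0:
            raise ValueError("merge must be >= 0")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.rate_policy not in ("global_nonzero", "windowed"):
            raise ValueError(f"unknown rate policy {self.rate_policy!r}")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.min_fold is not None and self.min_fold < 1.0:
            raise ValueError("min_fold must be >= 1 (or None)")


@dataclass
class RateEstimate:
    """Estimated expected counts per transcribed position for the two banks."""

    lambda_plus: float
    lambda_minus: float
    scope: Tuple = ()
    flagged: bool = False  # True when no position carried any read

    def __post_init__(self):
        if self.lambda_plus < 0 or self.lambda_minus < 0:
            raise ValueError("rates must be non-negative")


# ---------------------------------------------------------------------------
# Skellam distribution with exact lambda -> 0 limits
# ---------------------------------------------------------------------------

def skellam_pmf(k, lambda1: float, lambda2: float):
    """P(N1 - N2 = k) for independent Poisson(lambda1), Poisson(lambda2).

    lambda2 = 0 reduces exactly to the Poisson(lambda1) mass; both zero
    gives a point mass at 0.  Accepts scalar or array ``k``.
    """
    _check_rates(lambda1, lambda2)
    k = np.asarray(k)
    if lambda1 > 0 and lambda2 > 0:
        out = stats.skellam.pmf(k, lambda1, lambda2)
    elif lambda2 == 0 and lambda1 > 0:
        out = np.where(k >= 0, stats.poisson.pmf(np.maximum(k, 0), lambda1), 0.0)
    elif lambda1 == 0 and lambda2 > 0:
        out = np.where(k <= 0, stats.poisson.pmf(np.maximum(-k, 0), lambda2), 0.0)
    else:
        out = np.where(k == 0, 1.0, 0.0)
    return out if out.ndim else float(out)


def skellam_sf(d, lambda1: float, lambda2: float):
    """P(N1 - N2 >= d), the upper tail used as the one-sided p-value.

    Note the inclusive convention: ``skellam_sf(d, .) = P(D >= d)``, i.e.
    ``scipy.stats.skellam.sf(d - 1, ...)``.
    """
    _check_rates(lambda1, lambda2)
    d = np.asarray(d)
    if lambda1 > 0 and lambda2 > 0:
        out = stats.skellam.sf(d - 1, lambda1, lambda2)
    elif lambda2 == 0 and lambda1 > 0:
        # difference is Poisson(lambda1)
        out = np.where(d <= 0, 1.0, stats.poisson.sf(np.maximum(d, 1) - 1, lambda1))
    elif lambda1 == 0 and lambda2 > 0:
        # difference is -Poisson(lambda2)
        out = np.where(d > 0, 0.0, stats.poisson.cdf(np.maximum(-d, 0), lambda2))
    else:
        out = np.where(d <= 0, 1.0, 0.0)
    return out if out.ndim else float(out)


def _check_rates(lambda1: float, lambda2: float) -> None:
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError(f"negative rate: lambda1={lambda1}, lambda2={lambda2}")


# ---------------------------------------------------------------------------
# Rate estimation
# ---------------------------------------------------------------------------

def _union_positions(plus: EndProfile, minus: EndProfile) -> np.ndarray:
    return np.array(sorted(set(plus.counts) | set(minus.counts)), dtype=np.int64)


def estimate_rates(
    plus: EndProfile,
    minus: EndProfile,
    policy: str = "global_nonzero",
    window: int = 1000,
) -> RateEstimate:
    """Library-wide Poisson rates over transcribed (non-empty) positions.

    Zero-count positions are excluded from the average so untranscribed
    stretches of the genome do not deflate the rates (zero inflation).
    With no non-empty position at all both rates are 0 and the estimate is
    flagged rather than raising.
    """
    _check_pair(plus, minus)
    union = _union_positions(plus, minus)
    if union.size == 0:
        return RateEstimate(0.0, 0.0, scope=(plus.replicon, plus.strand, policy), flagged=True)
    lam_p = sum(plus.counts.values()) / union.size
    lam_m = sum(minus.counts.values()) / union.size
    return RateEstimate(lam_p, lam_m, scope=(plus.replicon, plus.strand, policy))


def windowed_rates(
    plus: EndProfile, minus: EndProfile, positions: np.ndarray, window: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-position rates from a centered sliding window of ``window`` nt.

    For each query position the mean count over non-empty positions within
    ``window // 2`` nt on either side is returned, for both libraries.
    """
    union = _union_positions(plus, minus)
    if union.size == 0:
        z = np.zeros(len(positions))
        return z, z.copy()
    kp = np.array([plus.get(int(p)) for p in union], dtype=float)
    km = np.array([minus.get(int(p)) for p in union], dtype=float)
    cp = np.concatenate([[0.0], np.cumsum(kp)])
    cm = np.concatenate([[0.0], np.cumsum(km)])
    half = window // 2
    lo = np.searchsorted(union, np.asarray(positions) - half, side="left")
    hi = np.searchsorted(union, np.asarray(positions) + half, side="right")
    n = np.maximum(hi - lo, 1)
    return (cp[hi] - cp[lo]) / n, (cm[hi] - cm[lo]) / n


def _check_pair(plus: EndProfile, minus: EndProfile) -> None:
    if plus.replicon != minus.replicon or plus.strand != minus.strand:
        raise ValueError(
            f"mismatched profiles: {plus.replicon}/{plus.strand} vs "
            f"{minus.replicon}/{minus.strand}"
        )


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------

def call_tss(
    plus: EndProfile,
    minus: EndProfile,
    params: Optional[DetectionParams] = None,
    rates: Optional[RateEstimate] = None,
) -> List[TssCall]:
    """Call TSSs on one replicon/strand from a "+"/"−" profile pair.

    Candidate positions have at least ``noise`` "+" reads and a positive
    count difference; the one-sided p-value is the Skellam upper tail of
    the difference under the estimated rates.  Positions passing the alpha
    (and fold-enrichment) gates are fused when at most ``merge`` nt apart,
    keeping the position with the largest difference (ties resolved
    5'-most: smallest coordinate on "+", largest on "−").
    """
    params = params or DetectionParams()
    _check_pair(plus, minus)

    cand = np.array(
        sorted(p for p, k in plus.counts.items() if k >= params.noise), dtype=np.int64
    )
    if cand.size == 0:
        return []
    kp = np.array([plus.counts[int(p)] for p in cand], dtype=np.int64)
    km = np.array([minus.get(int(p)) for p in cand], dtype=np.int64)
    diff = kp - km
    pos_mask = diff > 0
    cand, kp, km, diff = cand[pos_mask], kp[pos_mask], km[pos_mask], diff[pos_mask]
    if cand.size == 0:
        return []

    if params.rate_policy == "windowed":
        lam_p, lam_m = windowed_rates(plus, minus, cand, params.window)
        pvals = np.array(
            [skellam_sf(int(d), float(a), float(b)) for d, a, b in zip(diff, lam_p, lam_m)]
        )
    else:
        if rates is None:
            rates = estimate_rates(plus, minus, policy=params.rate_policy)
        pvals = np.asarray(skellam_sf(diff, rates.lambda_plus, rates.lambda_minus))

    keep = pvals <= params.alpha
    if params.min_fold is not None:
        keep &= kp >= params.min_fold * np.maximum(km, 1)
    cand, kp, km, diff, pvals = cand[keep], kp[keep], km[keep], diff[keep], pvals[keep]
    if cand.size == 0:
        return []

    # fuse runs of kept positions at most `merge` nt apart
    calls: List[TssCall] = []
    run_start = 0
    for i in range(1, cand.size + 1):
        if i < cand.size and cand[i] - cand[i - 1] <= params.merge:
            continue
        sl = slice(run_start, i)
        run_diff = diff[sl]
        best = np.flatnonzero(run_diff == run_diff.max())
        # tie -> 5'-most
        j = run_start + (best[0] if plus.strand == "+" else best[-1])
        calls.append(
            TssCall(
                replicon=plus.replicon,
                position=int(cand[j]),
                strand=plus.strand,
                k_plus=int(kp[j]),
                k_minus=int(km[j]),
                p_value=float(pvals[j]),
                condition=plus.condition,
            )
        )
        run_start = i
    return calls


def call_tss_all(
    plus_profiles: Dict[Tuple[str, str], EndProfile],
    minus_profiles: Dict[Tuple[str, str], EndProfile],
    params: Optional[DetectionParams] = None,
) -> List[TssCall]:
    """Run :func:`call_tss` over every (replicon, strand) pair present."""
    params = params or DetectionParams()
    calls: List[TssCall] = []
    for key in sorted(set(plus_profiles) | set(minus_profiles)):
        replicon, strand = key
        plus = plus_profiles.get(key) or EndProfile(
            replicon=replicon, strand=strand, library_kind="plus_lib"
        )
        minus = minus_profiles.get(key) or EndProfile(
            replicon=replicon, strand=strand, library_kind="minus_lib",
            condition=plus.condition, replicate=plus.replicate,
        )
        calls.extend(call_tss(plus, minus, params))
    return calls
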