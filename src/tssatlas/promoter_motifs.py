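"""Promoter window construction and OOPS EM motif discovery.

For each primary (P / IP) TSS a 20-nt positive window is cut at a fixed
TSS-relative offset: [-20, -1] for the −10 element, [-35, -16] for the −35
element (the window ending 15 nt upstream of the TSS, where the −35 box
sits given the canonical ~17-nt spacer).  A negative set of 20-nt windows
at [+100, +119] inside the transcribed region provides the background.

The motif finder is a single-motif "one occurrence per sequence" (OOPS)
expectation–maximization: every positive sequence is assumed to contain
exactly one motif instance at an unknown offset; the E-step computes each
sequence's posterior over start positions under the current position
weight matrix versus the background, the M-step re-estimates the PWM from
posterior-weighted counts with a Dirichlet pseudocount.  Differential
enrichment is realized by a negative-set background, a discriminative
k-mer initialization, and a label-permutation score test.  Window sets are
written as plain FASTA, so they can equally be fed to MEME.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import AnnotatedTss, GenomeSet, reverse_complement

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class MotifWindowSpec:
    """TSS-relative offset intervals (closed, 1 nt units; 0 is the TSS)."""

    name: str
    positive_offsets: Tuple[int, int]
    negative_offsets: Tuple[int, int] = (100, 119)

    def __post_init__(self):
        pa, pb = self.positive_offsets
        na, nb = self.negative_offsets
        if pb - pa != nb - na:
            raise ValueError("positive and negative windows must have equal length")
        if pa <= 0 <= pb:
            raise ValueError("positive window must exclude the TSS itself (offset 0)")

    @property
    def width(self) -> int:
        a, b = self.positive_offsets
        return b - a + 1

    @classmethod
    def minus10(cls) -> "MotifWindowSpec":
        return cls("minus10", (-20, -1))

    @classmethod
    def minus35(cls) -> "MotifWindowSpec":
        return cls("minus35", (-35, -16))


def _window_sequence(
    genome: GenomeSet, replicon: str, position: int, strand: str, offsets: Tuple[int, int]
) -> Optional[str]:
    a, b = offsets
    if strand == "+":
        lo, hi = position + a, position + b
    else:
        lo, hi = position - b, position - a
    if lo < 1 or hi > genome.lengths[replicon]:
        return None
    return genome.subsequence(replicon, lo, hi, strand)


def extract_window_sets(
    tss_list: Sequence[AnnotatedTss],
    genome: GenomeSet,
    spec: MotifWindowSpec,
) -> Tuple[List[str], List[str], int]:
    """Strand-aware positive and negative window sets for a TSS list.

    Returns (positive, negative, n_skipped); a TSS is skipped from a set
    when its window runs off the replicon.  Order follows the input list.
    """
    if not tss_list:
        raise ValueError("empty TSS list")
    positives: List[str] = []
    negatives: List[str] = []
    skipped = 0
    for a in tss_list:
        c = a.call
        pos_seq = _window_sequence(genome, c.replicon, c.position, c.strand, spec.positive_offsets)
        neg_seq = _window_sequence(genome, c.replicon, c.position, c.strand, spec.negative_offsets)
        if pos_seq is None or "N" in pos_seq:
            skipped += 1
        else:
            positives.append(pos_seq)
        if neg_seq is not None and "N" not in neg_seq:
            negatives.append(neg_seq)
    return positives, negatives, skipped


def write_fasta_set(seqs: Sequence[str], path: str, prefix: str = "seq") -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(seqs, start=1):
            fh.write(f">{prefix}_{i}\n{s}\n")


# ---------------------------------------------------------------------------
# OOPS EM
# ---------------------------------------------------------------------------

@dataclass
class PwmModel:
    width: int
    theta: np.ndarray  # 4 x width, columns sum to 1
    background: np.ndarray  # 4-vector
    consensus: str
    information_content: np.ndarray  # bits per column vs uniform, in [0, 2]
    log_likelihood: List[float] = field(default_factory=list)  # penalized trace
    plain_log_likelihood: List[float] = field(default_factory=list)
    iterations: int = 0


def _encode(seqs: Sequence[str]) -> List[np.ndarray]:
    out = []
    for i, s in enumerate(seqs):
        try:
            out.append(np.array([_BASE_INDEX[b] for b in s.upper()], dtype=np.int64))
        except KeyError as e:
            raise ValueError(f"sequence {i} contains a non-ACGT base: {e}")
    return out


def base_composition(seqs: Sequence[str], pseudocount: float = 1.0) -> np.ndarray:
    counts = np.full(4, pseudocount)
    for s in seqs:
        for b in s.upper():
            if b in _BASE_INDEX:
                counts[_BASE_INDEX[b]] += 1
    return counts / counts.sum()


def _kmer_counts(seqs: Sequence[np.ndarray], width: int) -> Dict[Tuple[int, ...], int]:
    counts: Dict[Tuple[int, ...], int] = {}
    for s in seqs:
        for j in range(len(s) - width + 1):
            key = tuple(s[j : j + width])
            counts[key] = counts.get(key, 0) + 1
    return counts


def _discriminative_init(
    pos: Sequence[np.ndarray],
    neg: Sequence[np.ndarray],
    width: int,
    match_prob: float = 0.7,
) -> np.ndarray:
    """Seed the PWM with the k-mer most enriched in the positive set."""
    pc = _kmer_counts(pos, width)
    nc = _kmer_counts(neg, width) if neg else {}
    n_pos = max(sum(pc.values()), 1)
    n_neg = max(sum(nc.values()), 1)
    best_key, best_score = None, -np.inf
    for key in sorted(pc):  # sorted -> deterministic tie-break
        score = np.log((pc[key] / n_pos) + 1e-9) - np.log((nc.get(key, 0) / n_neg) + 1e-9)
        if score > best_score:
            best_key, best_score = key, score
    theta = np.full((4, width), (1.0 - match_prob) / 3.0)
    for k, b in enumerate(best_key):
        theta[b, k] = match_prob
    return theta


def oops_em(
    positives: Sequence[str],
    width: int,
    background: Optional[np.ndarray] = None,
    negatives: Sequence[str] = (),
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
    pseudocount: float = 0.25,
) -> PwmModel:
    """Fit a single-motif OOPS model by EM.

    ``background`` defaults to the negative-set base composition (uniform
    if no negatives are given).  The trace recorded in
    ``model.log_likelihood`` is the penalized (maximum a posteriori)
    objective that the pseudocounted M-step maximizes; it is non-decreasing
    across iterations.  The plain data log-likelihood is kept alongside.
    EM stops at ``max_iter`` or when the objective improves by less than
    ``tol``.
    """
    if width < 4:
        raise ValueError("width must be >= 4")
    for i, s in enumerate(positives):
        if len(s) < width:
            raise ValueError(f"sequence {i} ({s!r}) is shorter than the motif width {width}")
    pos = _encode(positives)
    neg = _encode(negatives) if negatives else []
    if background is None:
        background = base_composition(negatives) if negatives else np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    background = background / background.sum()
    log_bg = np.log(background)

    theta = _discriminative_init(pos, neg, width)
    trace: List[float] = []
    plain: List[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        log_theta = np.log(theta)
        ll = 0.0
        counts = np.zeros((4, width))
        for s in pos:
            m = len(s) - width + 1
            # log-odds of placing the motif at each start
            w = np.empty(m)
            for j in range(m):
                win = s[j : j + width]
                w[j] = log_theta[win, np.arange(width)].sum() - log_bg[win].sum()
            wmax = w.max()
            z = np.exp(w - wmax)
            zsum = z.sum()
            z /= zsum
            # seq log-lik = bg log-lik of the whole seq + logmeanexp of odds
            ll += log_bg[s].sum() + wmax + np.log(zsum) - np.log(m)
            for j in range(m):
                win = s[j : j + width]
                counts[win, np.arange(width)] += z[j]
        penalty = pseudocount * np.log(theta).sum()
        trace.append(ll + penalty)
        plain.append(ll)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            break
        theta = counts + pseudocount
        theta /= theta.sum(axis=0, keepdims=True)

    consensus = "".join(BASES[i] for i in theta.argmax(axis=0))
    ent = -(theta * np.log2(np.clip(theta, 1e-300, None))).sum(axis=0)
    ic = 2.0 - ent
    return PwmModel(
        width=width,
        theta=theta,
        background=background,
        consensus=consensus,
        information_content=ic,
        log_likelihood=trace,
        plain_log_likelihood=plain,
        iterations=n_iter,
    )


# ---------------------------------------------------------------------------
# Differential enrichment score
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    statistic: float
    p_value: float
    n_permutations: int
    positive_scores: np.ndarray
    negative_scores: np.ndarray


def best_window_score(pwm: PwmModel, seq: str) -> float:
    """Maximum log2-odds (PWM vs background) over all windows of the sequence."""
    s = _encode([seq])[0]
    if len(s) < pwm.width:
        raise ValueError("sequence shorter than motif width")
    lo = np.log2(pwm.theta) - np.log2(pwm.background)[:, None]
    cols = np.arange(pwm.width)
    return float(
        max(lo[s[j : j + pwm.width], cols].sum() for j in range(len(s) - pwm.width + 1))
    )


def score_enrichment(
    pwm: PwmModel,
    positives: Sequence[str],
    negatives: Sequence[str],
    n_permutations: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Mean best-window score difference with a label-permutation p-value."""
    pos_scores = np.array([best_window_score(pwm, s) for s in positives])
    neg_scores = np.array([best_window_score(pwm, s) for s in negatives])
    stat = float(pos_scores.mean() - neg_scores.mean())
    pooled = np.concatenate([pos_scores, neg_scores])
    n_pos = len(pos_scores)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        if perm[:n_pos].mean() - perm[n_pos:].mean() >= stat:
            hits += 1
    p = (1 + hits) / (n_permutations + 1)
    return EnrichmentResult(stat, p, n_permutations, pos_scores, neg_scores)


def text_logo(pwm: PwmModel) -> str:
    """Plain-text logo: consensus with per-column information content."""
    lines = [
        "pos  " + " ".join(f"{i + 1:>5d}" for i in range(pwm.width)),
        "cons " + " ".join(f"{c:>5s}" for c in pwm.consensus),
        "bits " + " ".join(f"{b:>5.2f}" for b in pwm.information_content),
    ]
    for i, base in enumerate(BASES):
        lines.append(f"p({base})" + " ".join(f"{v:>5.2f}" for v in pwm.theta[i]))
    return "\n".join(lines)
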