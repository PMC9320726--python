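"""Promoter window geometry and OOPS EM motif recovery."""

import numpy as np
import pytest

from tssatlas.core import AnnotatedTss, GenomeSet, TssCall, reverse_complement
from tssatlas.promoter_motifs import (
    MotifWindowSpec,
    best_window_score,
    extract_window_sets,
    oops_em,
    score_enrichment,
)


def annotated(pos, strand="+", replicon="chr"):
    call = TssCall(replicon, pos, strand, 50, 1, 1e-9)
    return AnnotatedTss(call=call, labels=("P",), utr_length=30, leaderless=False)


@pytest.fixture()
def genome():
    rng = np.random.default_rng(4)
    return GenomeSet({"chr": "".join(rng.choice(list("ACGT"), size=400))})


def test_minus10_window_plus_strand(genome):
    pos, neg, skipped = extract_window_sets([annotated(100)], genome, MotifWindowSpec.minus10())
    assert pos == [genome.subsequence("chr", 80, 99)]
    assert neg == [genome.subsequence("chr", 200, 219)]
    assert skipped == 0


def test_minus10_window_minus_strand(genome):
    pos, neg, _ = extract_window_sets(
        [annotated(300, strand="-")], genome, MotifWindowSpec.minus10()
    )
    assert pos == [reverse_complement(genome.subsequence("chr", 301, 320))]
    assert neg == [reverse_complement(genome.subsequence("chr", 181, 200))]
    # a minus-strand TSS near the replicon start has no downstream window
    _, neg_edge, _ = extract_window_sets(
        [annotated(100, strand="-")], genome, MotifWindowSpec.minus10()
    )
    assert neg_edge == []


def test_off_edge_windows_skipped_and_counted(genome):
    pos, neg, skipped = extract_window_sets(
        [annotated(10), annotated(100)], genome, MotifWindowSpec.minus35()
    )
    assert skipped == 1
    assert len(pos) == 1


def test_empty_tss_list_rejected(genome):
    with pytest.raises(ValueError, match="empty"):
        extract_window_sets([], genome, MotifWindowSpec.minus10())


def test_window_extraction_strand_mirror(genome):
    spec = MotifWindowSpec.minus10()
    L = genome.lengths["chr"]
    mirrored = GenomeSet({"chr": reverse_complement(genome["chr"])})
    fwd, _, _ = extract_window_sets([annotated(100, "+")], genome, spec)
    rev, _, _ = extract_window_sets([annotated(L + 1 - 100, "-")], mirrored, spec)
    assert fwd == rev


# ---------------------------------------------------------------------------
# OOPS EM
# ---------------------------------------------------------------------------

def test_identical_planted_word_is_em_fixed_point():
    seqs = ["GGGGTATAATGGGGG"] * 20
    model = oops_em(seqs, width=6, negatives=["G" * 15] * 20, seed=0)
    assert model.consensus == "TATAAT"


def test_short_sequence_raises_naming_it():
    with pytest.raises(ValueError, match="sequence 1"):
        oops_em(["ACGTACGT", "ACG"], width=6)


def _planted_dataset(n=200, corruption=0.15, seed=0):
    """GC-rich 20-mers each carrying one corrupted copy of TATAAT."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    bg_p = np.array([0.16, 0.34, 0.34, 0.16])
    motif = "TATAAT"
    pos_set, neg_set = [], []
    for _ in range(n):
        seq = rng.choice(bases, size=20, p=bg_p)
        start = rng.integers(0, 20 - 6 + 1)
        for k, b in enumerate(motif):
            seq[start + k] = b if rng.random() >= corruption else rng.choice(bases)
        pos_set.append("".join(seq))
        neg_set.append("".join(rng.choice(bases, size=20, p=bg_p)))
    return pos_set, neg_set


def test_planted_motif_recovered_and_trace_monotone():
    pos_set, neg_set = _planted_dataset()
    model = oops_em(pos_set, width=6, negatives=neg_set, seed=0)
    matches = sum(a == b for a, b in zip(model.consensus, "TATAAT"))
    assert matches >= 5
    trace = np.array(model.log_likelihood)
    assert (np.diff(trace) >= -1e-9).all()
    assert ((model.information_content >= 0) & (model.information_content <= 2)).all()
    assert np.allclose(model.theta.sum(axis=0), 1.0, atol=1e-9)


def test_em_deterministic_given_seed():
    pos_set, neg_set = _planted_dataset(n=50)
    a = oops_em(pos_set, width=6, negatives=neg_set, seed=1)
    b = oops_em(pos_set, width=6, negatives=neg_set, seed=1)
    assert a.consensus == b.consensus
    assert np.array_equal(a.theta, b.theta)


# ---------------------------------------------------------------------------
# differential enrichment
# ---------------------------------------------------------------------------

def test_null_enrichment_is_flat():
    pos_set, _ = _planted_dataset(n=60, seed=3)
    model = oops_em(pos_set, width=6, negatives=pos_set, seed=0)
    res = score_enrichment(model, pos_set, pos_set, n_permutations=200, seed=0)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value > 0.05


def test_planted_enrichment_significant():
    pos_set, neg_set = _planted_dataset()
    model = oops_em(pos_set, width=6, negatives=neg_set, seed=0)
    res = score_enrichment(model, pos_set, neg_set, n_permutations=1000, seed=0)
    assert res.statistic > 0
    assert res.p_value <= 0.01


def test_single_sequence_sets_reduce_to_score_difference():
    pos_set, neg_set = _planted_dataset(n=30, seed=5)
    model = oops_em(pos_set, width=6, negatives=neg_set, seed=0)
    a, b = pos_set[0], neg_set[0]
    res = score_enrichment(model, [a], [b], n_permutations=50, seed=0)
    assert res.statistic == pytest.approx(
        best_window_score(model, a) - best_window_score(model, b)
    )
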