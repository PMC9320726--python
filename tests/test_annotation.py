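"""Classification against a literal interval-scan oracle, UTRs and summaries."""

import numpy as np
import pytest

from tssatlas.core import Feature, FeatureTable, GenomeSet, TssCall
from tssatlas.tss_annotation import (
    ClassParams,
    InternalConsistencyError,
    classify,
    classify_all,
    compute_utr,
    summarize,
)

GENE = FeatureTable([Feature("chr", 1000, 2000, "+", "gene", "gA")])


def probe(pos, strand="+"):
    return TssCall("chr", pos, strand, 10, 0, 0.0)


@pytest.mark.parametrize(
    "pos,strand,labels,utr",
    [
        (900, "+", ("P",), 100),
        (1500, "+", ("I",), None),
        (1500, "-", ("Ai",), None),
        (2020, "-", ("Ad",), None),
        (970, "-", ("Ad",), None),  # margin on the gene's upstream side
        (600, "+", ("O",), None),  # 400 nt upstream > 250 window
        (1000, "+", ("P", "I"), 0),  # on the start codon: leaderless gene TSS
    ],
)
def test_classification_rules(pos, strand, labels, utr):
    ann = classify(probe(pos, strand), GENE)
    assert ann.labels == labels
    assert ann.utr_length == utr
    if utr is not None:
        assert ann.leaderless == (utr <= 9)


def test_utr_arithmetic_both_strands():
    gene_plus = Feature("chr", 1000, 2000, "+", "gene", "g1")
    assert compute_utr(probe(936), gene_plus) == 64
    assert compute_utr(probe(1000), gene_plus) == 0
    gene_minus = Feature("chr", 1500, 2000, "-", "gene", "g2")
    assert compute_utr(probe(2084, "-"), gene_minus) == 84


def test_negative_utr_is_internal_consistency_error():
    gene = Feature("chr", 1000, 2000, "+", "gene", "g1")
    with pytest.raises(InternalConsistencyError):
        compute_utr(probe(1200), gene)


# ---------------------------------------------------------------------------
# brute-force oracle equivalence
# ---------------------------------------------------------------------------

def oracle_classify(pos, strand, feats, params):
    """Literal exhaustive scan over all TSS x feature pairs."""
    labels = set()
    p_best = None
    for f in feats:
        if f.replicon != "chr":
            continue
        if f.strand == strand:
            off = f.start - pos if strand == "+" else pos - f.end
            if 0 <= off <= params.primary_window:
                labels.add("P")
                if p_best is None or off < p_best:
                    p_best = off
            if f.start <= pos <= f.end:
                labels.add("I")
        else:
            if f.start <= pos <= f.end:
                labels.add("Ai")
            elif pos < f.start and f.start - pos <= params.antisense_margin:
                labels.add("Ad")
            elif pos > f.end and pos - f.end <= params.antisense_margin:
                labels.add("Ad")
    if not labels:
        labels = {"O"}
    return labels, p_best


def random_instances(seed, n):
    rng = np.random.default_rng(seed)
    for _ in range(n):
        feats = []
        for i in range(rng.integers(1, 20)):
            start = int(rng.integers(1, 9_500))
            length = int(rng.integers(50, 1500))
            feats.append(
                Feature("chr", start, min(start + length, 10_000),
                        rng.choice(["+", "-"]), "gene", f"g{i}")
            )
        pos = int(rng.integers(1, 10_001))
        strand = str(rng.choice(["+", "-"]))
        yield pos, strand, feats


def test_classify_matches_bruteforce_scan_exactly():
    params = ClassParams()
    for pos, strand, feats in random_instances(seed=17, n=1000):
        ann = classify(probe(pos, strand), FeatureTable(feats), params)
        want, p_best = oracle_classify(pos, strand, feats, params)
        assert set(ann.labels) == want, (pos, strand)
        assert ann.utr_length == p_best
        assert len(ann.labels) >= 1
        if "O" in ann.labels:
            assert ann.labels == ("O",)


def mirror(pos, strand, feats, L=10_000):
    mpos = L + 1 - pos
    mstrand = "-" if strand == "+" else "+"
    mfeats = [
        Feature(f.replicon, L + 1 - f.end, L + 1 - f.start,
                "-" if f.strand == "+" else "+", f.type, f.locus_tag)
        for f in feats
    ]
    return mpos, mstrand, mfeats


def test_strand_mirror_invariance():
    params = ClassParams()
    for pos, strand, feats in random_instances(seed=23, n=300):
        ann = classify(probe(pos, strand), FeatureTable(feats), params)
        mpos, mstrand, mfeats = mirror(pos, strand, feats)
        mann = classify(probe(mpos, mstrand), FeatureTable(mfeats), params)
        assert ann.labels == mann.labels
        assert ann.utr_length == mann.utr_length


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def test_empty_summary_is_all_zero():
    s = summarize([])
    assert s["per_replicon"].empty or s["per_replicon"]["n_tss"].sum() == 0
    assert s["class_counts"]["count_multilabel"].sum() == 0
    assert s["utr_hist"]["count"].sum() == 0
    assert s["utr_stats"] == {
        "n": 0, "mean": 0.0, "median": 0.0, "leaderless_fraction": 0.0,
    }


def test_class_fraction_recovery_from_planted_mix():
    from tssatlas.synthetic_data import SimulationConfig, plant_tss, simulate_genome

    mix = {"P": 0.4, "I": 0.2, "A": 0.3, "O": 0.1}
    cfg = SimulationConfig(genome_length=(400_000,), class_mix=mix, n_tss=1000,
                           n_processed_sites=0, seed=13)
    genome, features = simulate_genome(cfg)
    truth = plant_tss(features, cfg)
    calls = [TssCall(r.replicon, r.position, r.strand, 10, 0, 0.0) for r in truth.records]
    s = summarize(classify_all(calls, features), genome)
    frac = dict(zip(s["class_counts"]["label"], s["class_counts"]["frac_exclusive"]))
    for cls, want in mix.items():
        se = np.sqrt(want * (1 - want) / 1000)
        assert abs(frac[cls] - want) <= 3 * se, cls
    assert s["per_replicon"]["n_tss"].sum() == 1000
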