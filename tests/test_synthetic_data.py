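"""Generator contracts: composition, geometry, truth consistency, count laws."""

import numpy as np
import pytest

from tssatlas.synthetic_data import (
    SimulationConfig,
    TruthTable,
    plant_tss,
    profiles_for,
    simulate_genome,
    simulate_libraries,
    utr_length_pmf,
)
from tssatlas.tss_annotation import classify_all
from tssatlas.core import TssCall


def _probe_calls(truth):
    return [
        TssCall(r.replicon, r.position, r.strand, 10, 0, 0.0) for r in truth.records
    ]


def test_determinism_byte_identical():
    cfg = SimulationConfig(genome_length=(30_000,), n_tss=40, n_processed_sites=5,
                           n_conditions=1, n_replicates=1, seed=42)
    runs = []
    for _ in range(2):
        g, f = simulate_genome(cfg)
        truth = plant_tss(f, cfg)
        profs = simulate_libraries(truth, g, cfg)
        runs.append((dict(g.items()), f.records, truth.records,
                     {k: p.counts for k, p in profs.items()}))
    assert runs[0] == runs[1]


def test_zero_density_gives_empty_feature_table():
    cfg = SimulationConfig(genome_length=(10_000,), gene_density=0.0)
    _, features = simulate_genome(cfg)
    assert len(features) == 0


def test_unreachable_density_raises():
    with pytest.raises(ValueError, match="unreachable"):
        simulate_genome(
            SimulationConfig(genome_length=(50_000,), gene_density=0.9999)
        )


def test_gc_content_within_three_binomial_sd(default_sim):
    cfg, genome, _ = default_sim
    seq = genome["replicon_1"]
    n = len(seq)
    gc = (seq.count("G") + seq.count("C")) / n
    sd = np.sqrt(0.68 * 0.32 / n)
    assert abs(gc - 0.68) <= 3 * sd


def test_gene_density_near_target(default_sim):
    cfg, genome, features = default_sim
    genic = sum(f.length for f in features)
    assert abs(genic / 100_000 - 0.833) <= 0.05


def test_all_leaderless_config_gives_zero_utrs():
    cfg = SimulationConfig(genome_length=(30_000,), class_mix={"P": 1.0},
                           leaderless_fraction=1.0, n_tss=30, n_processed_sites=0)
    _, f = simulate_genome(cfg)
    truth = plant_tss(f, cfg)
    assert all(r.utr_length == 0 and r.is_leaderless for r in truth.records)


def test_utr_mixture_pmf_mean_is_calibrated():
    cfg = SimulationConfig()
    pmf = utr_length_pmf(cfg)
    grid = np.arange(cfg.utr_max + 1)
    mixture_mean = (1 - cfg.leaderless_fraction) * float((grid * pmf).sum())
    assert mixture_mean == pytest.approx(84.0, abs=1e-6)


def test_planted_utr_sample_mean_near_84():
    cfg = SimulationConfig(genome_length=(400_000,), class_mix={"P": 1.0},
                           n_tss=500, n_processed_sites=0, seed=5)
    _, f = simulate_genome(cfg)
    truth = plant_tss(f, cfg)
    utrs = [r.utr_length for r in truth.records]
    assert abs(np.mean(utrs) - 84) <= 10


def test_orphans_far_from_all_gene_starts():
    cfg = SimulationConfig(genome_length=(60_000,), class_mix={"O": 1.0},
                           n_tss=30, n_processed_sites=0, seed=2)
    _, f = simulate_genome(cfg)
    truth = plant_tss(f, cfg)
    starts = [(x.replicon, x.strand, x.five_prime()) for x in f]
    for r in truth.records:
        assert r.planted_class == "O"
        for rep, strand, s in starts:
            if rep == r.replicon and strand == r.strand:
                downstream = s - r.position if strand == "+" else r.position - s
                assert not (0 <= downstream <= 250)


def test_planted_sites_respect_min_spacing(default_sim):
    cfg, genome, features = default_sim
    truth = plant_tss(features, cfg)
    by_track = {}
    for r in truth.records:
        by_track.setdefault((r.replicon, r.strand), []).append(r.position)
    for track, positions in by_track.items():
        positions.sort()
        gaps = np.diff(positions)
        assert (gaps >= cfg.min_spacing).all()


def test_classifier_reproduces_planted_classes(default_sim):
    cfg, genome, features = default_sim
    truth = plant_tss(features, cfg)
    annotated = classify_all(_probe_calls(truth), features)
    for rec, ann in zip(truth.records, annotated):
        if rec.planted_class == "O":
            assert ann.labels == ("O",)
        else:
            assert rec.planted_class in ann.labels


def test_leaderless_fraction_converges():
    cfg = SimulationConfig(genome_length=(800_000,), class_mix={"P": 1.0},
                           n_tss=1000, n_processed_sites=0, seed=8)
    _, f = simulate_genome(cfg)
    truth = plant_tss(f, cfg)
    frac = np.mean([r.is_leaderless for r in truth.records])
    se = np.sqrt(0.07 * 0.93 / 1000)
    assert abs(frac - 0.07) <= 3 * se


def test_empty_rates_give_empty_profiles():
    cfg = SimulationConfig(genome_length=(30_000,), n_tss=10, depth=0.0,
                           enrichment=10.0, background_rate=0.0,
                           n_processed_sites=0, n_conditions=1, n_replicates=1)
    g, f = simulate_genome(cfg)
    truth = plant_tss(f, cfg)
    assert simulate_libraries(truth, g, cfg) == {}


def test_truth_site_counts_follow_poisson_law():
    """Mean "+" count at a planted TSS over many seeded draws is depth*enrichment."""
    kp_sum = km_sum = 0
    n_draws = 400
    for seed in range(n_draws):
        cfg = SimulationConfig(genome_length=(5_000,), class_mix={"P": 1.0},
                               n_tss=1, n_processed_sites=0, background_rate=0.0,
                               n_conditions=1, n_replicates=1, seed=seed)
        g, f = simulate_genome(cfg)
        truth = plant_tss(f, cfg)
        profs = simulate_libraries(truth, g, cfg)
        r = truth.records[0]
        plus = profiles_for(profs, "c1", "r1", "plus_lib")[(r.replicon, r.strand)]
        minus = profiles_for(profs, "c1", "r1", "minus_lib")[(r.replicon, r.strand)]
        kp_sum += plus.get(r.position)
        km_sum += minus.get(r.position)
    se_plus = np.sqrt(500 / n_draws)
    se_minus = np.sqrt(50 / n_draws)
    assert abs(kp_sum / n_draws - 500) <= 3 * se_plus
    assert abs(km_sum / n_draws - 50) <= 3 * se_minus


def test_processed_sites_balanced_between_libraries():
    """At processed sites the +/− count difference has mean ~0."""
    diffs = []
    for seed in range(300):
        cfg = SimulationConfig(genome_length=(5_000,), class_mix={"O": 1.0},
                               n_tss=1, n_processed_sites=1, background_rate=0.0,
                               processed_site_rate=50.0,
                               n_conditions=1, n_replicates=1, seed=seed)
        g, f = simulate_genome(cfg)
        truth = plant_tss(f, cfg)
        profs = simulate_libraries(truth, g, cfg)
        rep, pos, strand = truth.processed_sites[0]
        plus = profiles_for(profs, "c1", "r1", "plus_lib").get((rep, strand))
        minus = profiles_for(profs, "c1", "r1", "minus_lib").get((rep, strand))
        diffs.append((plus.get(pos) if plus else 0) - (minus.get(pos) if minus else 0))
    se = np.sqrt(100 / len(diffs))  # var(diff) = 2 * 50
    assert abs(np.mean(diffs)) <= 3 * se


def test_truth_table_tsv_round_trip(tmp_path, default_sim):
    cfg, _, features = default_sim
    truth = plant_tss(features, cfg)
    p = tmp_path / "truth.tsv"
    truth.write_tsv(p)
    back = TruthTable.read_tsv(p)
    assert back.records == truth.records
    assert back.processed_sites == truth.processed_sites
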