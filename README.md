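# tssatlas

Genome-wide mapping of bacterial transcription start sites (TSSs) from
differential RNA-seq (dRNA-seq) 5′-end data.

dRNA-seq locates the first transcribed nucleotide of every mRNA by
comparing two libraries built from the same RNA: an enriched "+" library
in which only primary transcripts (5′-triphosphate ends) survive the
enzymatic treatment, and an untreated "−" control that additionally
contains processed 5′-monophosphate ends. A genuine TSS shows an excess
of read starts in "+" over "−" at a single genomic position; a processed
site (e.g. an RNase E cleavage product) shows similar counts in both.
`tssatlas` implements the full desk-side analysis of such an experiment
for multi-replicon bacterial genomes, with GC-rich methylotrophs as the
motivating use case:

* **Detection** — at each position the read-start counts are modelled as
  independent Poisson variables, `k⁺ ~ Pois(λ⁺)`, `k⁻ ~ Pois(λ⁻)`, with
  rates estimated over transcribed (non-empty) positions. The difference
  `d = k⁺ − k⁻` then follows a Skellam distribution, and a TSS is called
  where the one-sided tail `P(D ≥ d)` falls below α = 0.01, the "+" count
  reaches the noise floor (10 reads), and the "+"/"−" ratio shows at
  least 2-fold enrichment (the classic primary-vs-processed
  discriminator). Adjacent significant positions ≤ 1 nt apart are fused,
  keeping the largest difference.
* **Curation** — replicate consolidation, resolution of call clusters
  less than 10 nt apart with similar (≤ 2-fold) read numbers — preferring
  the position that recurs in the other culture condition, then the most
  reads — and removal of calls upstream of tRNA genes.
* **Classification** — each TSS is labelled relative to the annotation:
  primary/gene TSS (`P`, ≤ 250 nt upstream of a same-strand gene start),
  internal (`I`), antisense inside or within 30 nt of an opposite-strand
  gene (`Ai`/`Ad`), or orphan (`O`); labels accumulate (a TSS can be both
  internal to one gene and primary for the next — the "IP" class). For
  primary TSSs the 5′UTR is the distance to the start codon; 0–9 nt flags
  a leaderless mRNA.
* **Promoter motifs** — 20-nt windows at [−20, −1] (−10 element) and
  [−35, −16] (−35 element) relative to each primary TSS form positive
  sets against a [+100, +119] negative set; a one-occurrence-per-sequence
  (OOPS) EM fits a position weight matrix with a discriminative k-mer
  initialization and a label-permutation enrichment test. Window sets are
  exported as FASTA, so they can also be fed directly to MEME.
* **Reference comparison** — a packaged table of TSSs previously mapped
  in *Methylorubrum* strains by nuclease S1 protection, primer extension
  and run-off transcription (with their −35/−10 boxes and spacers)
  supports positional-offset, 5′UTR and spacer-length comparisons.
* **Synthetic data** — a generator that emulates a GC-rich (68%), dense
  (83% genic) multi-replicon genome and plants TSSs of every class with a
  calibrated 5′UTR length distribution (mean 84 nt, median 64 nt, 7%
  leaderless), paired Poisson count profiles, balanced processed sites
  and low-level background, so the whole pipeline is testable offline
  against a known truth.

## Worked example

```python
from tssatlas import (SimulationConfig, DetectionParams,
                      call_tss_all, classify_all, summarize)
from tssatlas.synthetic_data import simulate, profiles_for

cfg = SimulationConfig(genome_length=(100_000,), n_tss=200,
                       n_conditions=1, n_replicates=1, seed=7)
genome, features, truth, profiles = simulate(cfg)
calls = call_tss_all(profiles_for(profiles, "c1", "r1", "plus_lib"),
                     profiles_for(profiles, "c1", "r1", "minus_lib"),
                     DetectionParams())
annotated = classify_all(calls, features)
s = summarize(annotated, genome)
print(f"{len(calls)} TSSs called from {len(truth)} planted")
frac = dict(zip(s["class_counts"]["label"], s["class_counts"]["frac_exclusive"]))
print("class fractions:", {k: round(v, 3) for k, v in frac.items() if v == v})
stats = s["utr_stats"]
print(f"5'UTRs: mean {stats['mean']:.1f} nt, median {stats['median']:.0f} nt, "
      f"leaderless {100 * stats['leaderless_fraction']:.1f}% (n={stats['n']})")
```

prints

```
200 TSSs called from 200 planted
class fractions: {'P': 0.33, 'I': 0.19, 'A': 0.31, 'O': 0.17}
5'UTRs: mean 90.7 nt, median 76 nt, leaderless 4.5% (n=66)
```

All 200 planted TSSs are recovered at their exact positions (none of the
50 high-coverage processed sites is called), and the exclusive class
fractions reproduce the planted mix — 33% primary, 19% internal, 31%
antisense, 17% orphan. The 5′UTR summaries here are computed from only
the 66 primary TSSs of this small run, so they scatter around the
configured mean of 84 nt; at n = 2000 they converge (see below).

The same analysis is available from the shell:

```bash
tssatlas simulate --outdir sim --seed 7
tssatlas detect --plus sim/c1_r1_plus_fwd.bedgraph sim/c1_r1_plus_rev.bedgraph \
                --minus sim/c1_r1_minus_fwd.bedgraph sim/c1_r1_minus_rev.bedgraph \
                --out calls.tsv
tssatlas annotate --calls calls.tsv --features sim/features.gff3 --out-prefix tss
tssatlas run --config pipeline.yaml     # full multi-condition pipeline
```

`tssatlas profile` converts SAM/BAM alignments to strand-specific 5′-end
bedGraph pairs; `tssatlas motifs` and `tssatlas compare` run the promoter
and reference-comparison stages on an annotated TSS table.

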