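# Methods

This note documents the statistical model, the parameter choices, the
synthetic-data generator and the numerical decisions behind `tssatlas`,
in the spirit of a package reference manual. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The differential 5′-end model

A dRNA-seq experiment yields, per genomic position and strand, two read
start counts: `k⁺` from the enriched library (primary, 5′-triphosphate
ends only) and `k⁻` from the untreated control (primary plus processed
ends). Under the no-TSS null both counts are modelled as independent
Poisson draws with library-wide rates λ⁺ and λ⁻, so the difference
`D = k⁺ − k⁻` follows a Skellam distribution and the one-sided p-value
of an observed excess `d` is the tail `P(D ≥ d)` (note the inclusive
convention). The test is one-sided because the library construction
enriches primary ends in "+" only.

### Rate estimation

`estimate_rates` with the default `global_nonzero` policy averages
counts over the union of positions holding at least one read in either
library, per replicon and strand. Excluding all-zero positions is a
pragmatic answer to zero inflation: most of a bacterial genome is
untranscribed at 5′-end resolution, and including those positions would
drive the rates toward zero and make every transcribed position look
significant. A `windowed` policy computes the same statistic in a
centered sliding window (default 1000 nt) for locally varying coverage.
With no non-empty position at all, both rates are 0 and the estimate is
flagged rather than raised as an error.

### Calling gates

An emitted call must satisfy, in order:

| gate | default | rationale |
|------|---------|-----------|
| noise floor `k⁺ ≥ noise` | 10 reads | minimal support for a single-nucleotide feature |
| positive difference `d > 0` | — | one-sided test |
| Skellam tail `P(D ≥ d) ≤ α` | α = 0.01, no multiple-testing correction | the conventional stringency for this analysis |
| fold enrichment `k⁺ ≥ min_fold · max(k⁻, 1)` | 2.0 | primary-vs-processed discrimination (below) |

Runs of surviving positions at most `merge` nt apart (default 1) are
fused into one TSS, keeping the largest difference; ties resolve to the
5′-most position (smallest coordinate on "+", largest on "−").

**Why the fold gate exists.** The Skellam p-value compares a position's
count difference against the *genome-wide* rates. At a deeply covered
processed site the counts are large and balanced (`k⁺ ≈ k⁻ ≈ μ`), but
their difference fluctuates with standard deviation `√(2μ)`; for μ in
the hundreds this fluctuation alone exceeds the significance threshold
implied by typical global rates of a few reads, so a pure Skellam rule
would call a third or more of such sites on the strength of Poisson
jitter. The enrichment *ratio*, by contrast, concentrates hard around 1
at balanced sites and around the true enrichment factor at a TSS, which
is why a ≥ 2-fold "+" excess is the standard primary/processed
discriminator in dRNA-seq practice. The gate is exactly the contrast
the library chemistry encodes; `min_fold=None` disables it. The type-I
calibration of the p-values themselves is independent of this gate and
is verified on a null simulation in the acceptance suite.

### Numerical notes

`skellam_pmf`/`skellam_sf` delegate to `scipy.stats.skellam` (stable to
rates ≥ 10⁴ via scaled Bessel evaluation) and handle the boundary cases
exactly: λ⁻ = 0 reduces to the Poisson tail, λ⁺ = 0 to a reflected
Poisson, both zero to a point mass at 0. The test suite pins the tail
against a brute-force truncated double-Poisson convolution to < 10⁻⁹.

## Curation

Clusters of same-strand calls within 10 nt whose "+" counts lie within
2-fold of one another are treated as one biological start observed with
jitter: one call survives per cluster, preferring the member nearest to
(and within 10 nt of) a call in the other culture condition, then the
most reads, then the 5′-most position. The 2-fold "similar read
numbers" quantification separates jitter from genuine alternative TSSs,
which pass through untouched; the operation is idempotent. Replicates
of a condition are consolidated by union (identical positions merge
with summed counts), with an optional `both` policy requiring support
within the cluster window in each replicate. Finally, calls with a
same-strand tRNA start within 250 nt downstream are removed — the same
association window used to link primary TSSs to genes — because tRNA
loci produce abundant, heavily processed 5′ ends; the removed calls are
returned for the audit trail.

## Classification and 5′UTRs

The label rules are interval predicates on the annotation. A TSS at
position p (strand s) is `P` if a same-strand gene start lies 0–250 nt
downstream (offset 0, i.e. the TSS on the first base of the start
codon, is a leaderless gene TSS with a 5′UTR of 0); `I` if inside a
same-strand gene body; `Ai` inside an opposite-strand gene; `Ad` within
30 nt beyond either end of an opposite-strand gene (the subclass name
keys to the downstream side, but both margins carry it — the biology
distinguishes only internal from flanking antisense); `O` if nothing
else applies, exclusive of all other labels. Labels accumulate; the
nearest eligible gene is linked per label. Summaries report both
multi-label tallies and an exclusive count under the precedence
P > I > A > O. The 5′UTR of a primary TSS is `gene.start − p` on "+",
`p − gene.end` on "−"; a negative value is an internal-consistency
error, never silently clamped. The classifier is vectorized per
replicon/strand; the test suite holds it to exact agreement with a
literal scan over all TSS × feature pairs and to invariance under
reverse complementation of the whole frame.

## Promoter motif discovery

The positive window sets are `[−20, −1]` (−10 element) and `[−35, −16]`
(−35 element) relative to each primary TSS, strand-aware; "20 nt ending
15 nt upstream" places the −35 window where the canonical ~17-nt spacer
puts the −35 box. The negative set is the `[+100, +119]` window inside
the transcribed region. The single-motif OOPS EM assumes exactly one
motif occurrence per positive sequence at an unknown offset: the E-step
computes each sequence's posterior over start positions under the
current PWM against the negative-set background, the M-step
re-estimates the PWM from posterior-weighted counts with a Dirichlet
pseudocount of 0.25 per cell. Initialization is discriminative: the
exact k-mer most over-represented in the positive relative to the
negative set seeds the PWM at 0.7 match probability. Iteration stops at
200 rounds or an objective improvement below 10⁻⁶.

The recorded `log_likelihood` trace is the penalized (maximum a
posteriori) objective that the pseudocounted M-step provably increases
each round; the plain data log-likelihood is kept alongside. Per-column
information content is reported against a uniform background
(`2 − H(θ)`, in [0, 2] bits) as in sequence logos; enrichment against
the GC-rich genomic background is instead carried by the log-odds
scores. Differential enrichment is scored as the mean best-window
log₂-odds difference between positive and negative sets with a
label-permutation p-value. One caveat is inherited from fitting and
scoring on the same sequences: the permutation test will flag whatever
composition difference best separates two finite sets, so a significant
p on real windows is evidence of *some* discriminating signal, not of a
canonical promoter box; motif identity should be read from the
consensus and information content. Window sets are exported as plain
FASTA so MEME can serve as an external cross-check.

## Reference comparison

`data/reference_tss.tsv` carries the previously published TSSs for
one-carbon-metabolism genes of *Methylorubrum extorquens* (strains DM4
and AM1), *Methylobacterium organophilum* XX and *Methylophilus* sp.
DM11 — positions where mapped, 5′UTR lengths, −35/−10 boxes and spacer
lengths, by method (dRNA-seq, nuclease S1, primer extension, run-off).
Signed positional offsets (call − reference, nearest within a 5-nt
tolerance, ties to the 5′-most and flagged), 5′UTR differences and
box-spacer lengths (nucleotides strictly between the −35 end and the
−10 start, nearest in-order pair) are computed from it; spacers of
15–20 nt are flagged as typical of the bacterial consensus, anything
else as atypical.

## The synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions everything downstream is validated under.

* **Genome.** Bases i.i.d. with P(G) = P(C) = 0.34 (GC 68%). Genes and
  intergenic gaps alternate with geometric lengths (means 887 and 183 nt,
  gap mean rescaled so expected gene density is 0.833); ~2% of features
  are tRNAs of 70–90 nt; gene length is floored at 60 nt to avoid
  degenerate models. Deterministic given the seed.
* **Planted truth.** Class mix defaults to 33% primary, 19% internal,
  31% antisense (80:20 internal:downstream), 17% orphan. Each plant is
  accepted only if the package's own classifier reproduces the planted
  class (primary TSSs may additionally be internal to an upstream gene
  — the combined IP situation), no tRNA start lies within 250 nt
  downstream (so curation never removes a true plant), and all plants
  sit ≥ 25 nt apart per strand, which makes 1-nt merging and 10-nt
  cluster curation unambiguous in tests.
* **5′UTR lengths.** Leaderless TSSs (fraction 0.07) plant on the start
  codon (UTR 0). Leadered UTRs are `10 + X` with X gamma-distributed,
  truncated at 250 nt and discretized; a leaderless mRNA is *by
  definition* one with a 0–9 nt UTR, so the leadered component must
  exclude that range or the realized leaderless fraction would drift
  above its setting. Shape and scale are calibrated jointly (nested
  root-finding on the truncated distribution) so the final mixture has
  mean exactly 84 nt and median ≈ 64 nt, the two summaries such
  right-skewed distributions are reported by. The pmf is cached per
  parameter set.
* **Counts.** Per condition × replicate, a true TSS draws
  `k⁺ ~ Pois(depth · enrichment)` vs `k⁻ ~ Pois(depth)` (defaults 50 and
  10-fold). Processed sites (50 by default, inside gene bodies) draw
  the *same* rate in both libraries — 500 by default, ten times the TSS
  control rate, deliberately deep so that discrimination cannot hide
  behind low coverage. Background Poisson noise (rate 0.2/position)
  covers gene bodies plus planted 5′UTRs on their own strand,
  reproducing the zero-inflation the rate estimator must handle. An
  optional condition-specificity probability drops truth sites from a
  condition; the default 0 makes both conditions share all sites.
* **What it does not model.** No read-level simulation (no FASTQ, no
  sequencing errors, no poly(A) artifacts), no operon structure, no
  condition-dependent expression levels, and no planted promoter boxes
  in the genomic sequence — motif recovery is validated on dedicated
  planted-motif sequence sets instead. Passing tests therefore
  demonstrate correctness of the statistics and the bookkeeping under
  the stated generative assumptions, not performance on real libraries,
  where rate heterogeneity and processing artifacts are harsher.

## Problem sizes and experiment design

The validation experiments use desk-scale problem sizes chosen to give
tight statistical tolerances: the null calibration uses 10⁵ positions;
detector recovery uses a 100-kb genome with 200 planted TSSs; class-mix
recovery uses 1000 TSSs on 400 kb; 5′UTR/leaderless recovery uses 2000
primary TSSs on 2.4 Mb, i.e. ≈ 0.9 TSSs per gene — the density regime
of a real bacterial TSS map. At several TSSs per gene the 25-nt spacing
constraint preferentially rejects plants near gene starts and biases
recovered UTR lengths upward by a few nt; keeping the planted density
realistic keeps that artifact below the reporting tolerances.

## Known limitations

* The Skellam null with globally estimated rates is miscalibrated at
  strong local coverage heterogeneity; the windowed policy and the fold
  gate mitigate but do not remove this, which is also why real dRNA-seq
  maps receive manual curation.
* Curation quantifies "similar read numbers" as ≤ 2-fold — a judgement
  call; genuinely co-active alternative TSSs spaced < 10 nt with
  near-equal usage will be collapsed to one.
* The OOPS finder fits a single motif of fixed width; no ZOOPS/ANR
  models, no multi-motif search, no MEME-style E-value calibration.
* The reference table is a transcription of previously published
  values; two of its historical UTR entries (mxaF AM1, reported as a
  167–168 range, and the sga orphan promoter rows) are recorded with
  the single most defensible reading, noted in their comment fields.
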