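# Methods

This note documents the models, numerical choices and open design
decisions behind `mirconsensus`, in the spirit of a statistical software
methods appendix. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Rank-product consensus

**Model.** Platforms are merged on the union of miRNA identifiers, each
miRNA carrying an *availability pattern* — the subset of platforms that
probe it. Within each pattern group of size G, every replicate column's
log2 ratios are ranked (average ranks on ties; rank 1 = most extreme in
the analyzed direction), and the statistic is the geometric mean of rank
ratios RP = (prod r/G)^(1/k) over the k columns. Using rank *ratios*
rather than raw ranks makes RP comparable across groups of different
size; since only p-values are pooled across groups this choice affects
nothing observable, but it is fixed for determinism. Ranks are computed
per replicate column, not per platform mean — the per-pair log2 ratios
are the unit of evidence throughout.

**Permutation null.** Each permutation shuffles every column's ranks
independently within the group; the p-value of gene g is the fraction of
null RP values (pooled over all G genes and all permutations) at or below
RP(g). Two refinements:

- When (G!)^k <= 10^6 the null is enumerated exactly. Because columns are
  permuted independently, one gene's rank vector is marginally uniform on
  {1..G}^k, so enumeration over the G^k integer rank tuples reproduces
  the pooled permutation distribution exactly at a fraction of the cost.
- The count is floored at 1: a p-value is never below the estimator's
  resolution 1/(G * n_perm) (or G^-k exhaustively), and never exactly 0.
  This keeps the null distribution super-uniform and gives a strongly
  planted gene in a noise-free simulation exactly the minimum attainable
  p of 1/(G * n_perm).

Default n_perm = 10,000 for analyses; tests and the demo pipeline use
1,000 (and the 200-simulation calibration check uses the minimum of 100),
sizes chosen so the full suite runs in minutes on one CPU while leaving
the Monte-Carlo error well below the decision thresholds.

**Directions and FDR.** Up and down are analyzed separately;
Benjamini–Hochberg step-up (via statsmodels) is applied to each
direction's p-values pooled over the union of all availability groups,
and the reported q is the smaller direction's adjusted p with a direction
flag. Groups of size 1 have no rank distribution and are reported
untestable (NaN) rather than silently dropped. The consensus rule is
strict: q < 0.05 and fold-change magnitude 2^|mean log2 ratio| > 1.2,
where the mean fold change is the geometric mean of the per-measurement
linear fold changes over all available columns (the combination rule
across platforms is a package choice; per-platform fold changes remain
available upstream).

## Read processing

**Adapter trimming.** Every start offset s is scored by aligning the
adapter prefix of length L = min(adapter length, read length - s)
ungapped against read[s:s+L]; a mismatch at read position i costs
w(i) = 1 + (L_read - 1 - i)/(L_read - 1), i.e. weight 2 at the 5' end
declining linearly to 1 at the last base. Any monotone decreasing weight
satisfies the qualitative contract ("penalize mismatches less at read
ends, where sequencing errors concentrate"); this ramp is fixed for
reproducibility. The lowest-penalty offset with penalty <= 2.5 and
L >= 5 wins, ties to the smallest s. If no offset is accepted the read is
cut down to 22 nt — truncation only; shorter reads pass through, since
the canonical mature miRNA length is a ceiling, not a pad target.

**Mapping.** Inserts are compared by Hamming distance at every ungapped
offset inside the mature window padded by 5 nt on each side (so templated
trims and extensions align), with at most 2 mismatches ("fewer than 3").
If the full insert finds no hit it is 3'-shortened one base at a time to
a floor of 16 nt, admitting variable product sizes. Exactly one locus at
the best distance is an assignment; two or more is AMBIGUOUS; none is
UNMAPPED. N bases never match. Only unambiguous assignments are counted.

**Normalization.** Effective library size = raw library size x a
trimmed-mean-of-M-values factor against a reference sample, trimming 30%
of M and 5% of A (plain, unweighted), factors rescaled to geometric mean
1. The reference sample is the one whose 75th count percentile (scaled by
library size) is closest to the cross-sample mean, with ties broken by
sample id — a label-order-invariant rule, so normalization commutes with
relabeling. Degenerate cases: an all-zero sample is an error; a sample
pair with no co-positive loci gets factor 1.

## isomiR classification and filters

A mapped unique sequence is anchored at its best ungapped offset within
the padded precursor window (fewest mismatches; ties resolved toward the
mature start, then to the smaller offset). The anchored geometry is then
read off directly:

- start offset != 0 -> 5' trim (negative values denote templated 5'
  extensions);
- 3' end short of the mature end -> 3' trim;
- trailing bases beyond the mature end that match the precursor ->
  templated 3' extension, recorded as a negative 3' trim, *not* an
  addition;
- from the first mismatching base at or beyond the mature end, the whole
  remaining tail is the non-templated 3' addition;
- mismatches within the mature span are substitutions with
  mature-relative positions.

A sequence equal to the mature is the reference class, which excludes all
others. Multi-label annotations are preserved; for percentage summaries a
read is tallied once under the precedence subst > add3 > trim5 > trim3
(the binning of mixed variants is a package choice).

**Filters.** Frequency: count > 3, strict, on raw counts before
normalization, applied to every record. Contribution: a variant must
contribute more than 10% of its locus's total *variant* (non-reference)
reads, strict. Z-score: for substitution records,
z = (x - n p) / sqrt(n p (1 - p)) with n the locus's total reads, p the
global per-base error rate supplied by the caller, and x the reads
bearing the record's *specific* nucleotide change (position plus
alternative base, pooled over records sharing it); records are kept when
z > 1.96. Pooling per specific change rather than per position is what
separates signal from noise: a genuine variant concentrates its reads on
one change and exceeds the error expectation n·p, while sequencing errors
scatter across the three alternative bases at roughly p/3 each and fall
below it. Contributions and z statistics are frozen on the records when
first computed; re-filtering a filtered set does not recompute them,
which makes the filter idempotent and monotone in the contribution
cut-off.

## Target enrichment

The observed statistic is o = |union of the regulated miRNAs' validated
targets ∩ DE gene list| — a gene targeted by several regulated miRNAs
counts once. Two null strategies, both sampling without replacement:
draw as many miRNAs as were regulated and pool their targets, or draw as
many genes as the regulated miRNAs target in total. The p-value is the
literal exceedance fraction p = #{e_i > o}/N with N = 400 by default,
strict inequality and no +1 correction. That formula is kept verbatim at
the cost of slight anti-conservativeness (ties don't count toward
significance and p can be exactly 0); the calibration check accordingly
bounds the null p <= 0.05 rate at 0.08 rather than 0.05. The 3-of-4
prediction vote filter retains (miRNA, gene) pairs present in at least 3
of the 4 supplied prediction tables, duplicates within a table counting
once.

## ddCt quantification

Technical replicates are averaged first (arithmetic mean of Ct). The
reference normalizer is the arithmetic mean of the two housekeeping Cts —
equivalent to the geometric mean of their linear quantities. Fold change
is 2^(-ddCt) with amplification efficiency fixed at 2 and no efficiency
correction. The calibrator's fold change is identically 1.

## Synthetic-data generators

The generators define the study conditions under which everything is
tested:

- **Expression matrices**: 3 platforms x 3 replicates of log2 ratios,
  300 miRNAs, each platform probing an independent Bernoulli(0.8) subset;
  unregulated entries Normal(0, 0.4), planted miRNAs Normal(±1.5, 0.4).
  Effect 1.5 log2 with sd 0.4 mirrors a clearly induced miRNA measured
  with typical inter-replicate scatter.
- **Reads**: 36-nt reads (the shorter end of the 36–41-cycle runs the
  design emulates), insert + 3' adapter + random fill, Phred+33 constant
  qualities, ACGT only. isomiR magnitudes default to trims of 1–3 nt
  uniform, single substitutions uniform over positions, and 3' additions
  of 1–2 nt whose first base is non-templated. The positional error model
  is a linear ramp from err_rate/2 at the first base to 3·err_rate/2 at
  the last — a concrete stand-in for the end-heavy error profile of
  short-read sequencers, which is not otherwise quantified. The true
  per-base error rate is a free parameter, not an estimate; 0.01 is used
  as the stress setting for the Z filter and 0.005 in the demo pipeline.
- **Target database**: each miRNA's targets are a uniform
  without-replacement sample of the gene universe; planted enrichment
  oversamples the down-regulated list by a factor (5 in tests) for a
  designated miRNA set of 8 — the enrichment geometry the method is meant
  to detect.
- **Ct tables**: two samples (calibrator, treated), two technical
  replicates, target Cts shifted by -log2(fold change) in the treated
  sample, housekeeping Cts constant up to noise. The 2.73-fold default is
  a realistic induction magnitude for a validated miRNA.

What the generators deliberately do *not* emulate: realistic miRBase
sequence content, quality-score realism, multi-lane/paired-end structure,
cross-hybridization and probe-affinity biases of real microarrays, or
count overdispersion beyond sampling. Passing tests therefore demonstrate
the correctness and calibration of the algorithms under the stated
generative model, not robustness to every artifact of real data.

## Determinism and problem sizes

Every generator and every permutation routine takes an explicit seed; the
pipeline derives one independent stream per stage by hashing the global
seed with the stage name, so stages re-run in isolation reproduce their
outputs and two runs with the same configuration are byte-identical
(verified via manifest content hashes). Test and acceptance problem sizes
— 10,000 reads for trimming exactness, 300 miRNAs x 9 columns x 1,000
permutations x 20 seeds for consensus recovery, 400 simulated studies for
enrichment calibration — were chosen as the smallest sizes at which the
Monte-Carlo error of each check is negligible relative to its decision
margin.

## Known limitations

- The mapper is ungapped and mature-window-local by design: no indels, no
  genome-wide search, no quality-aware scoring.
- The exact end-weight function and acceptance threshold of the original
  adapter-trimming heuristic are unpublished; only the qualitative
  contract (monotone decreasing weights toward the 3' end) is
  implemented, with one fixed concrete choice.
- The enrichment p-value's strict-inequality convention is slightly
  anti-conservative at the 1/N granularity, as documented above.
- Availability groups with a single miRNA are untestable and excluded
  from the consensus rather than rescued by sharing ranks across groups.
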