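# Methods

## Study design model

A pooled study is P pools of N diploid individuals (defaults P = 5,
N = 20), each pool sequenced as one library: 2N chromosomes per pool,
a singleton at within-pool frequency 1/(2N). `detectability_margin`
expresses the design rule that this frequency must clear the per-base
error rate: at N = 20 the 2.5% singleton sits 2.5–5× above a 0.5–1%
error floor. Per-individual DNA contributions are an explicit per-pool
vector so that pooling imbalance — a named failure mode of pooled
designs — is a tunable quantity rather than an assumption; the default
is equimolar.

## Synthetic data

The simulator emulates the statistical structure of a pooled
target-capture experiment; it does not model chemistry.

* **Truth sets.** Each site draws a population alt-chromosome count m
  from a site frequency spectrum over 1..2NP (default neutral, mass ∝
  1/m, which places ~50% of variants at ≤5% population frequency) and
  scatters the m carriers across pools by multivariate hypergeometric
  sampling. A site is an indel with probability 100/2849 (the indel
  share of the study-scale variant set); indel lengths are 1–18 bp,
  short-skewed (∝ 1/length); representation is VCF-style with an
  anchor base, left-normalized.
* **Coverage.** Per-site, per-pool depth is Poisson–gamma (negative
  binomial) around the pool mean (default 683×). The gamma shape
  defaults to 2.0, solved numerically so that ~94% of sites fall
  within [mean/5, 5·mean] — the observed spread of in-solution capture
  coverage. Passing `coverage_dispersion=None` fixes depth exactly,
  used for experiments conditioned on a coverage stratum. A 2%
  read-loss factor stands in for mapping/base-quality filtering
  (`raw_depth` vs `depth`).
* **Reads and errors.** Each read samples an individual with
  probability proportional to its DNA fraction (optionally
  Dirichlet-perturbed: `imbalance` is the symmetric-Dirichlet
  concentration; smaller = more imbalance) and one of its two
  chromosomes uniformly. Substitution errors flip a base to each
  alternative at e/3; indel errors occur per read at 10⁻⁴ (no
  published per-read indel error rate exists for this platform;
  the value is a config parameter). The per-site error rate wobbles
  around the configured mean with CV 0.1, and the reported
  `mean_error_prob` equals that quality-derived rate — base qualities
  are assumed calibrated, which is what makes the caller's error test
  honest in simulation.
* **Gapped reads.** `simulate_reads_with_indels` builds the indel
  haplotype, emits 55 bp reads from either haplotype, and, for a
  configurable fraction of indel-overlapping reads, emits a gapless
  left-anchored alignment instead of the correct gapped one —
  reproducing the failure mode of independent per-read alignment that
  the realignment module exists to repair.

What the simulator does **not** model: GC- or probe-dependent capture
bias, duplicate reads, paired-end structure, quality miscalibration,
strand artifacts, and systematic error hotspots. Synthetic results
therefore bound what the method can do when its error model is
correct; they do not certify performance on real libraries, where
FDR in particular is driven by exactly the artifacts omitted here.

## Realignment

Candidates are the distinct left-normalized indels occurring in ≥ 2
gapped alignments. Each candidate yields one alternate reference
window (flank = read length on both sides) with the indel applied and
an invertible coordinate map. Every read overlapping a window is
scored at every gapless offset (+1 match / −3 mismatch, quality-blind)
and its alignment replaced only when the best placement is *strictly*
better than the current alignment's score; ties keep the original.
Insertion bases of a gapped alignment score as matches, so a correct
gapped alignment exactly ties its gapless equivalent on the alternate
haplotype and is never churned. One haplotype per candidate indel is
built; windows with several interacting indels are out of scope.

## Variant calling

All thresholds live in config; defaults:

| parameter | default | meaning |
|---|---|---|
| `min_alt` | 4 | alt reads required in the best pool |
| `alpha_error` | 10⁻⁴ | per-pool binomial error-test level |
| `alpha_pool` | 10⁻³ | cross-pool contingency level |
| mapq/baseq floors | 20 / 10 | read/base filters (strict `<` discards) |
| `indel_error_rate` | 10⁻⁴ | per-read spurious indel rate |

PASS requires: max per-pool alt ≥ 4, min per-pool binomial tail ≤
alpha_error, and cross-pool p ≤ alpha_pool — where the cross-pool test
is the Fisher-rule exact multivariate-hypergeometric test when total
alt ≤ 20 and a 10,000-draw Monte-Carlo χ² otherwise (stream keyed to
the sorted margins, so calls are invariant to pool relabeling). With
one informative pool the cross-pool test is not applicable and the
decision rests on the error test. A variant at similar frequency in
every pool is homogeneous by construction, so the contingency gate is
bypassed when each informative pool independently clears the support
floor and the error test. The alphas were calibrated on error-only
simulations (683× pools, 0.5–1% error) to hold the per-site false-call
rate below alpha_error; measured rate ≈ 2–6 × 10⁻⁵ per site, i.e. a
handful of false calls per 600 kb of target. Multi-allelic pileups
test each non-reference allele separately. The cross-pool p-value is
only computed where it can affect the decision (reported NaN
elsewhere); `full_stats=True` forces it everywhere.

## Frequency estimation and evaluation

The frequency estimate is the raw read fraction per pool (no
error-rate correction is subtracted), combined across pools by depth
weighting; a rounded companion snaps to the 1/(chromosomes-with-data)
grid. Accuracy is reported as per-pool r² and as the fraction of
pool-site observations within 1/40 and 1/20 of truth — r² alone is
sign-blind and can be 1.0 for a badly biased estimator, hence both.

Evaluation matches calls to truth by exact normalized (contig,
position, ref, alt) keys, per pool: a call is assigned to pool p when
that pool shows ≥ 4 alt reads *and* a per-pool error p ≤ 10⁻⁴. The
second condition is this package's choice (the assignment rule of the
original multi-pool caller is not published): without it, deep
non-carrier pools collect enough error reads at real variants' sites
to register as pool-level false positives. Coverage strata keep a
site in stratum t when pool depth / N ≥ t (defaults 10× and 30× per
individual); the ≤5% frequency class uses true within-pool frequency
on the truth side and the estimated read fraction for false positives,
which have no truth. FNR = FN / stratum truth total; FDR = FP / total
calls, with an arbitrary boolean "known-variant" flag splitting FPs
(the stand-in for catalogue membership, which is out of scope).

## Cost model

Prep is $275 per library ($75 prep + $200 capture), so pooling divides
prep cost by the pool size (20). Sequencing cost is linear in raw
gigabases — no rounding up to whole flowcells, matching fractional
per-Gb pricing — at $11,150 per 200 Gb. The raw-overhead factor
converting on-target bases to raw sequenced bases defaults to 8.0,
the single value consistent with all published sequencing-cost cells
(it absorbs the ~55% on-target rate, duplicates and coverage
non-uniformity). The displayed fold difference is the ratio of the
table-rounded totals, which is how the published 7.5× (3 Mb, 4,000
samples) arises: the unrounded ratio is 7.449.

## Numerical and reproducibility choices

* All randomness flows from one integer seed through named substreams
  (`_rng.substream`), so each stage is independently reproducible and
  pipeline outputs are bitwise-identical across runs.
* Binomial tails come from `scipy.stats.binom.sf`; the test suite
  checks them against explicit pmf summation at 10⁻¹² relative.
* Exact contingency p-values sum all tables no more probable than the
  observed one, with a 10⁻⁹ log-tolerance for float ties; the
  Monte-Carlo branch uses (1 + #{T ≥ T_obs}) / (n + 1).
* Degenerate inputs: zero-depth pools are dropped from the cross-pool
  test (NaN when < 2 remain); sites with zero alt reads everywhere are
  not candidates; an all-zero-depth site yields a no-estimate
  sentinel; identity "indels" are rejected at construction.
* Realignment tie-breaks: equal scores keep the original alignment;
  among equal alt placements the leftmost representable one wins.

## Problem sizes

The shipped experiments use 2,849 truth sites for study-scale runs,
10⁵ error-only sites for calibration, 1,000 replicates for singleton
power (at fixed 600× pool depth — sensitivity at a coverage stratum is
conditional on reaching that stratum), and ≥ 10⁴ reads for the
realignment-vs-enumeration sweep. These sizes make the stochastic
summaries stable to roughly one part in thirty while keeping the whole
suite in the low minutes.

## Known limitations

Single-contig simulations; one alternate haplotype per candidate
indel; no base-quality-aware alignment scoring; no genotype assignment
within pools; FDR on real data is not predictable from these
simulations (see the simulator's non-goals above); and the caller is a
principled reimplementation of pool-aware testing, not a reproduction
of any published caller's likelihood.
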