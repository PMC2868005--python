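# Methods

## The model

`motifenrich` treats motif enrichment analysis as measuring association
between an in-silico binding score and an experimental signal.  The input is
a set of DNA sequences S_1..S_n with signals Y_1..Y_n (typically microarray
fluorescence p-values transformed to a larger-is-stronger scale).  A motif M
is a position probability matrix over A,C,G,T; its score matrix is the
log-likelihood ratio log2(p_j(a)/0.25) — the denominator is fixed at the
uniform distribution, as is conventional for PWM construction, while the
*scanning null* used for match p-values is a separate zero-order background
estimated from the scanned sequences themselves.

### Affinity functions

- **MC** counts strand-positions on both strands whose discretized LLR score
  has p-value ≤ t_m.  P-values come from the exact distribution of the
  integer-discretized score of a random w-mer drawn i.i.d. from the
  background, computed by position-wise convolution of the per-position
  score distributions.
- **AMA** is the arithmetic mean of the likelihood ratio (not its log) over
  all valid strand-positions on both strands.  The reverse strand is scored
  by applying the motif to each window's reverse complement, so AMA is
  invariant under reverse-complementing the input sequence.
- **RMA** divides AMA by the product over positions of the best single-base
  likelihood ratio, bounding it in [0, 1] for use in regression.

Windows containing any non-ACGT character are skipped entirely by every
affinity function; the AMA denominator counts only the windows actually
scored.  Sequences with no valid window are dropped from the mapped dataset
with a warning; under MC such sequences are retained with a count of 0,
since a match count is well defined even without a scoreable window.

### Association functions

Fisher exact, multi-hypergeometric (mHG) and rank-sum return the reciprocal
of a one-sided p-value; Clover and linear regression return non-statistical
scores; Spearman returns the rank correlation.  Conventions that the
literature leaves open and that are fixed here:

- **Rank-sum direction**: points are ranked by X with rank 1 = largest, and
  the lower tail of the positive set's rank-sum is tested, so small p (large
  F) means the high-signal set holds unusually high affinities.
- **mHG tail**: with counts capped to [0..c] (c = 2 by default, matching the
  MC alphabet {0,1,2}), "more extreme" is defined as a total matched count
  Σ j·k_j at least as large as observed — the natural multi-category
  extension of Fisher's one-sided enrichment tail.  With c = 1 the statistic
  is identical to Fisher at t_x = 1 (and is computed by the same code path).
- **Clover score**: the mean over subset sizes j of the mean size-j subset
  product of the positive set's AMA values, i.e. (1/P) Σ_j e_j(a)/C(P,j)
  with e_j the elementary symmetric polynomials, evaluated by the stable
  per-point recursion d(i,j) = [j·a_i·d(i−1,j−1) + (i−j)·d(i−1,j)]/i.
- **Linear regression**: Y = mX + b fitted by least squares over *all*
  points, no outlier handling; F = sgn(m)/E with E the mean squared
  residual.  The standard pairing is the RMA affinity against
  Y = −log10(p).
- **Permutation p-values**: p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm),
  permuting Y against X with a seeded generator.
- **Direction**: enrichment is the default; `--direction negative` reports
  depletion via exact tail identities rather than approximations — Fisher
  tests the upper tail of the "no match" indicator (equal to the lower tail
  on matches), mHG reverses the capped count scale (x → c − x), rank-sum
  reflects the ranks (x → max x − x), Clover reverses the multiplicative
  affinity scale (x → 1/x), and the regression/Spearman scores are negated.

### Partition maximization

YFP evaluates F at one fixed threshold; YCPM maximizes over all thresholds
whose positive set contains only points with raw p ≤ b; YUPM maximizes over
every distinct observed signal value.  Candidate thresholds are the distinct
observed Y values, so equal-signal points always fall on the same side of a
partition and every distinct nonempty positive set is evaluated exactly
once.  By construction R_yupm ≥ R_ycpm(b) ≥ R_yfp(t) for any admissible
(b, t); the implementation preserves this *exactly* (see Numerical choices).
Ties in F are broken toward the smaller positive set, which is deterministic
and biologically conservative.  A count-based cap on the positive set
(`max_positive`, the DRIM-style constraint of at most 300 positives) is
available as a candidate filter.

The PASTAA-style score sorts points by affinity and by signal and minimizes
the Fisher tail p of the overlap of the top-i-by-X and top-j-by-Y sets over
the full (i, j) grid, both cutoffs capped at 1000 (the cap is applied to
both axes; the original description only documents the positive-set cap, and
the symmetric reading is adopted).  Overlap counts are maintained
incrementally, so the grid costs O(max_x·max_y).

### Evaluation

PRA = 100·(R_k − 1)/(N − 1) maps the designated motif's rank onto [0, 100].
Ties receive average ranks, so a method that scores every motif identically
lands at PRA 50 rather than at either extreme.  Datasets where a signal
threshold yields an empty positive set are skipped — the skip is a property
of the partition, not of any motif, so it is all-or-none per dataset — and
excluded from mean/median aggregation.  Threshold sweeps record the
retained-dataset count per cell, since stricter thresholds retain
monotonically fewer datasets.

## Synthetic data

The generator emulates a scaled-down yeast-intergenic ChIP-chip experiment:
500 sequences of length 500, i.i.d. background (uniform by default), of
which 50 "positives" carry 1–3 sites sampled from the planted motif's
probability matrix (not consensus-only, so MC and AMA disagree
realistically), inserted at non-overlapping positions on a uniformly chosen
strand.  Positive signals are p = 10^(−U) with U ~ Uniform(3, 10), spanning
the 10⁻³..10⁻¹⁰ threshold range that partition methods sweep; negatives draw
p ~ Uniform(0, 1].  The default planted motif is an 8-bp yeast-TF-like PWM
with 0.85 consensus-base probability per column (~11 bits); decoy libraries
draw columns from a symmetric Dirichlet (concentration 1 by default).
Everything is deterministic given the seed.

What this does *not* emulate: probe-level noise and replicate structure,
nucleosome/accessibility effects, sequence composition bias, correlated
probes, or motif libraries with realistic redundancy (paralogous motif
families).  Passing the planted-recovery tests therefore demonstrates
correctness and calibration of the statistics, not field performance on real
ChIP data.

## Numerical choices

- **Score discretization**: LLRs are multiplied by `scale` (default 1000
  units per log2) and rounded before convolution, bounding total rounding
  error at w/scale log2 units.  Oracle tests compare against exhaustive
  4^w-word enumeration.
- **Log-domain scores**: 1/p overflows double precision long before the
  tests lose resolution, and Clover subset products overflow for large
  positive sets, so every p-value-based result carries log10(F), the Clover
  DP runs in log space, and ranking/maximization compare in the log domain.
- **Hypergeometric tails** are computed by a vectorized term-ratio series
  with per-cell convergence and renormalization decisions.  Because each
  cell's result depends only on its own table, a fixed-threshold evaluation
  and the corresponding cell of a maximization sweep are bit-identical —
  this is what makes the nesting invariant exact rather than approximate.
  The same care applies to the other sweeps: rank-sums are recomputed with
  the same masked summation as single calls, and the Clover sweep's
  incremental DP replays exactly the prefix computation of a fixed call
  (positives are processed in descending-signal order everywhere).
- **Rank-sum regimes**: exact enumeration (integer DP over doubled ranks,
  handling average-rank ties) for n ≤ 20, else a normal approximation with
  tie-corrected variance and 0.5 continuity correction.  The approximation
  is within 10% relative error of the exact tail in the central regime
  (p ≳ 0.02) at the switch point; like any normal approximation it diverges
  in relative terms deep in the tail.
- **Degenerate inputs**: an exact linear fit (E = 0) is capped at
  sgn(m)/10⁻¹², flagged `exact_fit`; zero background frequencies are floored
  at 10⁻⁴ and renormalized; probabilities read from motif files are floored
  at 10⁻⁶; decoy Dirichlet columns are floored at 10⁻³ (raw Dirichlet draws
  can carry vanishing probabilities that explode the discretized score
  support).
- **LLR base**: log2 throughout; the base only rescales thresholds.

## Design decisions

- The pseudocount (default 0.25) is spread uniformly over the four bases,
  matching the uniform LLR denominator.
- Both-strand scanning scores the reverse strand by applying the motif to
  each window's reverse complement (the AMA-tool convention); both strands
  share one null distribution, which is exact because all backgrounds
  produced here are strand-symmetric.
- Overlapping MC matches all count; no greedy masking.
- Signal transforms: 1/p for all methods except linear regression, which
  uses −log10(p).  All transforms are strictly decreasing in p, so
  partition thresholds can be stated on the raw p-value scale (as in the
  CLI and this package's reporting) and converted internally.
- Default t_m = 0.001 for MC scanning; default fixed threshold
  t_y = 0.001 — the smallest threshold at which typical ChIP-style datasets
  keep a nonempty positive set.
- Problem sizes in the shipped study (50 datasets × 500 sequences × 30
  motifs; 500 calibration replicates at n = 200 with 999 permutations) were
  chosen as the smallest sizes at which the planted-recovery and
  calibration properties are stable across seeds.

## Known limitations

- Only zero-order backgrounds; no higher-order Markov models, IUPAC motifs,
  or motif trimming.
- The mHG fast path is specialized to c = 2 (the standard MC alphabet); a
  general-c grid evaluation exists but scales poorly for large c.
- The normal-approximation rank-sum tail is unreliable deep in the tail
  (use n ≤ 20 data or permutation p-values when extreme rank-sum p-values
  matter).
- Clover p-values by background randomization, two-sided tests and
  multiple-testing correction across motifs are out of scope; motif
  rankings use raw scores.
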