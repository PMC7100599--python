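# Methods

`lncsurv` implements a four-stage framework for studying long non-coding
RNAs (lncRNAs) in expression compendia that measure only protein-coding
genes: (1) infer each lncRNA's *regulon* — the coding genes whose expression
tracks it — from an RNA-seq-like cohort where both are measured; (2) use the
regulon as a weighted, signed gene-set to impute the lncRNA's relative
expression in coding-only cohorts; (3) screen the imputed expression for
survival association per cohort and combine cohorts by weighted meta-analysis;
(4) test the resulting hazardous/protective lncRNA sets for copy-number and
growth-essentiality enrichment.  A synthetic-data module plants all of this
structure with known ground truth so every stage has a parameter-recovery
test.

## Regulon inference

The network is anchored on a declared set of lncRNA regulators.  For every
regulator–gene pair, mutual information (MI, in nats) is estimated on
within-vector ranks, so both estimators are exactly invariant under strictly
monotone transforms of either input:

- **Equal-frequency binning** (default for network construction): each
  vector's ranks are cut into `bins` equal-count bins (default 4) and the
  plug-in MI of the joint bin table is computed.  Its closed form makes it
  exactly testable against hand-computed tables.
- **Adaptive partitioning** (default for `estimate_mi`): the rank plane is
  recursively split into quadrants while a chi-square test (3 d.f.,
  alpha = 0.05) rejects uniformity; leaves contribute
  `p * log(p / (w_x * w_y))`.  This follows the character of the standard
  network-inference tools but is a per-pair recursion, so the vectorised
  binned estimator does the heavy lifting in bootstrap runs.

A constant vector carries no information and scores MI = 0 rather than
raising.

Edges must exceed the empirical `(1 - p)` quantile (default p = 0.01) of a
permutation null: MI between independently permuted rank vectors of the same
length.  Bootstrap resampling duplicates samples, and duplicated joint
observations bias plug-in MI upward, so inside the bootstrap loop ties are
broken with a vanishing jitter and the threshold is calibrated on null pairs
subjected to the same with-replacement resampling (`mi_threshold(...,
bootstrap=True)`).  Skipping this calibration floods each bootstrap network
with an order of magnitude more spurious edges.

The **data processing inequality** prunes indirect edges: in every fully
connected triple the weakest edge is removed when its MI falls below
`(1 - tolerance)` times the smaller of the other two (default tolerance 0).
Removal decisions are simultaneous against the input network, verified
against exhaustive triangle enumeration.

**Bootstrap consensus** (default 100 bootstraps): each bootstrap resamples
samples with replacement, thresholds MI, applies DPI, and records surviving
edges.  An edge is kept when its support count is significant under a
Poisson null whose mean is total edge occurrences / distinct edges,
Bonferroni-corrected at `consensus_p` (default 0.05); its final MI is the
mean over supporting bootstraps.  With a single bootstrap the consensus is
that bootstrap's network.  Note the Poisson rule needs enough bootstraps to
separate signal from the null mean — with very small networks where true
edges dominate occurrences, support ceilings below ~15 bootstraps cannot
reach Bonferroni significance; desk-scale runs here use 30+.

Each regulator's regulon weights are its edge MIs divided by the regulon's
maximum MI (so the top target has weight exactly 1); the sign is the sign of
the Pearson correlation between regulator and target expression.  Targets
with exactly zero correlation are dropped (measure-zero).  Weights split
into an "up" profile (positive signs) and a "down" profile (magnitudes of
negative signs); a profile with fewer than `min_genes` (default 20) nonzero
entries is invalid and contributes nothing, and a lncRNA with two invalid
profiles is non-inferable.  The threshold applies per profile: one failing
profile does not disqualify the lncRNA.

## Expression imputation (iExpr)

For one sample, genes are sorted by expression descending (ties broken by
lexicographic gene id, for determinism).  For a non-negative weight profile
with support S:

- foreground `F(k) = sum_{i<=k, i in S} w_i m_i / sum_{i in S} w_i m_i`,
- background `B(k) = #{i<=k : i not in S} / #{i not in S}`,

and the statistic is `F(k*) - B(k*)` at `k* = argmax_k |F(k) - B(k)|`
(first k on exact ties).  The magnitudes `m_i` are the descending rank
scores `N - rank_i` by default, which makes the statistic an exact function
of the within-sample ranking — imputed values are bit-identical under any
strictly monotone per-sample transform, the property that justifies applying
profiles across microarray platforms.  Weighting by raw `|expression|` is
available as `value_mode="abs_expression"` for users who want
magnitude-sensitive scores at the cost of that exact invariance.

pre-iExpr = (up-profile deviation) − (down-profile deviation); an invalid
profile contributes 0, so pre-iExpr lies in [-2, 2].

The permutation null re-draws the gene-to-expression assignment uniformly
(default 1,000 permutations).  Because the statistic depends only on which
ranks carry the profile genes, each null draw samples `|S_up| + |S_down|`
distinct rank positions jointly and evaluates the deviation at the 2m break
points of the piecewise-linear `F - B` — algebraically identical to the full
scan (oracle-tested to 1e-12) but O(m log m) per draw instead of O(N).

Normalisation divides pre-iExpr by a null summary.  The default
`sign_conditional` mode divides a non-negative score by the mean of the
*positive* null values and a negative score by |mean of the negative null
values|: the plain null mean sits near zero with mixed signs and dividing by
it is numerically explosive.  The literal plain-mean division is retained as
`mode="literal_mean"`.  A zero denominator yields iExpr 0 with a warning
flag.

Profile genes absent from the target matrix are dropped without
renormalising the remaining weights (the max-weight anchor is retained); a
lncRNA retaining under 50% of its support is flagged `low_coverage`.

## Survival screen and meta-analysis

Each lncRNA's (inferred or actual) expression is scored per dataset by a
univariate Cox proportional-hazards model.  The solver maximises the Efron
tie-corrected partial likelihood by damped Newton iteration (|step| < 1e-8
or 50 iterations; steps halve while the likelihood worsens and are clipped
to ±5), with the standard error from the observed information.  It is
implemented in-package because the screen fits one model per lncRNA per
dataset and the batch path runs one vectorised Newton update for all genes
simultaneously; it is cross-checked in the tests against both lifelines and
brute-force 1-D likelihood maximisation.  A multivariate variant
(complete-case, collinearity-checked) covers covariate-adjusted models such
as age/size/stage/ER/HER2 adjustment in breast-cancer cohorts.

Per-dataset z = beta / SE; z > 0 marks a hazardous lncRNA (higher expression,
higher mortality), z < 0 protective.  Dataset z-scores within one
cancer-type family combine by weighted Stouffer's method,
`meta_z = sum(w_i z_i) / sqrt(sum w_i^2)`, with `w_i` = dataset sample size
(as the method is usually quoted in this setting; `sqrt_n`, the
variance-optimal choice, is an option).  The robust variant recomputes the
meta z after dropping the dataset with the largest |z| (ties break to the
lexicographically first dataset id) and is undefined with fewer than two
datasets.  Meta p-values are two-sided normal; BH and Bonferroni adjustments
are applied within one family.  Kaplan–Meier comparison dichotomises at
iExpr 0 (exact zeros fall in the low group) and uses the standard two-group
log-rank test (via lifelines), emitting the per-group survival step tables.

## Downstream analyses

Named classification schemes reproduce the threshold sets used at different
stages: raw meta p <= 0.1 (essentiality overlap), FDR <= 0.01 (CNA analysis),
FDR < 0.05 prognostic vs FDR > 0.1 non-prognostic strata (cross-dataset
validation, middle band excluded), raw p < 0.05 and FDR <= 0.1 variants for
low-powered cohorts.  All enrichments use the one-sided (upper-tail) Fisher
exact test with the sample odds ratio `ad/bc` (infinite when b·c = 0,
flagged).

Per-patient CNA enrichment counts lncRNAs: a lncRNA is "altered" when any
segment with the direction's call overlaps its interval (0-based half-open,
any nonzero intersection; strand ignored).  The 2×2 table is {concordant
class, discordant class} × {altered, not} — hazardous pairs with
amplification, protective with deletion — and a patient is tested only when
every cell has at least 5 counts; BH runs across tested patients within one
direction.  Gene-level CNA signal is the unweighted mean of overlapping
segment signals (length-weighted as an option), exactly as the procedure is
usually stated.

Subtype exploration selects the top-k (default 500) rows by across-sample
variance (ties by gene id), z-transforms rows, and clusters gene-wise with
Euclidean distance and complete linkage (scipy); zero-variance rows are
excluded with a warning.

## Synthetic-data generator

The generator is the package's study design, not a tuning knob; defaults
define the standard cohort used in the tests:

- 50 lncRNAs over 5,000 coding genes, 200 RNA-seq-like samples; regulon
  sizes Poisson(30) clipped at >= 5, disjoint target sets, true weights
  uniform on [0.5, 1], 30% negative edges.
- Latent activity (standard normal per lncRNA × sample) drives everything:
  lncRNA rows are activity + N(0, 0.5); each planted target is
  sign · weight · signal_strength · activity + an independent per-entry
  component (sd 0.3) + N(0, 0.5) noise.  Non-target genes are pure noise.
- Microarray-like cohorts (default 3 × 150 samples) regenerate coding
  expression from fresh activities, drop lncRNA rows (a configurable few can
  be retained, emulating available probes), and apply a per-dataset affine
  jitter — rank-preserving, hence invisible to the imputation by
  construction, and asserted as a test.
- Survival: exponential times with hazard
  `baseline_hazard · exp(sum beta_l · activity_l)` (default baseline 0.1,
  |beta| = 0.8 for 5 hazardous and 5 protective lncRNAs) and independent
  exponential censoring (rate 0.05); `censoring_rate=0` means no censoring.
  This is the simplest generator consistent with proportional hazards.
- CNA: a 5-chromosome synthetic genome (10 Mb each) tiled by 500 kb
  segments, one lncRNA per segment.  With probability `cna_bias` (default
  0.9) the segment over a hazardous locus is amplified in patients with
  positive activity and the segment over a protective locus deleted in
  patients with negative activity; all segments also receive symmetric
  background events (rate 0.15) so the per-patient contingency tables have
  counts in every cell.
- Essentiality: the planted essential set (defaults to the hazardous set)
  receives mean phenotype score −1 across 4 replicates with Gaussian noise;
  p-values from a one-sample t-test.

What the generator does *not* emulate: count-based noise and library-size
effects (inputs are accepted as already normalised), probe-level microarray
artifacts, overlapping/correlated regulons, copy-number breakpoint
processes, and batch structure beyond affine jitter.  Passing tests
therefore demonstrate correctness of the machinery and recoverability under
the planted model, not performance on real cohorts.

## Problem sizes and numerical choices

The test suite and the acceptance script run the standard 50 × 5,000 × 200
cohort with 100 bootstraps and 1,000 permutations (a few minutes end to
end); calibration checks use 1,000 null lncRNAs across 3 cohorts of 100;
sign-consistency uses 100 replicates at n = 300; enrichment recovery uses
80 lncRNAs (40 hazardous / 40 protective) across 200 patients.  These sizes
were chosen as the smallest at which the binomial/Monte-Carlo tolerances in
the tests are comfortably stable.

Ties: expression ranking breaks ties by gene id; robust-meta by dataset id;
clustering follows scipy's deterministic merge order; the running-sum argmax
takes the first maximising k.  Seeds: every stochastic routine takes an
explicit seed; nested stages derive independent child streams with
`numpy.random.SeedSequence` spawn keys, so results are independent of
evaluation order and worker count.

## Known limitations

- The adaptive-partition MI estimator is not used inside bootstrap consensus
  (per-pair Python recursion is too slow at genome scale); the two
  estimators are cross-checked on small data instead.
- The Poisson consensus rule is undefined for a single bootstrap
  (special-cased) and weak below ~15 bootstraps at desk scale.
- Exponential survival times satisfy proportional hazards by construction;
  the screen's behaviour under violations is untested here.
- The per-patient CNA test counts lncRNAs, not segments; with very few
  prognostic lncRNAs the >= 5-count rule excludes nearly all patients.
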