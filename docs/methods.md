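# Methods

## Pair difference profiles

Each sample is a table of per-CpG log2 ratios of methylated vs unmethylated
hybridization signal.  A pair profile subtracts the extracranial from the
intracranial measurement per CpG and orders the result by chromosome and
position (natural chromosome order chr1..chr22, chrX, chrY; position ties
broken by CpG id).  CpGs missing in either sample are dropped — the HMM has
no missing-data emission — so the profile is the intersection of the two
samples' measured CpGs.  Sample positions are 1-based (array-manifest
convention); all interval annotations are 0-based half-open BED and are
converted at the boundary.

## The three-state HMM

States (-, =, +) model decreased, unchanged and increased methylation in
the intracranial metastasis.  Emissions are state-specific Gaussians;
observations are the chromosome-ordered difference values, with each
chromosome of each pair treated as an independent sequence that restarts
from the start distribution.

Initialization: means (-3, 0, 3), SDs (0.3, 0.5, 0.3), start
(0.1, 0.8, 0.1).  Transition rows are initialized to (0.1, 0.8, 0.1) as
well (only the start distribution is prescribed; mirroring it in the rows
keeps the chain's prior marginal at the start value).

### MAP training

All sequences of all pairs share one parameter set (joint training keeps
calls comparable across patients).  The penalized objective is

    F(theta) = log L(theta)
               - sum_i kappa_i (mu_i - m_i)^2 / (2 sigma_i^2)
               - sum_i [ (alpha_i + 1) log sigma_i^2 + beta_i / sigma_i^2 ]

with prior centers m_i and s_i equal to the initialization,
beta_i = (alpha_i + 1) s_i^2 (so the variance-prior mode is exactly s_i^2),
kappa = (1e6, 1e3, 1e6) and alpha = (5e5, 10, 5e5).  The M-step maximizes
the expected complete-data version of F coordinate-wise and exactly:

    mu_i      <- (kappa_i m_i + sum_t gamma_t(i) x_t) / (kappa_i + sum_t gamma_t(i))
    sigma_i^2 <- (S_i + kappa_i (mu_i - m_i)^2 + 2 beta_i)
                 / (sum_t gamma_t(i) + 2 (alpha_i + 1))

where S_i = sum_t gamma_t(i)(x_t - mu_i)^2 uses the updated mean.  The
kappa (mu - m)^2 term in the variance numerator is required for exact
coordinate ascent of F — dropping it would void the monotonicity guarantee
the training trace asserts; with the default huge kappa it is numerically
negligible.  Setting kappa_i = 0 removes the mean prior and alpha_i = 0 is
the flat-variance sentinel; with both off the updates are plain
maximum-likelihood Baum-Welch (verified against an independent
log-space ML-EM implementation to 1e-8).  Start and transition parameters
get maximum-likelihood updates from expected counts (no prior).

Numerics: scaled forward-backward with a per-position max-shift of the
emission log-densities (stable for sequences of 1e5+ CpGs even with
collapsing variances), batched across sequences; variance floor 1e-6;
convergence at relative penalized log-likelihood change < 1e-4 or 500
iterations (non-convergence is flagged on the trace, not raised).  After
training, states are relabeled if needed so mu(-) < mu(=) < mu(+), guarding
against label switching when the priors are weakened.

### Decoding and conformity

Posterior decoding assigns each CpG the state with maximal marginal
posterior; an exact tie resolves to "=" (no alteration is claimed without a
posterior majority).  Conformity between two call sets is the percentage of
shared CpGs with identical states; within- vs between-patient conformity is
compared by a one-sided Wilcoxon rank-sum test (exact enumeration of group
assignments with midranks for combined n <= 10, normal approximation with
tie correction otherwise).  Note the exact one-sided p uses the standard
P(W >= w_obs) convention, so the p-values of the test and its
group-swapped mirror sum to 1 plus the null mass at the observed statistic.

## Autocorrelation

rho(k) is the exact Pearson correlation of the sequence against itself at
positional lag k (per-lag means and variances, computed via cumulative sums
and an FFT cross-term), per chromosome; aggregation is median over
chromosomes within a pair, then median over pairs.  The null band permutes
values within each chromosome (preserving lengths and value distributions)
and reports per-lag quantiles (0.5, 25, 75, 99.5%) over the permutation
replicates.  Default max lag 100.

## Clustering stability

Samples are compared by Manhattan distance over shared CpGs (robust in high
dimension) and clustered with Ward's minimum-variance linkage in the
ward.D2 convention (scipy's `linkage(..., "ward")` on the condensed
distance matrix; verified against a hand-written Lance-Williams ward.D2
oracle).  Stability uses the multiscale feature bootstrap: features are
resampled with replacement at relative sizes r in {0.5, ..., 1.4}; BP is
the recovery proportion at r = 1; AU fits z(BP_r) = d sqrt(r) + c/sqrt(r)
by weighted least squares (binomial delta-method weights) and reports
100 Phi(c - d).  A node recovered in every replicate at every scale is
reported BP = AU = 100; a node never recovered has AU undefined with
BP = 0; a degenerate fit falls back to BP only.  Desk-scale default is
1000 replicates per scale (10,000 supported).

## Enrichment

The background universe of each test is every CpG measured in the pair.
For each direction, category and pair, the one-sided Fisher p is the
hypergeometric upper tail P(X >= a); q-values are Benjamini-Hochberg within
each pair-and-panel family (family scope is configurable; within-pair was
chosen since cross-pair pooling mixes very different alteration burdens).
A CpG contributes to every category it overlaps; island/shore/shelf are
mutually exclusive with open sea as complement.

## Candidates, clinical context, expression

Multiple pairs of a patient collapse per CpG by majority vote over the
- / + calls; ties (equal counts) are unchanged, so each patient votes once.
CpGs are ranked by the number of patients with a decreased or increased
consensus; genes qualify per direction when >= 1 linked promoter /
enhancer / gene-body CpG reaches the patient threshold (default: more than
50% of patients).  A gene may appear in both direction lists if distinct
CpGs support each.

Alteration burdens per patient average the per-pair - and + counts; the
balance score s = (n_inc - n_dec)/(n_inc + n_dec) lies in [-1, 1] and is
undefined (not zero) when nothing is altered.  Joins with clinical
covariates are descriptive; Spearman rank correlations are reported as
exploratory annotations only, since the design supports no formal
inference there.  Expression log2 ratios (intra minus extra, per gene and
pair, optionally averaged per patient) are tested per gene by a two-sided
one-sample t-test against zero with BH across genes; genes passing q < 0.05
are re-tested by a paired t-test on the per-patient levels.  The joint
methylation/expression classes are (decreased, up) = i, (decreased, down)
= ii, (increased, down) = iii; (increased, up) did not occur in the
motivating data and is reported as "other".

## The synthetic cohort generator

Defaults encode the cohort the analyses target: 14 patients, 24 pairs
(seven patients with multiple pairs), emission means (-3, 0, 3) and SDs
(0.3, 0.5, 0.3), start (0.1, 0.8, 0.1), and stationary altered fractions
(7.8% decreased, 3.4% increased).  The transition matrix is
A = s I + (1 - s) 1 f^T with self-transition s = 0.9, whose stationary
distribution is exactly the target fraction vector f.  Per pair, a state
path is drawn per chromosome (restarting from the start distribution) and
the difference value from the state's Gaussian.  Samples are reconstructed
as extracranial = patient baseline + pair offset and intracranial =
extracranial + emission, so the pair difference reproduces the emission
exactly while the patient baseline (SD 2.0) dominates the pair offset
(SD 0.3) — this is what makes both samples of a patient mutual nearest
neighbors and sibling leaves, the sample-level structure the clustering
stage detects.  Multiple pairs of one patient share the patient's state
path up to 5% resampled positions.  A small fraction of CpGs (0.5%)
carries recurrent alterations shared across patients (each patient is a
carrier with probability 0.75; 80% decreased), which is the cohort-level
signal behind top-ranked CpGs and candidate genes.  Annotations tile genes
(promoter / body / enhancer), island / shore / shelf with open-sea
complement, and transposon intervals along each chromosome; one pathway is
assembled from the most-altered genes (trimmed toward an odds ratio of
about 5 against background) and one from genes whose per-pair,
per-direction alteration rates deviate least from that pair's background.
The per-pair neutrality criterion matters: HMM runs correlate neighboring
body CpGs, inflating single-pair fluctuations of gene-level alteration
rates well beyond the independence expectation, and a pathway neutral only
on cohort average would be flagged too often.  Expression couples gene
shifts to the planted body-methylation direction (class i: +effect;
ii/iii: -effect; default effect 1.0, noise SD 0.3).  Clinical tables draw
months between metastases from N(4, 4^2), treatment groups with
probabilities (8, 2, 3, 1)/14 over untreated / IM-treated /
IM+EM-treated / unknown, and lognormal survival with a 1/14 alive rate.

One global seed expands into independent sub-streams (states, baselines,
annotations, clinical, expression) via `SeedSequence.spawn`, so components
can be regenerated independently and reproducibly.

What the generator does **not** emulate: array noise and probe effects
(beta-value heteroscedasticity, cross-reactive probes), realistic CpG
spacing and chromosome counts, copy-number or mutation co-variation, batch
effects, and biologically structured (rather than tiled) annotation
geometry.  Passing tests therefore demonstrate correctness of the
algorithms under the model's own assumptions, not robustness to array
artifacts — probe filtering and normalization are upstream of this
package by design.

## Problem sizes

Tests and the acceptance script run at desk scale: cohorts of 2
chromosomes with 1000-5000 CpGs each, parameter recovery at 24 pairs x 2 x
5000 CpGs, 1000 permutation replicates for the autocorrelation null, and
500-1000 bootstrap replicates per scale for clustering support.  All
quantities scale to full EPIC-array profiles (850k CpGs); the
forward-backward pass is linear in sequence length and handles 1e5+ CpGs
per chromosome in one batch.

## Known limitations

- The exact prior parameterization of the original Bayesian Baum-Welch
  implementation (a consumed Java tool) is not published; the conjugate
  scheme above reproduces its documented behavior (pinned altered states,
  adaptive unchanged state, ML in the no-prior limit) and is stated fully
  here.  The hyperparameter grid search itself is out of scope; the
  published values are defaults.
- Fisher's exact test treats CpGs as independent; under the HMM's run
  structure it is anti-conservative for small categories.  The
  within-pair BH family mitigates but does not remove this; category-level
  conclusions should weigh effect sizes, not p-values alone.
- Conformity is computed over all shared CpGs (not only altered ones), so
  its baseline is high wherever most CpGs are unchanged.
- AU values inherit the usual multiscale-bootstrap caveats for nodes whose
  BP pattern is degenerate across scales; such nodes fall back to BP.
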