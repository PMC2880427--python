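# Methods

## The analysis in brief

`bloodsig` estimates how well whole-blood expression separates disease
cases from healthy controls, in the presence of processing-batch effects,
and identifies which probes carry the separation.  The classifier is PLS1
regression on a dummy −1/+1 response with a strict score > 0 disease call;
feature selection is a jackknife t-test of the PLS coefficients across
leave-one-out segments; honesty of the accuracy estimate comes from a
second, outer leave-one-out loop around the entire selection procedure
(double cross-validation), supplemented by a label-permutation null.

## Preprocessing model and assumptions

The chain assumes log2 single-channel intensities with per-measurement
signal-to-noise ratios and scanner flags.  Fixed order and defaults:

| step | parameter | default | rationale |
|---|---|---|---|
| quality masking | `snr_min`, `flag_max` | 3, 8191 | entries with SNR < 3 or flag > 8191 are unreliable spots; both comparisons strict |
| probe filter | `max_missing_frac` | 0.05 | probes missing in > 5% of arrays carry too little information to impute |
| standardization | — | per-probe, (n−1) sd | required so KNN distances across probes are comparable |
| imputation | `knn_k` | 10 | probes are the items; Euclidean distance over mutually observed arrays, rescaled by the number of shared arrays; 1/(d+1e−6) weights; fewer than k eligible neighbours → all of them; none → probe mean |
| batch adjustment | — | per-probe batch mean-centering | one-way ANOVA batch-effect removal; batch means are estimated with the technical controls still present (all arrays of a batch) |
| control exclusion, replicate averaging, global mean subtraction | — | — | one array per subject remains; each array ends mean-zero |

Two deliberate properties worth flagging:

* **The chain runs once, on the full dataset, outside the outer CV.**
  Standardization, imputation and batch centering therefore see all
  samples, including each future held-out sample.  This mirrors the
  original workflow the package reimplements; the leakage is mild (no step
  uses the class labels) but real, and the double CV protects only against
  *selection* bias, not against this preprocessing leakage.
* **Standardization is per probe**, not per array; a per-probe scale is
  what makes probe-space KNN imputation meaningful.  Per-array level
  differences are handled at the end by global mean subtraction.
* Zero-variance probes abort `standardize()` with an error when called
  directly; inside the pipeline they are dropped with a warning, since a
  constant probe carries no class information and failing a 10k-probe run
  for one dead probe helps nobody.

## PLS1, component choice, jackknife

PLS1 is fitted by NIPALS deflation.  `fit_pls1` centers predictors (and
optionally rescales; the pipeline standardizes upstream, so the default is
centering only) and stores weights W, loadings P, y-loadings q, scores T
and the coefficient vector B_a for every truncation order a.

The cross-validation loops use an algebraically exact sample-space
(kernel) reformulation: because NIPALS scores are orthogonal, the deflation
operator is the projector I − Σ t tᵀ/c, and all per-fold quantities follow
from the training Gram matrix with one Gram-matvec per component
(`bloodsig/_kernel.py`).  Unit tests assert bit-level agreement (1e−8)
between the kernel path and explicit per-fold NIPALS refits, and the
OLS limit at full rank.

Model order: the LOO-CV misclassification rate err(a) is minimized over
a = 1..A_max, ties broken toward fewer components; A_max defaults to
min(30, n−2).  The jackknife standard error around the full-data
coefficient b is se² = ((M−1)/M) Σₘ (b − bₘ)² over the M = n LOO segments,
referred to Student t with M−1 df, two-sided.  Conventions at the
boundary: se = 0 with b ≠ 0 gives p = 0 (a perfectly stable coefficient);
b = 0 gives p = 1.  Selection keeps p ≤ α (default 0.05, configurable);
if nothing passes, the single smallest-p probe is kept and the fallback
logged, so downstream code always has a model.

Probes that are constant within a CV training split contribute exactly
zero coefficients there (centering sends them to zero), which is the
"treated as 0 in the jackknife" behaviour without a special case.

## Double cross-validation and its nulls

The outer loop removes one sample, reruns the entire inner analysis
(order choice → jackknife selection → refit → second order choice) on the
rest, and predicts the held-out sample at that fold's order.  A spy test
asserts blindness: grossly perturbing a held-out sample's expression
cannot change which probes its fold selects.

The permutation test permutes the response against the fixed processed
matrix and reruns the full double CV per permutation; empirical p-values
use the plus-one convention (never zero), and the distribution maxima are
reported alongside.  AUC uses the Mann–Whitney rank statistic with tie
half-credit, checked against brute-force pair counting.  The learning
curve subsamples each class proportionally (at least 3 per class),
repeating the double CV per subset.

## Global test and core probes

The per-probe influence Q_i = (Σⱼ x_ij (y_j − ȳ))² and the set statistic
mean(Q) are calibrated against a seeded permutation null of y (default
B = 10,000; B < 100 is rejected): z_i = (Q_i − E_i)/s_i with E, s the null
moments of that probe's own influence.  The permutation (rather than
asymptotic) version is used throughout because it makes the per-probe null
moments well-defined with no distributional assumptions.  Core probes have
z strictly above 2, split into up/down by the sign of the covariance with
the case code; zero covariance is assigned "up" with a warning (such
probes cannot pass z > 2 anyway).

## Enrichment

Over-representation of a query gene list against a user-supplied
background and GMT sets: hypergeometric upper tail (Fisher) or the EASE
variant (overlap reduced by one, floor 0), the conservative default of
annotation-clustering tools; fold enrichment
(count/|query|)/(|term∩background|/|background|); Benjamini–Hochberg FDR
across reported terms, in percent.  The recommended background is the
post-preprocessing probe universe mapped to genes.  The package ships no
annotation data; probe→symbol tables and GMT files are user inputs.

## Synthetic data generator

`generate_dataset` emulates the batched study design: 13 batches × (10
study samples + 2 technical controls) = 156 arrays by default, cases and
controls balanced 5/5 within each batch, three healthy subjects
contributing two arrays each so 127 subjects remain after replicate
averaging.  Per-probe components on the log2 scale: baseline
~N(8, 1.5²); per-batch additive shift, drawn N(0, batch_sd²) and centered
across batches so every probe's grand mean is exactly invariant to
`batch_sd`; a subject-level deviation and array-level noise that split the
within-group variance evenly (replicate arrays correlate at 0.5 on null
probes); technical controls share one reference profile.  Signal probes
get a ±`effect_size`·`noise_sd` shift in cases with random sign.  Quality:
each entry is low-SNR with probability `p_low_snr` (drawn below the
masking threshold), and a `p_bad_flag` fraction carries flag 9000.  All
streams are independent children of one seed, so changing one parameter
never reshuffles the others.

Defaults (`n_probes=2000`, `n_signal_probes=100`, `effect_size=0.5`,
`batch_sd=0.5`, `noise_sd=1`, `p_low_snr=0.01`) describe a moderate-effect
study with batch shifts half as large as biological noise — the magnitude
of real batch effects in such data is not identifiable from published
summaries, so it is a free parameter here.  What the generator does *not*
model: probe–probe correlation, intensity-dependent variance, operator or
lot effects beyond the batch term, and clinical covariate structure.
Passing tests therefore establish the *procedural* correctness and
calibration of the pipeline, not expected performance on real blood
expression data.

`simulate_plain` is the batch-free variant used by the classifier
calibration studies: standard-normal probes, balanced ±1 response, and a
planted mean shift of `effect` sd with random sign on the first
`n_signal` probes.

## Study sizes and numerical choices in the validation suite

The simulation studies in `tests/test_acceptance.py` and
`scripts/acceptance.py` use n = 40–60 samples, 200–1000 probes, and an
A_max of 5: at these sample sizes with a single planted mean-shift
component the cross-validated optimum is bracketed well below 5, and the
cap keeps the thousandfold-repeated double CV a desk-scale computation.
Permutation counts are k = 50 (tests) and k = 30 (script) per dataset, and
B = 2,000–50,000 for the global test.  Tolerances: kernel-vs-NIPALS and
PLS-vs-OLS agreement at 1e−6–1e−8 relative; batch means below 1e−10;
Monte-Carlo z-score agreement within 0.3 between B = 5,000 and a
B = 50,000 oracle.

## Known limitations

* Binary response only (PLS1); no multi-class or continuous phenotypes.
* The outer loop is leave-one-out exactly; no stratified k-fold option.
* Preprocessing leakage discussed above is reproduced by design.
* EASE/Fisher enrichment depends entirely on the user's annotation and
  gene-set files; published enrichment tables from any particular
  annotation-tool era are not numerically reproducible without that tool's
  tables.
* The jackknife p-values are selection statistics, not calibrated
  hypothesis tests after model-order selection; the package's own null
  simulations show the pooled rejection rate at α = 0.05 lands near 0.04,
  and α is configurable to absorb such calibration differences.
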