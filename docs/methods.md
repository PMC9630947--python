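# Methods

## The problem

Matching on the propensity score e(**Z**) = P(T = 1 | **Z**) discards
subjects: treated subjects with no control inside the caliper, and controls
never selected.  The retained ("in") subjects define the population the
matched estimate covers.  This package treats the matching procedure as a
black box and models its in/out decision — with a pruned classification tree
at the population level and with local linear surrogates at the individual
level.  No causal effect is estimated; the deliverable is a description of
the effective study population.

## Synthetic cohorts

Registry extracts of the kind that motivate this tool are access-restricted,
so the package generates cohorts whose ground truth is known.

- Covariates are mutually independent by default: truncated normal on a
  bounded support for continuous covariates (rejection sampling; optionally
  rounded to integers — ages are stored in whole years), multinomial with
  configurable marginals for categoricals.  No joint dependence is claimed
  by the source cohort descriptions, so none is imposed.
- Treatment is Bernoulli with logistic probability: intercept plus one
  coefficient per design column (dummy coding, first declared level as
  reference).  The generator and the logistic estimator are deliberately
  well-specified relative to each other, so coefficient recovery is a valid
  end-to-end test.
- Presets: `hn_ncdb` (n = 4042, seven covariates, 63% treated; site split
  50.4/35.5 with the published 1% rounding residual assigned to
  hypopharynx; age effect −0.2 log-odds per year, chosen so the unmatched
  group ends up ~3 years older than the matched group as in the published
  balance table; intercept calibrated numerically to the 63% treated
  fraction) and `gbm_ncdb` (n = 10128, adds surgery and year-of-diagnosis,
  83.3% treated, modeling one pairwise arm of a 3-arm comparison).
- What the generator does **not** emulate: covariate correlations, missing
  data, outcome/survival processes, site- or year-specific structure.
  Passing tests demonstrate the machinery recovers planted structure; they
  do not certify behavior on real registries with correlated covariates.

## Propensity estimators

- **Logistic**: maximum likelihood via IRLS with step-halving on likelihood
  decrease; converged when every score-equation component |X'(T − p)| <
  tol (default 1e−8, max 50 iterations).  Rank-deficient designs raise an
  error naming the collinear columns (greedy rank-growth identification).
  Separation is flagged (warning, not error) when coefficients diverge or
  any |linear predictor| exceeds 20; scores are still returned, clipped.
- **Tree**: the CART engine below with treatment as the target, pruned at
  the minimum-CV-error cp; a subject's score is the treated fraction of its
  terminal node.  When nothing separates treatment every subject receives
  one identical score — the degenerate outcome a user should check for
  before matching on such scores.
- **Bagged trees**: bootstrap resamples, per-split random feature subsets
  of size `mtry`, scores averaged over trees; deterministic given the seed.
  With one tree, no bootstrap and full `mtry` it reduces exactly to the
  unpruned single tree.
- **External**: any (subject_id, score) CSV covering each subject exactly
  once; this is how scores from estimators the package does not implement
  (covariate-balancing, SVM, boosted weighting) enter the workflow.
- All emitted scores are clipped to [1e−6, 1 − 1e−6] so logit transforms
  are always defined.

## Matching

Greedy nearest-neighbor on |score_t − score_c|, computed on the logit scale
by default (raw optional).  Treated subjects are processed in descending
score order (data order and seeded random order available); each takes its
K nearest in-caliper controls; without replacement a used control leaves
the pool.  Distance ties break to the lower control id, for determinism.
A treated subject with no in-caliper control gets no pairs.  By default a
treated subject keeps however many (1..K) controls it finds; strict
all-or-nothing K is an option.  The default caliper is 0.2 sample standard
deviations (n−1) of the logit scores, the classical recommendation; any
positive width can be given.

The describing literature states 1:1 matching *without* replacement in its
procedural box but reports K:1 *with* replacement for the analyses; both
are implemented and `with_replacement=True` is the default.  Inclusion
labels count each subject once regardless of how often a control is reused.

## The tree engine

Binary classification trees with the Gini criterion, grown by exhaustive
search: continuous cutpoints at midpoints between adjacent observed values;
categorical level bipartitions enumerated exactly up to 12 observed levels,
above that the order-by-class-proportion scan (exact for a binary outcome).
Controls mirror rpart: minsplit 20, minbucket 7, cp_grow 0.01, maxdepth 30.
A split is accepted when its Gini decrease, weighted by the node's share of
the sample and scaled by the root impurity, reaches cp_grow.  Split ties
break to the earlier column, then the smaller cutpoint.  Majority-label
ties go to "in".  Unseen categorical levels at prediction time are routed
to the child with more training subjects and flagged.  No surrogate splits:
complete data are required.

**Pruning** is weakest-link cost-complexity on the training
misclassification risk R (fraction of all training subjects): repeatedly
collapse the internal nodes minimizing α = (R(node) − R(branch)) /
(|branch leaves| − 1), yielding a nested ladder with strictly increasing α.
The rung at α = 0 is the smallest subtree with the full tree's risk —
splits that never change a majority label are already collapsed there,
since they are cost-equivalent at cp = 0 and strictly worse for any
cp > 0.  `prune(tree, cp)` returns the ladder subtree whose α-interval
contains cp, which provably minimizes R(T) + cp·|leaves| over all pruned
subtrees (verified against exhaustive enumeration in the tests).

**Cross-validation**: stratified K-fold (default 10); candidate cps are the
geometric midpoints of adjacent ladder αs (0 below the first rung, the top
α at the end); per-fold trees are grown and pruned at each candidate, and
held-out misclassifications are pooled, with a binomial standard error.
cp is selected at the *minimum* CV error (ties to the larger cp, i.e. the
smaller tree); the 1-SE rule is available as an option.

## Population explainer and balance table

The explainer is simply the tree engine applied to the in/out labels over
the original covariates, pruned at the min-CV-error cp.  Single-class
labels yield a flagged root-only tree, not an error — "no tree grew" is an
informative outcome (inclusion unexplainable from **Z**).  The balance
table reports mean (SD) with Welch's t for continuous covariates and level
counts/percentages with Pearson's χ² (df = levels − 1, no continuity
correction — the common table-one convention) for categoricals; a level
absent from both groups is dropped from the test with a note.  Report
files round to table-one style; the JSON form keeps full precision.

## Individual explainer

For one subject: draw `n_permutations` (default 5000) perturbed rows, each
feature independently resampled from its training marginal — categorical
levels by frequency; continuous values by quartile bin (edges at the
25/50/75th linear-interpolation percentiles, upper-inclusive bins), with
the raw value resampled from the training values of the drawn bin.  The
surrogate design is the same-bin/same-level indicator (row 0 = the
unperturbed subject, all ones); with the `none` discretizer continuous
features enter as training z-scores instead, perturbed by Gaussian draws.
Similarity weights are exp(−d²/w²) on the Euclidean distance from row 0 in
design space, w = 0.75·√p by default (the lime-package convention; the
unscaled distance is used, since a distance divided by √p would make this
default width vacuous).  Feature selection keeps the `n_features` (default
5) largest |coefficient| of a full weighted least-squares fit; the model is
refit on the kept indicators (optional ridge, off by default), and the
**explanation fit** is the weighted R² of that refit, defined as 0 for a
zero-variance weighted response.  A weight *supports* the predicted label
when its sign pushes the probability toward that label.  The surrogate
explains the tree's predicted in-probability, not the observed label —
the object of interest is how the model reached its decision.
Quartile binning is skipped (the feature is treated as categorical) when a
numeric column has fewer than four distinct values.

## Pipeline and reproducibility

`run_pipeline` derives each stage's seed from the global seed by a fixed
counter scheme (`SeedSequence([seed, stage])`, stages 0–4), so stages can
be re-run in isolation and two runs with one config are byte-identical —
run.log carries no timestamps for that reason.  Machine CSVs print floats
at 17 significant digits.  "auto" subject selection explains the first
correctly classified subject of each inclusion group; a group with no
correctly classified member is noted and skipped.  Cohorts loaded from CSV
infer covariate roles from dtypes, treating numeric columns with at most 5
distinct values as categorical codes so integer-coded scores survive the
round trip.

## Problem sizes in the checks

The verification suite uses brute-force oracles at small n (matching
replay at n ≤ 20; exhaustive split search at n ≤ 50; exhaustive pruned-
subtree enumeration for trees with ≤ 10 internal nodes), parameter
recovery at n = 20 000, the planted age > 80 exclusion rule at n = 4000
over 50 seeds, and the acceptance script's recovery study over 20 seeds —
sizes at which the targeted properties are already sharply testable.

## Known limitations

- Only binary treatments; multi-arm comparisons are handled as pairwise
  binary cohorts (as the `gbm_ncdb` preset does).
- Only greedy nearest-neighbor matching; optimal (network-flow), exact,
  Mahalanobis and full matching are out of scope.
- The tree engine fits binary classification only — no regression trees,
  surrogate splits or variable-importance measures.
- LIME mode is tabular only, with the single "highest weights" selection
  heuristic.
- Balance tables compare in/out groups, not treated/control balance;
  standardized mean differences are not computed.
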