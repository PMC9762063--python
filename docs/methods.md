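# Methods

`pathbn` analyses pooled longitudinal behaviour-change intervention
data with hybrid (conditional-Gaussian) Bayesian networks.  This note
documents the model, the algorithmic and numerical choices, the
synthetic data the package is validated on, and the known limits of
what those validations show.

## Model class

The joint distribution over a participant record is a conditional
-Gaussian Bayesian network (CG-BN).  Discrete nodes (gender, 3-level
education, the binary intervention indicator) are multinomial given
their discrete parents.  A continuous node (age, determinant concept
scales, minutes/week of moderate-to-vigorous physical activity) is
Gaussian with a linear mean in its continuous parents and a separate
(intercept, coefficients, noise variance) triple per configuration of
its discrete parents.  Arcs from continuous to discrete nodes are
outside the class and never proposed.

A consequence worth knowing: adding a discrete parent to a continuous
node duplicates the node's entire local model per level, so a discrete
parent costs `(p + 2) * (L - 1)` extra BIC parameters, not one.  Weak
direct effects of a binary variable on a noisy outcome are therefore
intrinsically harder to detect than continuous-continuous effects of
the same standardised size.

## Structural constraints

Variable metadata (tier T0..T3 or static, role) generates per-arc
legality rules: no arc into an earlier tier; demographics accept only
demographic parents; baseline (T0) measurements accept only
demographics and other baseline measurements; the randomised
intervention indicator accepts only demographics and baseline
measurements (the type rule further restricts these to the discrete
ones).  Legality is decidable per arc; acyclicity is enforced by the
search.

## Scoring and search

Structures are scored by the decomposable BIC,
`sum_v [ ll_hat(v | pa(v)) - (k_v / 2) ln n ]` (higher is better;
the sign convention is stated because texts differ).  Discrete local
likelihoods use maximum-likelihood frequencies; continuous ones use
per-configuration OLS with ML (1/n) variance, floored at 1e-12.
A configuration with fewer observations than `p + 2` makes the local
score `-inf`, so the search never selects an unfittable model; the
penalty counts all possible configurations.  Search is greedy
add/delete/reverse hill-climbing from the empty graph with strict
improvement (epsilon 1e-9) and lexicographic (child, parent, kind)
tie-breaking for determinism; reverse moves are proposed only when the
reversed arc is itself legal.  Optional random restarts perturb the
start graph; the default is 0 restarts because robustness is supplied
by bootstrap averaging, not by multi-start search.

## Missing data: structural EM with expected statistics

Pooling studies with different measurement designs leaves block
missingness; extra item nonresponse is modelled as MCAR.  Structure is
learned by structural EM:

* **E-step** — for each record, exact conditional-Gaussian inference
  given the observed cells and the (always observed) discrete
  configuration yields the conditional mean *and covariance* of the
  missing continuous cells.  These accumulate into expected first and
  second moments of the continuous block, per discrete configuration.
  The first E-step uses the empty-graph marginal model.
* **M-step** — hill-climbing over the expected BIC computed in closed
  form from the moments (no data passes per candidate move), then a
  moment-regression parameter update.

An iteration is accepted only if the expected score improves by more
than `score_tol` (default 1e-4); the accepted-score trace is therefore
non-decreasing, and iteration stops at the first non-improving step or
at `max_iter` (default 25).  On complete data the moments are the
exact empirical moments and the procedure reduces to one hill-climb.

A single conditional-mean ("hard") completion was evaluated first and
rejected: imputing means deflates noise variances, and on a 14-node
benchmark with 20% MCAR the completed-data score then rewards spurious
arcs (median SHD 3-6 to the complete-data result, against 0-1 for the
expected-statistics version).  The expectation/draw completion API
(`impute_table`) remains available and supplies the completed table
that structural EM returns.

## Bootstrap stability and averaging

Arc confidence is the fraction of structures, learned on resamples
drawn with replacement to the original size, containing the directed
arc.  Resampling is stratified by study so no design block can vanish
from a resample (the source analysis does not state stratification;
this is a documented choice).  Confidence is direction-specific, since
tiers force most orientations.  The averaged network keeps arcs with
confidence at least the threshold (default 0.6, inclusive); cycles —
possible only within a tier — are repaired by removing the lowest
-confidence arc per cycle, logged.  The number of replicates is chosen
by `select_n_boot`: the smallest candidate count whose thresholded
consensus is SHD-identical to the next candidate's (replicate seeds
depend only on the replicate index, so prefix runs equal smaller
runs).

## Fragments and annotation

The reported object is the union of all directed paths from the
intervention node to the activity outcomes at T2 (short-term) and T3
(long-term): an arc survives iff its tail is reachable from the source
and a target is reachable from its head, which in a DAG is exactly
membership of a simple path.  Arcs are annotated with

* a width band from confidence, cut at 0.7 / 0.8 / 0.9 above the
  display threshold, and
* an asterisk band from jackknife bias-corrected mutual information,
  cut at the 33% / 67% quantiles *of the displayed fragment's arcs*
  (matching how per-model cut-off values are reported); values exactly
  on a cut-off take the higher band.

MI is computed on pairwise complete cases (per arc, not listwise):
Gaussian MI `-0.5 ln(1 - r^2)` for continuous pairs, pooled-minus
-conditional Gaussian entropies for discrete-continuous pairs, and the
contingency plug-in for discrete pairs, each corrected by the
leave-one-out jackknife `n*I - (n-1)*mean_i I_(-i)` and floored at 0.
The fragment report quotes the realised cut-offs and the MI range.

## Synthetic cohorts

No real cohort ships with the package, so generators with known ground
truth stand in:

* `build_default_truth` — the full inventory: three demographics, the
  intervention indicator, eleven determinant concepts at the waves any
  study measured them, and the outcome at all four waves (47 nodes);
  five study designs reproduce the published availability pattern and
  enrolment proportions (1976/2140/766/623/478; intervention share
  4405/5975).  Concept scales are linear-Gaussian around mid-scale
  (mean 3.2, noise SD ~0.67; intention on 1-10 around 6), clipped to
  their ranges at sampling time; the outcome is minutes/week around
  150 (SD ~55) truncated at 0; age is N(65, 9.32^2).  Intervention
  effects on determinants are weak (about a quarter scale point),
  autoregressive and theory-guided cross-concept effects moderate
  (standardised 0.25-0.6), so intervention influence reaches the
  outcomes mostly through mediation chains.  Coefficients get a +-10%
  seed-dependent jitter; the structure is fixed.
* `compact_truth` — a fixed 14-node benchmark (intervention, four
  determinant concepts over three follow-up waves, outcome at T1-T3)
  used by the recovery, EM, and bootstrap validations.  Its effects
  were calibrated once so that the recovery task is well-posed:
  intervention effects enter at T1 only and all downstream effects are
  continuous-continuous, hence every true arc is detectable at a few
  thousand records and no covered-edge orientation ambiguity exists.
  Validation sizes (n = 2000, 10 seeds, 100-150 bootstrap replicates)
  are the package's chosen desk-scale study conditions.
* `demo_truth` — ten nodes with demographics and two studies of
  different designs, for end-to-end runs.
* `random_truth` — random legal tiered DAGs for randomised soundness
  checks.

What the generator does *not* emulate: ordinal item-level responses
(scales are Gaussian, not discretised item means), MNAR/dropout
mechanisms, study-level heterogeneity in effect sizes, and floor
/ceiling clumping of real psychometric scales.  Passing validations
therefore demonstrate correctness of the machinery under the model's
own assumptions, not robustness to real-data violations of them.

## Numerical choices and degenerate inputs

CPT estimation smooths with a Laplace pseudo-count of 1 by default
(configurable to 0) so EM never meets a zero-probability cell;
structure scoring always uses ML counts.  Variances are floored at
1e-12 (scoring: 1e-9) and conditioning adds 1e-12 jitter, so exactly
deterministic arcs (noise variance 0) survive fitting, sampling and
imputation.  Missing-discrete imputation enumerates at most 4096 level
combinations.  Bootstrap confidence compares against thresholds with
1e-12 slack so counts like 60/100 sit on the inclusive boundary.
Concept scales apply the 25%-missing-items rule inclusively.
Education is ordinal-coded {0,1,2} but modelled multinomially; age
enters uncategorised.

## Known limitations

Greedy search finds local optima; within-tier arcs whose reversal is
score-equivalent are oriented by tie-break, exactly the ambiguity the
source methodology acknowledges, and bootstrap averaging is the
mitigation.  Expected-statistics EM assumes discrete cells are
observed (true under the design, where demographics and the
intervention are never masked); tables with missing discrete cells are
rejected by `structural_em` though `impute_table` handles them.  The
fragment is a description of stable directed paths, not a causal
-effect estimate; no backdoor analysis or effect-size computation along
paths is attempted.
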