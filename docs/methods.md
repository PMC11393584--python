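# Methods

This note records the statistical conventions the package implements, the
design choices made where the field's practice is genuinely open, and what
the synthetic-data generator does and does not emulate.

## Model

Item responses are treated as noisy indicators of a multivariate-normal
latent vector whose inverse covariance (precision) matrix Θ encodes
conditional dependencies.  An edge between items i and j is the
regularized partial correlation

    w_ij = −θ_ij / √(θ_ii θ_jj),

estimated by the graphical lasso: Θ maximizes
`log det Θ − tr(SΘ) − λ Σ_{i≠j}|θ_ij|` with the diagonal unpenalized, where
S is the item Pearson correlation matrix (Spearman available by flag;
polychoric correlations are out of scope, see Limitations).

### Estimation conventions

* **Solver.** Blockwise coordinate descent on the working covariance (the
  classic W-update formulation), numba-compiled, with warm starts along the
  λ path.  Convergence: maximum change of any working-covariance entry
  below 1e−6, at most 10,000 sweeps; the inner lasso tolerance is one tenth
  of that.  The unit tests verify the solver against both direct numeric
  maximization of the penalized likelihood (smoothed-L1, Powell) and an
  independent coordinate-descent implementation.
* **Path.** 100 log-spaced penalties from `λ_max = max_{i≠j}|S_ij|` (the
  screening bound above which the graph is empty) down to `0.01 λ_max`.
* **Selection.** Minimum EBIC, `EBIC = −2L + E log n + 4γE log p` with
  `L = (n/2)(log det Θ − tr(SΘ))` and E the number of nonzero
  off-diagonal pairs; `γ = 0.5`.  Ties break toward the larger penalty
  (sparser model).  No post-hoc thresholding of edges.
* **Degenerate input.** Mildly indefinite correlation matrices are
  repaired by eigenvalue clipping and re-normalization (logged);
  n < p is allowed with a warning (minimum n = 10); constant items are an
  error naming the item.

At large n, EBIC selection with γ = 0.5 retains small spurious edges; on
planted 19-node networks at n = 2,000 the suite measures edge-pattern
sensitivity near 1 and specificity around 0.85–0.92 depending on the draw.
This is a property of the selection rule, not of the solver.

## Centrality

Strength `Σ_j |w_ij|` and one-step expected influence `Σ_j w_ij` (a
two-step variant is available by flag).  Closeness and betweenness use
edge lengths `1/|w_ij|`; closeness is the reciprocal of summed shortest
paths and is 0 when any node is unreachable (harmonic closeness was
rejected to follow the dominant convention in the field's centrality
plots); betweenness splits tied shortest paths fractionally and excludes
endpoints.  Z-standardized columns accompany the raw ones; a constant
column z-scores to zeros with a warning.

## Stability

* **Edge accuracy.** Nonparametric bootstrap (row resampling with
  replacement), full re-estimation per replicate, quantile CIs.  Replicates
  that fail to estimate are skipped and logged, with a 10% failure ceiling.
* **CS-coefficient.** Case-dropping subset bootstrap over 10 equally
  spaced drop proportions on [0.05, 0.75] (the grid on which commonly
  reported CS values land after rounding).  At each proportion q, B
  subsamples retain `⌈(1−q)n⌉` rows without replacement; the Pearson
  correlation between full-sample and subset centralities is recorded, and
  the CS-coefficient is the largest q whose 5th-percentile correlation
  stays ≥ 0.7 — operationalizing "with 95% probability the correlation
  stays at 0.7".  A CS of 0 is reported as "< 0.05" (below the grid).

## Network comparison test

Groups are compared on independently estimated networks with identical
estimator settings.  `M = max_{i<j} |w_ij^A − w_ij^B|` tests structural
invariance; `S` is the absolute difference in global strength
`Σ_{i<j}|w_ij|`.  The permutation null pools the rows and re-splits them
into the original group sizes, re-running the full estimator (λ
re-selected) each iteration — the conservative, standard choice.  P-values
use the +1 smoothing `(#{perm ≥ obs}+1)/(iters+1)` (unsmoothed counts by
flag), so they live in `[1/(iters+1), 1]`.

Two implementation details make label swapping exactly neutral: pooled
rows are canonicalized by lexicographic sort before permuting, and the
smaller group is always drawn first.  Since M and S are symmetric in the
two estimated networks, every permutation statistic — hence every
p-value — is invariant under exchanging the inputs.

Per-edge p-values are the permutation tail probabilities of the absolute
edge difference, uncorrected by default (Holm by flag), matching the raw
p-values reported in applied change tables.  Significant differences are
classified with group A read as control and B as depressed: lost
(A ≠ 0, B = 0), new link (A = 0, B ≠ 0), strengthened (|B| > |A|),
weakened (|B| < |A|).

Measured operating characteristics (reproduced by the suite): under the
null (two groups of 300 drawn from one planted 10-node ordinal network,
100 permutations) the rejection rate of `p_S` at α = 0.05 is ≈ 0.05 over
200 replicates.  Against the default planted alternative (eight-edge
change profile plus a 0.25 global-strength gap, 2,500 per group) power is
moderate (~0.5 at α = 0.05): the between-split variability of EBIC-glasso
global strength is of the same order as the planted gap.  The suite
therefore tests the ordering of rejection rates (alternative ≫ null)
rather than a high absolute power value.

## Bridge centrality

Communities are fixed a priori by instrument (S1–S10 self-efficacy,
D1–D9 depression), not detected.  Bridge strength is the summed |w| to
other communities; bridge expected influence is its signed companion; per
node, bridge strength + within-community strength = total strength.  The
combined 19-item network is estimated on the pooled sample (both groups),
since the bridge analysis concerns the sample-wide structure; per-group
bridge analysis is available by flag.  Ranked key-bridge nodes break ties
by node label order.

## Synthetic-data generator

The generator exists because the study's raw questionnaire data are not
deposited; it emulates the *design* so every downstream stage is testable.

* **Truth.** A sparse symmetric partial-correlation matrix with zero
  diagonal; the implied precision (unit diagonal, off-diagonals −w_ij)
  must be positive definite.  Infeasible draws are repaired by uniformly
  shrinking un-pinned off-diagonals by factor 0.95 (tolerance 1e−8, at
  most 100 iterations) — repair never touches planted edit values.
* **Defaults = study conditions.** 3,094 controls and 560 depressed; 19
  items in two communities.  Within-instrument blocks are dense with small
  positive weights (uniform 0.03–0.20 at density 0.85), matching the
  reported self-efficacy networks (37–39 of 45 edges, mean weight ≈ 0.1,
  global strengths ≈ 4.3–4.6); cross-community bridges are sparse
  (density 0.06), weak (0.02–0.10) and negative with probability 0.8,
  matching the reported negative self-efficacy↔depression links.  The
  depressed group's network differs by the eight-edge change profile
  (two strengthened, two weakened, one lost, three new links, with the
  reported control/depressed weight pairs) and carries an exact 0.25
  global-strength deficit in the self-efficacy block, planted by
  rescaling un-edited block edges.
* **Ordinal responses.** Latent multivariate-normal draws cut at per-item
  thresholds.  GSES thresholds give group item means ≈ 2.7 (control) and
  ≈ 2.2 (depressed) on the 1–4 scale; PHQ-9 thresholds give strongly
  right-skewed controls (total ≈ 3.2) and symptomatic depressed
  (total ≈ 13.9), so that classification by the PHQ-9 ≥ 10 cutoff
  reproduces the two-group design with realistic misclassification
  (a few percent of controls cross the cutoff).  Demographics (age,
  gender, education) are drawn per group from the reported marginals.
* **Seeding.** One master seed; every stage derives a named child seed,
  so identical configurations are bit-identical.

What the generator does **not** emulate: item-level content, polychoric
dependence beyond the Gaussian copula implied by thresholding,
differential item functioning, longitudinal structure, or sampling-design
effects (classroom clustering).  Passing recovery tests on these data
therefore show the pipeline's correctness under the latent-Gaussian
threshold model, not agreement with the original study's exact estimates.

## Problem sizes used in the automated checks

The suite runs the solver-oracle sweep at p ∈ {2, 3, 4}; pattern recovery
on a 19-node planted network at n = 2,000; the null-calibration study with
200 replicates of two 300-row groups at 100 permutations (25-point λ path,
chosen as sufficient resolution for 10 items); case-dropping stability at
B = 250 for n ∈ {200, 2,000}; and the acceptance script simulates the full
3,654-participant study with B = 250 and 1,000 permutation iterations on a
50-point path.

## Known limitations

* Pearson correlations on 4-category items attenuate latent associations;
  polychoric input is the natural extension and is deliberately deferred.
* EBIC-glasso specificity degrades at very large n (small spurious edges
  survive selection).
* The CS-coefficient inherits the coarse 10-point grid; values between
  grid points are not resolved.
* Betweenness on dense weighted networks is unstable under resampling
  (low CS is expected, as in applied reports).
* The NCT's S statistic has moderate power against diffuse
  global-strength differences of the size planted by default.
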