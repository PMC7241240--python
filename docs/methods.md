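# Methods

`mota` ranks candidate disease biomarkers in one designated omic dataset
(the *centric* block, e.g. metabolomics) by combining two signals measured
on the same two-group cohort (e.g. cancer cases vs. cirrhotic controls):
how strongly a feature's own level differs between groups, and how strongly
the *correlation structure* around it changes — both within its own omic
layer and across other omic layers profiled on the same samples.

## Model and procedure

### Intra-omic differential network

Within each biological group g, the centric block X (n_g samples × h
features) is column-standardized and a sparse precision matrix Θ⁽ᵍ⁾ is
estimated by the graphical lasso, maximizing the penalized Gaussian
log-likelihood

    log det Θ − tr(S Θ) − ρ ‖Θ‖₁ ,

with S the sample covariance. Partial correlations follow as

    pc_ij = −θ_ij / √(θ_ii θ_jj) ,

which, unlike marginal correlation, removes associations mediated by the
other features in the block. The differential statistic is
Δpc_ij = pc_ij⁽¹⁾ − pc_ij⁽²⁾ (group 1 minus group 2; the group-label file's
first-seen label becomes group 1, and the mapping is logged because it fixes
every sign downstream).

The penalty ρ is chosen per group by K-fold cross-validation (held-out
Gaussian negative log-likelihood, K = 5) with the one-standard-error rule:
the **largest** ρ whose mean CV loss is within one SE of the grid minimum,
i.e. the sparsest model statistically indistinguishable from the best
fitting one. The grid is 20 log-spaced values on [0.01, max|off-diagonal of
S|]; the upper end is the analytic threshold at which every off-diagonal of
Θ is exactly zero.

Significance of Δpc is assessed by a permutation test: group labels are
shuffled (group sizes preserved), both pseudo-groups are re-standardized
and refit with the ρ values selected on the *unpermuted* data (re-running
CV inside each of 1000 permutations would multiply the cost a
thousand-fold for no change in the selected penalties' distribution under
the null), and all off-diagonal Δpc values are pooled across pairs and
permutations into one empirical null. A pair becomes an intra-omic edge
when its observed Δpc falls strictly below the 2.5% quantile or strictly
above the 97.5% quantile of that pooled null (quantiles use the inclusive
linear-interpolation convention, R type 7, recorded in the run metadata).
A per-pair null is available behind `permutation.pooled: false` for
sensitivity analysis.

### Inter-omic differential edges

For each (centric, ancillary) block pair and each group separately, the
package fits regularized generalized canonical correlation analysis
(rgCCA): find per-block weight vectors a_l maximizing

    Σ_{l,k} c_lk · g(cov(X_l a_l, X_k a_k))
    s.t. (1 − τ_l)·var(X_l a_l) + τ_l·‖a_l‖² = 1 ,

with the *horst* scheme (g = identity) and τ = 0, i.e. classical
correlation maximization. The solver is the standard monotone
block-relaxation iteration; the objective is asserted non-decreasing at
every step and convergence requires an objective change below 1e-8.
Components beyond the first are obtained by deflating each block on its own
component scores, which makes within-block scores orthogonal. With τ = 0 a
rank-deficient within-block covariance (h ≥ n, or any block after
deflation) makes the variance constraint singular; the package substitutes
τ = 1e-8 — logged loudly for undeflatened blocks — rather than failing.

Each feature is then projected onto the plane spanned by the first two
canonical variates **of its own block**: feature j's coordinate is
(cor(x_j, y⁽¹⁾), cor(x_j, y⁽²⁾)). The canonical similarity of a centric
feature i and an ancillary feature j is the inner product of their
coordinates, cc_ij ∈ [−2, 2], and an inter-omic edge is called when
|Δcc_ij| = |cc_ij⁽¹⁾ − cc_ij⁽²⁾| strictly exceeds 0.5 (configurable as
`inter.threshold`).

Two genuinely open design choices were resolved as follows. (1) Blocks are
combined **pairwise** (centric vs. one ancillary at a time, a star design)
rather than in one joint L-block fit: the method's integration topology
connects the centric block to each ancillary block and deliberately leaves
ancillary–ancillary interactions out of scope, and pairwise fitting keeps
each similarity matrix interpretable as a two-set canonical analysis.
(2) Feature coordinates use the block's own variates rather than averaged
cross-block variates; the block-own variant keeps |coordinates| ≤ 1 and
makes the duplicated-block sanity check exact.

Weight-vector signs are indeterminate in CCA; the package flips each
component so the centric block's largest-magnitude weight is positive,
flipping all blocks together so the objective (hence every cov(y_l, y_k))
is preserved. Outputs are therefore reproducible bit-for-bit.

### Activity scores and ranking

Per-feature two-group significance comes from a two-sided pooled-variance
Student t-test (p clamped into (0, 1]); externally computed p-values (e.g.
from a count model for sequencing data) can be supplied per block and
bypass the t-test. p-values convert to nonnegative z-scores via
z = Φ⁻¹(1 − p/2), computed as `norm.isf(p/2)` so that very small p stay
finite and accurate. For each centric feature k, its network neighbors are
grouped by omic block (intra-omic neighbors form one group) and each
group's z-scores are Stouffer-combined, z_lk = Σᵢ zᵢ / √m. The activity
score is

    M_k = z_k + Σ_l z_lk ,

and features are ranked by M_k descending, ties broken by smaller p, then
feature id. The printed combination rule admits an arithmetic-mean reading
(Σ zᵢ / m); since the rule is named after Stouffer's method, whose
denominator is √m, √m is the default, with `score.denominator: m` available
for sensitivity checks. The ranking table reports both the p-value rank and
the activity-score rank, plus the sign of the group-1-minus-group-2 mean
difference (direction is deliberately not folded into z, which is two-sided
by construction).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `permutation.n` | 1000 | label permutations for the Δpc null; ≥ 100 enforced for tail resolution |
| `permutation.tail` | 0.025 | per-tail rejection level for intra edges |
| `permutation.pooled` | true | pool the null across feature pairs |
| `glasso.folds` | 5 | CV folds for ρ selection |
| `glasso.grid_size`, `glasso.grid_min` | 20, 0.01 | log-spaced ρ grid up to max|off-diag S| |
| `rgcca.tau` | 0.0 | correlation (0) ↔ covariance (1) constraint interpolation |
| `rgcca.tol`, `rgcca.max_iter` | 1e-8, 1000 | block-relaxation convergence |
| `inter.threshold` | 0.5 | |Δcc| cutoff for inter-omic edges |
| `score.denominator` | sqrt_m | Stouffer (√m) vs arithmetic-mean (m) combination |
| `seed` | required | drives the permutation stream; runs are bit-reproducible |

## Synthetic data: what it emulates and what it does not

The `mota.synthetic` generator draws grouped multi-block Gaussian data with
known ground truth: group-specific partial correlations are planted
directly in a unit-diagonal precision matrix (θ_ij = −pc_ij, with the
minimal diagonal loading that makes the Cholesky succeed, so planted values
stay interpretable); ancillary features are tied to centric features
through shared latent factors (an ancillary feature with link strength s is
s·factor + √(1−s²)·noise, so its population cross-correlation is exactly
s per group); and selected centric features receive mean shifts in SD
units. All randomness derives from one seed through `SeedSequence` spawn
keys, one stream per (block, group), so adding a block never changes
earlier blocks' draws. `null_study` draws both groups from one multivariate
normal whose precision is randomly sparse (Bernoulli(0.15) support,
|pc| uniform on [0.2, 0.4] — magnitudes typical of the sparse-precision
simulation literature and of reported metabolite reaction-pair partial
correlations).

What the generator does **not** emulate: non-Gaussian and heavy-tailed
intensity distributions, missingness, batch effects, feature-count
imbalance across platforms, or correlated noise within ancillary blocks.
Tests passing on these fixtures therefore demonstrate correctness of the
algorithms under the model's own assumptions, not robustness of the method
on real instrument data.

## Numerical choices

- The graphical-lasso subproblem is solved by scikit-learn's coordinate
  descent; the ℓ1 penalty applies to off-diagonal entries (the convention
  of Friedman's reference implementation — variances are not shrunk), and
  reported objective values use that same convention. Optimality is
  verified in the test suite through the KKT conditions rather than against
  the solver's own objective.
- At ρ = 0 the estimate is the closed-form inverse of S (the unpenalized
  MLE) rather than a coordinate-descent run.
- Inside the permutation loop the solver tolerance is 1e-3 (vs 1e-4 for
  single fits): the coordinate-descent dual gap can oscillate just above
  tight tolerances, and pooled-null quantiles are insensitive at this
  resolution while the loop runs ~2000 fits per analysis.
- Empirical quantiles use numpy's inclusive linear interpolation (type 7);
  the convention and the realized cutoffs are written to the run metadata
  because borderline edges depend on them.
- Degenerate inputs: zero-variance features are dropped at load (they
  cannot be standardized); zero pooled variance in the t-test yields p = 1
  with a warning; p ≤ 0 is clamped to the smallest usable float; fewer than
  3 samples per group is refused outright.

## Known limitations

- **Calibration of the intra-omic edge test in the sparse regime.** When
  cross-validation with the one-SE rule selects a near-saturating penalty —
  which happens often at small n with weak conditional dependencies — most
  Δpc values are *exactly* zero, the pooled permutation null acquires a
  large atom at 0, its 2.5%/97.5% quantiles collapse to 0, and the strict
  tail rule cannot call zero-valued pairs. The per-tail false-edge rate on
  null data is then conservative (measured ≈ 1.5–1.9% per tail at h = 15,
  n = 40 per group, against the nominal 2.5%): the usual exchangeability
  argument for permutation calibration assumes a continuous statistic, and
  glasso-thresholded Δpc is not continuous. Edges that *are* called remain
  valid at at most the nominal level; the test errs on the side of fewer
  false edges.
- The one-SE rule is intentionally conservative; on weak-signal data it can
  return fully diagonal precision fits, in which case the intra-omic
  network is empty and ranking reduces to inter-omic and own-significance
  signal.
- ρ is selected once per group and held fixed across permutations; the
  permutation null therefore conditions on the selected sparsity level.
- The |Δcc| > 0.5 cutoff is a pragmatic default inherited from the method's
  original calibration on serum multi-omic data; it has no universal
  justification and should be examined per dataset.
- Runtime is dominated by the permutation loop: roughly
  `2 × permutation.n` graphical-lasso fits of an h × h problem. The test
  suite and the bundled acceptance experiment use desk-scale problem sizes
  (h = 15–20 features, 40–100 samples per group, 25–50 replicates) chosen
  so a full run completes in minutes on one core.
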