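# Methods

## The one-class model

`occmap` analyzes subject × feature tables of regional cortical morphometry
(62 DKT structures × five surface measures + 4 per-hemisphere globals = 314
features) with a ν-one-class SVM. The model places a hyperplane in the RBF
feature space separating the target-class sample from the origin with
maximal margin; its dual is

    min_α ½ Σ_ij α_i α_j k(x_i, x_j),   0 ≤ α_i ≤ 1/(νN),  Σ_i α_i = 1,

with k(x, x′) = exp(−γ‖x − x′‖²), decision f(x) = Σ_i α_i k(x_i, x) − ρ,
and ρ the mean of Σ_j α_j k(x_j, x_s) over margin support vectors
(0 < α_s < 1/(νN)); when every support vector sits at a bound the midpoint
of the max and min of that quantity over support vectors is used instead.
ν ∈ (0, 1] upper-bounds the fraction of training points left outside the
boundary and lower-bounds the support-vector fraction (the ν-property,
verified exactly in the test suite). SVDD — the minimal enclosing
hypersphere — is provided as well; under an RBF kernel with C = 1/(νN) its
dual has the same minimizer, so support sets coincide and test scores are a
monotone transform of the ν-OCC scores.

The dual is solved by SMO-style maximal-violating-pair coordinate updates
(JIT-compiled), KKT-gap tolerance 1e-10, with deterministic tie-breaking by
training-row order. A generic convex-QP path (SLSQP + exact active-set KKT
polish) exists solely as an independent oracle for the tests.

**Standardization.** Morphometric measures live on incommensurate physical
scales (mm², mm³, mm, mm⁻¹); unscaled RBF distances would be dominated by
the areas and volumes. Every fit therefore z-scores each feature with
statistics of its own training target class and applies the same transform
to test rows. Zero-variance features get unit scale, which makes decision
values invariant to constant columns. Inside cross-validation the
standardizer is refit per fold (inner folds included), so no held-out
subject influences any training statistic.

## Matched units and leave-pair-out cross-validation

Cases and controls are matched on z-scored (age, NVIQ) by minimum-cost
optimal assignment. A surplus case joins the pair whose matched control is
nearest, forming one triplet (two cases, one control); a 21/20 stratum thus
yields 19 pairs + 1 triplet, M = 20 units. LPO-CV holds out one unit per
fold: the classifier is trained on the target-class members of the other
M − 1 units and scored on both classes of the held-out unit, so the
concatenated out-of-fold scores support a ROC. AUC is computed by the
midrank Mann-Whitney formula (ties ½) and equals exact pairwise counting.

**Kernel-parameter optimization** (optional) runs two sequential inner
LPO-CV searches on the training units only: γ over 19 powers of two,
2⁻¹⁵ … 2³, with ν = 0.1, refined on a ±1 log₂ bracket at step 0.25 around
the coarse argmax (9 points — the refinement rule is this package's
decision; a bounded deterministic bracket); then ν over 10 linear values in
[0.01, 0.5] and 20 in [0.01, 0.3] with γ fixed. Ties break toward smaller
γ, then smaller ν. The default mode is fixed ν = 0.1 with the heuristic
γ = 1/d (d = number of features). The two-class reference SVM follows the
same CV contract with a C grid of 2⁻⁵ … 2¹⁵ (our own choice of span).

## Preimage maps

The weight vector w = Σ_i α_i φ(x_i) has no exact preimage under the RBF
map; the point z maximizing Σ_i α_i k(x_i, z) (equivalently minimizing
‖w − φ(z)‖²) satisfies z = Σ_i w_i x_i / Σ_i w_i with
w_i = α_i exp(−γ‖z − x_i‖²), and is found by iterating that map. Because
α ≥ 0, every iterate stays in the convex hull of the support vectors. The
iteration tolerance is 1e-8 on the step norm with at most 10⁴ iterations —
far below the resolution at which the map is interpreted and cheap relative
to the permutation loop. The map can have several basins, so the search is
multi-start: the α-weighted support-vector mean, plus restarts from support
vectors sampled by α (default 5; 2 inside permutation loops, where the same
policy is applied to observed and null maps alike). A decrease of the
objective or denominator underflow triggers a restart. For linear kernels
the primal w is exact and returned directly. The initialization, tolerance
and restart policy are this package's own choices; published descriptions
of the method delegate them to toolboxes without stating values.

## Permutation inference

The null for a matched design exchanges labels within units: independently
per unit, with probability ½ the case and control swap (for a triplet the
control swaps with one of the two cases, chosen uniformly), giving 2^M
equiprobable relabelings. How many units to swap per draw is not uniquely
dictated by the matched-pair framing; the independent Bernoulli(½) exchange
is the standard exchangeable null and is what we implement.

* **AUC null:** each relabeling defines an artificial target class; the full
  LPO-CV (including nested optimization when the observed run used it) is
  repeated and the out-of-fold AUC recorded. p = #(null AUC > observed)/B,
  one-sided with no add-one correction; the corrected (count+1)/(B+1) is
  reported alongside.
* **Preimage null:** the observed map comes from one model trained on the
  full target class at fixed ν = 0.1 and heuristic γ; each permutation
  refits and recomputes z identically. Per feature, p_k = #(|z_k-null| >
  |z_k-obs|)/B. Features with p < α (default 0.05) are flagged; no
  multiple-testing correction is applied to the primary flag (a
  Benjamini-Hochberg column is emitted for reference). A permutation whose
  preimage fails to converge is resampled once from a fresh stream, then
  excluded with denominator adjustment; a warning fires above 1% failures.

For the map, features are standardized once against the **pooled sample**
(all subjects) rather than per target class: pooled statistics are invariant
under label permutation, so observed and null z components live on a common
scale — without this the permuted refits would each re-center on their own
artificial class and the comparison would be meaningless. Classification CV
keeps per-fold target-class standardization (the two stages answer different
questions and have different leakage constraints).

Each permutation's random stream derives from (seed, permutation index), so
results do not depend on execution order or worker count.

Sign trends annotate significant features with the direction of the
case-minus-control mean difference (standardized; |diff| < 1e-12 → none).
Mean difference is the default statistic; medians would also be defensible,
but the mean matches the Gaussian generator and is the conventional report.

## The synthetic cohort generator

The generator emulates the study design the analysis assumes:

* **Covariates.** Ages from a truncated normal (49 ± 12 months on [22, 72]);
  NVIQ stratified into a DD stratum (< 70; 52 ± 10) and a no-DD stratum
  (≥ 70; 91 ± 14), with the DD fraction of matched units set by
  `control_mixture_weight` (default 0.5, i.e. 20 DD / 20 no-DD controls at
  n = 40). A control's age and NVIQ equal its designed case partner's value
  plus a small jitter, so covariate matching recovers the designed pairing
  and the LPO structure (20 pairs, or 19 pairs + triplet) is reproducible.
  The DD threshold NVIQ < 70 is fixed, not configurable.
* **Features.** Latent standardized scores follow a block-covariance
  Gaussian: the five measures of one region correlate at 0.5 (they describe
  one structure), regions are independent; globals are independent. Scores
  are mapped to realistic native units per measure (e.g. areas ~1500 ±
  250 mm², thickness ~2.6 ± 0.25 mm). Planted case effects, the control
  mixture shift, and optional age/NVIQ coupling act on the SD scale.
* **Class structure.** Cases are one Gaussian (covariance scale 1.0 by
  default). Controls are a two-component mixture: DD and no-DD means sit at
  ±h/2 per feature along a seed-fixed random sign pattern, h =
  `control_heterogeneity`.

**Designed conditions.** Two named conditions are used throughout the tests
and the acceptance script:

* *Asymmetry condition* (the defaults): h = 2.5, no planted effects. At
  this separation the expected RBF similarity of a case to control support
  vectors equals the mixture-averaged similarity of a held-out control
  (balance exp(−γ(d(1+s) + d h²/4)) ≈ ½ exp(−2γd)(1 + exp(−γ d h²)) at
  γ = 1/d), so a control-trained one-class boundary discriminates at
  chance, while the case-trained boundary excludes the spread-out controls.
  Checked at 150 cases/150 controls, where a chance-level LPO-CV AUC has
  sampling sd ≈ 0.02 and the ±0.07 chance band is meaningful; at 40 + 40
  the band would be about one sd of a chance AUC and the check would be
  uninformative.
* *Recovery condition*: 40 + 40 subjects, 10 features planted at ±1.5 SD,
  h = 1.5. Heterogeneity this strong still drives case-trained AUC ≈ 1.0,
  while leaving the permutation-null preimage unimodal enough that all ten
  planted components are recovered at p < 0.05. At h = 2.5 the null
  preimage becomes mode-seeking — artificial target sets are bimodal and z
  collapses into one control mode, inflating null |z| on every feature —
  and recovery collapses; this regime is deliberately reserved for the
  asymmetry condition, which makes no map claims.

**What the generator does not emulate:** scanner/site effects, non-Gaussian
tails, long-range anatomical covariance between regions, measurement error
correlated with age, or longitudinal growth. Passing tests therefore
demonstrate correctness of the algorithms and calibration under the assumed
model, not clinical performance on real MRI-derived tables.

## Numerical and degenerate-input choices

* SMO start: unit mass spread over the first ⌈νN⌉ coordinates; convergence
  at KKT gap ≤ 1e-10; non-convergence raises with iteration diagnostics.
* N = 1 target sets are valid (α = [1], ρ = 1, the point lies on the
  boundary). All-identical target sets give radius 0 in SVDD.
* Degenerate kernel denominators in the SMO pair update fall back to the
  maximal feasible step.
* Support vectors are α_i > 1e-9 · (1/(νN)); margin SVs additionally
  α_i < (1 − 1e-7) · bound.
* TSV round-trips are bit-exact: floats are written as %.17g and parsed by
  numpy's exact converter.
* Matching is deterministic; unit lists are sorted by subject id.

## Problem sizes in the test and acceptance runs

Calibration and recovery runs are scaled so the whole suite fits a desktop
budget: null calibration uses 50 cohorts of 20 + 20 with 200 permutations
each; recovery uses 500 permutations; the acceptance script uses 200–500
permutations per test. Production analyses would use the 10⁴ permutations
the CLI defaults to; the permutation machinery is identical, only B varies,
and p-value granularity scales as 1/B.

## Known limitations

* The preimage is a single point summary of w; multimodal weight vectors
  are summarized by their dominant basin (restarts report only the best).
* The raw p = count/B convention can return exactly 0; the add-one column
  is provided and preferred for downstream thresholding.
* No spatial/cluster-level inference across neighboring regions.
* The two-class reference grid (C span) is a package decision, not a
  reproduction of any published grid.
* With very small strata (M < ~10) the inner LPO-CV AUC used for parameter
  selection is noisy; fixed ν = 0.1 with heuristic γ is the safer default.
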