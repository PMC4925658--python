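# occmap

One-class SVM analysis of regional brain-morphometry feature tables.

Case-control neuroimaging studies of heterogeneous conditions (the motivating
application is autism spectrum disorder in preschoolers) often cannot rely on
binary classifiers: the patient group, the control group, or both may lack a
common multivariate signature. `occmap` instead *describes one class at a
time*. It trains a ν-one-class support vector machine (ν-OCC SVM) on a single
target class of subjects — each subject a vector of 314 regional morphometric
features (62 DKT cortical regions × {Area, Volume, Thickness, ThicknessStd,
MeanCurv} plus per-hemisphere total white-surface area and mean thickness) —
and asks whether the *other* class falls outside the learned boundary.

The toolkit provides:

* **ν-OCC SVM core** — the dual problem
  min½ Σᵢⱼ αᵢαⱼ k(xᵢ,xⱼ) s.t. 0 ≤ αᵢ ≤ 1/(νN), Σαᵢ = 1, with RBF kernel
  k(x,x′) = exp(−γ‖x−x′‖²), solved by an SMO-style maximal-violating-pair
  optimizer; decision f(x) = Σᵢ αᵢk(xᵢ,x) − ρ. ν bounds the fraction of
  training outliers from above and the support-vector fraction from below.
  SVDD (minimal enclosing hypersphere) is included and is identical to the
  ν-OCC under RBF with C = 1/(νN).
* **Leave-pair-out cross-validation (LPO-CV)** — cases and controls are
  matched on age and non-verbal IQ (optimal assignment); each CV fold holds
  out one matched unit (pair, or a 2-case/1-control triplet), so every test
  set contains both classes. Kernel parameters can be fixed (ν = 0.1,
  heuristic γ = 1/d) or tuned by nested inner LPO-CV over the protocol grids
  (γ: 19 powers of two from 2⁻¹⁵ to 2³ plus refinement; ν: 10 values in
  [0.01, 0.5] then 20 in [0.01, 0.3]).
* **RBF preimage maps** — the learned weight vector w = Σᵢ αᵢφ(xᵢ) is pulled
  back to input space by fixed-point iteration, giving a per-feature
  discriminative map z whose components align with the 314 features.
* **Matched-pair permutation inference** — within-unit label exchange
  (Bernoulli ½ per unit) builds exact nulls for both the LPO-CV AUC and the
  per-feature |z| components; features with p < 0.05 are reported per region
  and measure with case-vs-control sign-trend arrows.
* **Synthetic cohort generator** — covariate-matched cases/controls with a
  homogeneous case class, a two-subpopulation (DD / no-DD) control mixture,
  region-block feature covariance and plantable effects, so the entire
  pipeline is testable without clinical data.

## Worked example

```sh
occmap simulate --n-cases 41 --n-controls 40 --seed 7 --out cohort/
occmap validate-input --stats-dir cohort --meta cohort/subjects.tsv
occmap run-cv --stats-dir cohort --meta cohort/subjects.tsv \
       --target case --fixed --out scores.tsv
```

which prints (this exact cohort and seed):

```
OK: 81 subjects (41 cases, 40 controls), 314 features
AUC = 1.000 (M = 40, target = case)
AUC [NVIQ < 70] = 1.000
AUC [NVIQ >= 70] = 1.000
```

The simulated control class is a DD/no-DD mixture and the case class is
homogeneous, so the case-trained one-class boundary separates the held-out
controls essentially perfectly at this effect strength, uniformly across NVIQ
strata. Training on the *controls* instead (`--target control`) prints
`AUC = 0.423` — chance level up to sampling noise at 81 subjects. That is the
designed asymmetry: a heterogeneous class does not support a normative
one-class boundary. The same experiment from Python:

```python
from occmap import (CohortConfig, EffectSpec, simulate_cohort, match_pairs,
                    run_occ_cv, roc_auc)

features, subjects = simulate_cohort(CohortConfig(n_cases=41, n_controls=40, seed=7))
partition = match_pairs(subjects)            # 39 pairs + 1 triplet, M = 40
cv = run_occ_cv(features, subjects, partition, target_class="case")
auc, _ = roc_auc(cv.scores, cv.labels)       # 1.0
```

Permutation significance of the AUC and the preimage map:

```sh
occmap permutation-test --stats-dir cohort --meta cohort/subjects.tsv \
       --mode auc --n-perm 200 --seed 1 --out perm/
occmap permutation-test --stats-dir cohort --meta cohort/subjects.tsv \
       --mode preimage --n-perm 500 --seed 1 --out perm/
```

or end-to-end from one YAML config with `occmap run --config run.yaml`.

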