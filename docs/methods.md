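# Methods

## Model

The package fits a linear multitask regression where the tasks are the
`k` time points of a longitudinal outcome measured on `n` subjects with
`p` shared covariates. Writing `Θ ∈ R^{p×k}` for the coefficient matrix
(rows = features, columns = tasks), `Λ ∈ {0,1}^{n×k}` for the response
observation mask, and `G_1..G_q` for a disjoint partition of the
features into groups with weights `w_l` (default `sqrt(|G_l|)`), the
estimator solves

    min_Θ ½‖Λ ⊙ (Y − XΘ)‖_F² + λ₁‖Θ‖₁
          + λ₂ Σ_l w_l ‖Θ[G_l, :]‖_F
          + λ₃ Σ_{t} Σ_l w_l ‖(ΘD)[G_l, t]‖₂ .

Assumptions encoded by each term:

* **Masked squared loss.** Unobserved responses contribute nothing;
  missingness is taken as non-informative given the visit (a column-wise
  missing-completely-at-random model). No imputation occurs anywhere.
* **λ₁ (lasso)** — most individual coefficients are zero.
* **λ₂ (task-common group norm)** — relevance is organized by group
  (region of interest): a group is either in the model for all time
  points or excluded from all of them.
* **λ₃ (group-guided fused-Laplacian norm)** — an active group's
  coefficients drift smoothly across visits. `D` has unit diagonal and
  `−w_{l,t}` off-diagonal, where

      w_{l,t} = exp(−(τ_l − τ_t)²/σ²) / Σ_{l'≠t} exp(−(τ_{l'} − τ_t)²/σ²)

  are Gaussian-kernel weights over the task positions `τ` (default
  `1..k`), normalized so each column of `W` sums to one. Column `t` of
  `ΘD` is then the deviation of task `t` from the weighted average of
  *all* other tasks — unlike a chain fused Lasso, which couples only
  neighbors. Because a constant trajectory lies in the null space of
  `D`, the penalty never discourages a stable effect.

The per-column normalization makes `W` (and hence `D`) asymmetric at the
edge tasks. The solver is derived for general `D` and uses
`Φ = DDᵀ`, which is symmetric positive semidefinite regardless; a
`symmetrize` option replaces `D` by `(D + Dᵀ)/2` for users who prefer a
symmetric transform. Visit positions may be passed in months to model
irregular spacing; the default uses indices, which corresponds to
treating visits as equally spaced.

## Optimization

ADMM on the equivalent constrained problem with slack copies `Q = Θ` and
`Γ = ΘD`:

1. **Θ step.** The quadratic subproblem decouples by task after the
   cross-task coupling through `Φ` is moved to the right-hand side
   (Jacobi sweep by default; a Gauss–Seidel sweep is available). Task
   `t` solves
   `(X_tᵀX_t + ρ(1 + Φ_tt) I) θ_t = X_tᵀy_t − u_t − (VDᵀ)_t + ρ q_t +
   ρ(ΓDᵀ)_t − ρ Σ_{l≠t} Φ_{tl} θ_l`,
   where `X_t, y_t` contain only the rows observed at task `t`. The
   matrix is positive definite for any `ρ > 0`; one Cholesky factor per
   task is computed at the start of the fit and reused every iteration
   (mask and ρ are fixed).
2. **Q step.** Exact two-stage prox of the sparse-group penalty:
   elementwise soft-threshold at `λ₁/ρ`, then per-group Frobenius
   shrinkage at `λ₂ w_l/ρ`. Exactness of the composition relies on the
   groups not overlapping.
3. **Γ step.** Per-(group, task) block ℓ₂ shrinkage at `λ₃ w_l/ρ`.
4. **Dual ascent** on `U` (for `Θ − Q`) and `V` (for `ΘD − Γ`).

All variables start at zero; the solver is fully deterministic.
Convergence is declared when both primal residuals `‖Θ − Q‖_F` and
`‖ΘD − Γ‖_F` fall below `tol_primal · max(1, ‖Θ‖_F)` *and* the relative
objective change is below `tol_obj`. The reported coefficients are the
slack copy `Q`: its prox produces exact zeros, so sparsity patterns and
group-support counts are well defined; the smooth iterate is retained as
`theta_smooth` and agrees with `Q` to within the primal tolerance.
A non-finite objective raises an error naming the iteration; hitting
`max_iter` returns a result flagged `converged=False` rather than
raising.

Degenerate inputs: a zero prox block maps to zero (the limit of the
shrink factor, avoiding 0/0); tasks whose kernel weights all underflow
(`σ → 0`) fall back to exact nearest-neighbor weights; zero-variance
feature columns are rejected at standardization with the offending
feature named.

## Tunable parameters

| parameter | default | meaning |
| --- | --- | --- |
| `λ₁, λ₂, λ₃` | 0 | penalty strengths, on the scale of the squared loss; CV grids default to the decade ladder 0.1–1000 |
| `σ` | 1.0 | kernel bandwidth, in units of the task positions; ~1 couples mainly adjacent visits, large σ couples all visits equally |
| `ρ` | 1.0 | ADMM penalty; affects the iteration path, not the solution. An optional residual-balancing adaptation is off by default so runs are exactly reproducible |
| `tol_primal` | 1e-6 | relative primal-residual tolerance |
| `tol_obj` | 1e-10 | relative objective-change tolerance |
| `w_l` | `sqrt(ν_l)` | group weights; the square-root convention makes penalties comparable across group sizes |

Features are z-scored with population (1/n) standard deviations learned
on training rows only. Responses are left on their original scale by
default so rMSE is interpretable in score units (an option scales them
too).

## Evaluation metrics

Per task: rMSE and Pearson correlation over observed cells. Aggregates:
`nMSE = Σ_h ‖Y_h − Ŷ_h‖² / Var(Y_h) / Σ_h n_h` with population variance
of the observed responses, so the per-task mean predictor scores exactly
1; and `wR`, the observation-count-weighted mean of the per-task
correlations. A task whose observed responses (or predictions) are
numerically constant has no defined correlation and is flagged rather
than scored 0; `wR` then averages over the defined tasks. The variance
normalizer can be switched to the standard deviation for comparability
with conventions that use it.

## Model selection

Nested cross-validation: outer 10-fold over subjects (all visits of a
subject stay together), inner 5-fold grid search on each outer training
fold minimizing mean validation nMSE, standardization re-learned inside
every split so no test information leaks. Ties are broken toward the
lexicographically smallest `(λ₃, λ₂, λ₁)`. A diverging grid point scores
infinitely bad instead of aborting. Baselines: per-task ridge (closed
form on observed rows) and per-task Lasso (the main solver with
`λ₂ = λ₃ = 0`, under which the objective decouples across tasks).

## Synthetic cohorts

The generator emulates the structure above: iid standard-normal
features; `q` disjoint groups (default sizes 4, mirroring
several-measures-per-region layouts); `s` active groups whose
coefficient blocks are a random base vector plus kernel-smoothed
temporal jitter (`jitter_sd`, default 0.2 — modest drift around a stable
effect); Gaussian noise calibrated to a target signal-to-noise ratio
(default 5, a clearly learnable but non-trivial regime); and monotone
per-visit observation probabilities (default 1, .9, .8, .6, resembling
cohort attrition). Defaults are `n=200, p=60, q=15, s=4, k=4`, a
mid-sized single-site study.

Deliberate simplifications — and hence what passing tests do *not*
show about real data: features are independent and Gaussian (real
imaging measures are correlated within and across regions), the temporal
signal is generated by the same smoother the model penalizes
(well-specified by construction; a `misspecified` flag substitutes
piecewise-constant trajectories with one change point to probe
robustness), dropout is random given the visit rather than related to
disease severity, and responses are unbounded rather than confined to a
test's score range.

## Design choices

* The group-shrinkage prox for the task-common penalty scales *all rows
  of a group together* by the group's Frobenius-norm margin; this is the
  reading consistent with the penalty definition and is verified against
  a generic convex-solver oracle in the tests.
* The Θ update keeps the observation mask in the normal equations
  (per-task factors) instead of assuming complete responses.
* Cross-terms in the Θ step are derived from the exact gradient with a
  possibly asymmetric `D` (`VDᵀ`, `ΓDᵀ`, `ΘΦ`), which reduces to the
  symmetric-transform expressions when `D` is symmetric.
* The Jacobi sweep is the default because its per-column solves are
  independent; Gauss–Seidel typically needs fewer iterations and is
  available as an option. Both pass the same oracle tests.
* No warm starts across grid points: every grid fit starts cold, so
  selection results are independent of grid enumeration order.

## Known limitations

* Groups must not overlap (the two-stage prox is exact only then).
* The task transform is fixed by `σ` and the visit positions; the task
  graph is not learned from data.
* Fixed `ρ` can converge slowly for badly scaled problems; standardize
  features (the CV protocol does) or enable the adaptive option.
* `k = 1` is rejected: with a single task the temporal machinery is
  meaningless — use the ridge/Lasso baselines instead.
* The solver targets dense `p` up to a few thousand; each fit stores
  `k` Cholesky factors of `p×p` matrices.

## Problem sizes in the shipped checks

Oracle comparisons run at `p ≤ 12, k ≤ 4, n ≤ 30` (where the generic
convex solver is reliable to the tolerances asserted); the recovery
study runs 10 replicate cohorts at the default generator conditions with
a 200/100/100 train/validation/test subject split and a 12-point penalty
ladder; the acceptance script repeats that computation on 3 cohorts.
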