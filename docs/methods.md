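# Methods

## Model

`topconnmf` factorizes a nonnegative expression matrix `X` (`g` samples ×
`s` biomarkers) as `X ≈ W H`, with the basis `W` (`g × k`) and the
coefficients `H` (`k × s`) both nonnegative, by minimizing

```
J(W, H) = ‖X − W H‖_F + α ‖W‖_{2,1} + β T(H)
```

* `‖W‖_{2,1} = Σ_i ‖w_i·‖₂` induces row sparsity in the basis: samples
  contribute through few latent components.
* `T(H)` is a topological-overlap penalty on the coefficient columns.
  Each biomarker `j` is represented by the column `h_j`; correlated
  biomarkers should have correlated columns, including *indirect*
  (shared-neighbour) association.  With `A` the `s × s` Pearson
  correlation matrix of the columns of `H`, the overlap matrix is
  `B = (k−1)(A·A) + A` (matrix product by default — the shared-neighbour
  TOM semantics; a Hadamard variant is available), `S = Hc' Hc` is the
  centred Gram matrix of the columns, and

  ```
  T = ‖ B ⊘ S ‖_F          (elementwise quotient, |S| floored)
  ```

The quotient structure means `T` *rewards* coefficient columns whose
overlap is backed by substantial (co)variance and has poles where Gram
entries vanish.  It is an unusual and numerically delicate functional;
the consequences are handled explicitly below.

## Optimization

`W` and `H` are updated by alternating multiplicative ratio rules, which
preserve nonnegativity:

```
W ← W ⊙ (X Hᵀ) ⊘ (W H Hᵀ + P(W))
H ← H ⊙ (Wᵀ X + (β/2)(T′)⁻) ⊘ (Wᵀ W H + (β/2)(T′)⁺)
```

* `P(W)` is the basis-penalty contribution.  The default `reweighted`
  mode uses the iteratively reweighted form
  `P(W) = (α/2) · diag(1/(2‖w_i‖₂ + ε)) · W`, which targets the stated
  L2,1 term; a `literal` mode uses the ridge-like `(α/2) W`.
* `T′ = ∂T/∂H` is the exact chain-rule gradient of the implemented
  penalty (see below).  Its positive part enters the denominator and its
  negative part the numerator — the standard split-gradient construction
  for signed regularizer gradients.  Clipping the negative part away
  instead leaves the update unable to descend `T` where the penalty
  favors larger coefficients, and in practice produces persistent cost
  oscillation.

### Monotone safeguard with backtracking

Because `T` is an unbounded quotient, a raw multiplicative step can jump
the cost by orders of magnitude when a trajectory passes near a Gram
pole, and can overshoot badly when the penalty gradient dominates the
update denominator.  The fit loop therefore treats each multiplicative
step `M → M ⊙ r` as a *proposal*: it is accepted only if the total cost
does not increase; otherwise geometrically damped trials `M ⊙ r^θ`,
`θ = 1/2, 1/4, …` (default 6 levels, `FactorConfig.max_backtracks`) are
tested, and if all fail the previous iterate is kept (counted in
`FactorResult.n_rejected_steps`).  This makes the cost trace
non-increasing by construction while keeping the multiplicative rules as
the step generators.  With `α = β = 0` the classical update is provably
monotone, so the first trial is always accepted and the algorithm
reduces *exactly* (elementwise) to textbook multiplicative NMF — a
property the test suite asserts at rtol 1e−12 against an independently
coded oracle.

Without damping (rejection only), fits at the default synthetic scale
stall almost immediately: `β T` at a random initialization is ~10⁴ times
larger than the reconstruction term, every raw coefficient step
overshoots, and the factorization never leaves the neighbourhood of its
initialization.  With damping the same cost is descended to a solution
whose `β T` term is negligible (~0.2 vs RE ~31 on the default fixture) —
the objective is well-behaved at its optima; only the raw step size is
pathological.

### Stopping, flooring, determinism

Iteration stops when the relative total-cost change falls below `tol`
(default 1e−6) or at `max_iter` (default 300).  All denominators and
factors are floored: non-finite entries and, for contract-nonnegative
matrices, entries below `floor_eps` (default 1e−10) are replaced by
`floor_eps`.  In the penalty, near-zero Gram entries are floored in
*magnitude* preserving sign.  Every stochastic choice flows from an
integer seed through `numpy.random.default_rng`; identical inputs and
seeds give bit-identical results.  Initial factors are uniform on
(0, 1] scaled by `sqrt(mean(X)/k)` so the initial reconstruction has a
magnitude comparable to `X`.

### Topology gradient

The default gradient mode is the exact reverse-mode (chain-rule)
gradient of the implemented penalty through the pipeline
`H → Hc → S → A → B → G → T`, with zero derivative assigned through
floored Gram entries and zero-variance columns.  A central
finite-difference oracle (step 1e−6) is the correctness reference; a
`literal` gradient mode implements the closest dimensionally consistent
reading of the originally printed closed form (whose repeated
rectangular inverses do not type-check as written) using Moore–Penrose
pseudo-inverses — it is retained for fidelity, not correctness.

Gradient validation is performed on coefficient matrices drawn by
rejection until every off-diagonal centred-Gram entry has magnitude
≥ 0.05 (`simulate.generate_coefficient_matrix`).  This conditions the
*oracle*, not the implementation: near a Gram zero the penalty's
curvature diverges and the fixed-step difference quotient loses absolute
accuracy (the chain-rule gradient still agrees to ~1e−8 *relative*
there).  On the conditioned ensemble the worst absolute deviation is
~1.5e−7 against a 1e−4 tolerance.

## Biomarker ranking

1. **Two-layer SOM hierarchy.**  Coefficient columns are mapped onto an
   8×8 self-organizing map, its prototypes are consolidated by C-means
   (k-means, 4 centres), and a 2×2 second layer — initialized at the
   C-means centroids — refines the grouping; each biomarker's group
   (1–4) is the layer-2 best-matching unit of its layer-1 prototype.
   SOM training is *batch* (per epoch: assign all inputs, recompute
   prototypes as neighbourhood-weighted means, radius decaying
   exponentially), which makes clustering independent of column order —
   permuting biomarkers permutes assignments identically, a property the
   classical online rule lacks.  The online winner-takes-all step is
   still exposed (`som_step`).  Defaults: 100 epochs, η₀ = 0.5,
   σ₀ = half the grid diagonal.
2. **Class contrast.**  Groups are associated with a class by comparing
   mean expression of their member features between diseased and
   control samples; with `m_j = ‖h_j‖₁`, the statistics
   `C_μ = (μ_B − μ_D)/(n_B + n_D)` and the squared-deviation difference
   `C_σ` are evaluated over the class-associated column sets (explicit
   index sets may be passed instead).  The deviations inside `C_σ` are
   taken against the *summed* masses — kept literal to the originating
   formulation even though a per-column mean would be the conventional
   choice.
3. **Relative expression.**  `X_r = γ₁(D/B) ⊙ γ₂(P/B) ⊙ γ₃(Pc/B)` with
   γ = (1, 1, 1) by default and the baseline floored before division.
   The four `g × s` ingredients are under-determined in the source
   method; the package's documented convention (swappable — any four
   matrices can be passed) is: `B` mean control expression at the first
   time point, `D` mean diseased expression overall, `P`/`Pc` mean
   diseased/control expression at each sample's own time point.
4. **Ranking score.**  Features are ordered by the mean over samples of
   `|log X_r|` — departure from baseline in either direction — and the
   top `ceil(fraction · s)` are returned (default 3%).

## Synthetic data

`generate_timecourse` emulates a small-sample two-arm rodent time-course
study: 2 classes × 4 equally spaced time points × 5 replicates (g = 40)
over s = 300 features, of which 15 planted signal features are
differentially expressed.  Baselines are `0.5 + Gamma(2,1)` (right-
skewed, bounded away from zero so ratio statistics are meaningful); a
diseased sample at time `t` expresses a signal feature at
`baseline · (1 + effect·t)` with `effect = 0.5` — a progressive effect
reaching a 2.5-fold change at the last time point, the magnitude of a
strong validated disease marker.  Noise is additive Gaussian
(`sd = 0.3`, ~12% of the mean baseline), exchangeably correlated within
the signal block (`ρ = 0.6`, emulating co-regulation) and independent
elsewhere; values are clipped at zero.  `generate_planted_factorization`
draws `W*, H* ~ Gamma(2,1)` and returns `X = W*H*` plus optional clipped
Gaussian noise.

What the generator does *not* emulate: count-distribution artefacts
(library size, overdispersion), batch effects, heteroscedastic
mean–variance coupling, or realistic correlation structure among null
features.  Passing tests therefore demonstrate the pipeline's mechanics
and its behaviour under idealized planted signal, not performance on
real assays.

## Problem sizes and known limitations

Test and acceptance workloads use desk-scale problems chosen as the
package's own evaluation conditions: 20×40 (k = 3) instances for
descent/reduction checks, 30×60 (k = 4) planted recovery, the 40×300
(k = 5) time-course fixture for the 60-run stability protocol and the
10-seed ranking study.

Two documented behaviours of the faithful implementation are worth
knowing:

* **Sublinear convergence of multiplicative updates.**  On exactly
  low-rank data the unregularized fit reaches a relative reconstruction
  error of ~3e−3 after 500 iterations (and ~5e−4 after 2000); this
  matches scikit-learn's `NMF(solver="mu")` trajectory exactly and is a
  property of the update class, not of this implementation.
* **Run-to-run spread under the topology penalty.**  At the pinned
  regularization weights (α = 0.0150, β = 0.0095) the penalized cost is
  multi-attractor at the fixture scale: most seeds converge to the same
  deep optimum, but occasional runs settle at a shallower one, so the
  across-run coefficient of variation of the final reconstruction error
  can exceed the ~5% figure one would like from an
  initialization-resilient method.  Practitioners should run several
  seeds and keep the lowest-cost solution.
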