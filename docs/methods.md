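# Methods

## Model and cost

A trial of muscle activity is a non-negative matrix `M^s` with T time
steps and M muscles. The space-by-time decomposition writes every trial
as `M^s ≈ W̃ A^s W`: P temporal modules (columns of `W̃`, waveforms over
normalized movement time), N spatial modules (rows of `W`, weightings
across muscles), and a P×N coefficient matrix `A^s` per trial. The
modules are trial-invariant; all trial-to-trial (and hence task-to-task)
structure is carried by the coefficients. All factors are non-negative,
and each temporal-module column and spatial-module row is constrained to
sum to one so the factorization's scale ambiguity is resolved into the
coefficients. (Equivalent transposed statements of the unit-sum
convention exist; this package consistently normalizes *columns* of `W̃`
and *rows* of `W`, matching the constraint structure of its
least-squares solvers.)

With task labels partitioning the S trials into K groups `G_k` of size
`n_k`, the within- and between-task scatter matrices of the vectorized
coefficients are

    S_w = Σ_k Σ_{s∈G_k} vec(A^s − Ā_k) vec(A^s − Ā_k)ᵀ
    S_b = Σ_k vec(Ā_k − Ā) vec(Ā_k − Ā)ᵀ

with `Ā_k` the task means and `Ā` the grand mean. `S_b` is deliberately
*unweighted* by `n_k` — each task contributes once — which differs from
the textbook LDA between-class scatter; the two coincide for balanced
designs. The full fitting cost is

    E² = E²_NMF + γ·tr(S_w) − δ·tr(S_b),

with `E²_NMF = Σ_s ‖M^s − W̃A^sW‖²_F`. Traces are evaluated through the
Frobenius identity `tr(S_w) = Σ_k Σ_{s∈G_k} ‖A^s − Ā_k‖²_F` without
materializing (PN)² matrices; the matrices themselves are built only on
request. Note that `−δ·tr(S_b)` is unbounded below, so over-weighting δ
can make the optimizer trade arbitrary reconstruction error for task
separation; δ should stay well below the scale at which this happens
(the VDM tuning below enforces this in practice).

The analytic gradients used everywhere (solvers, finite-difference
validation) are, for `s ∈ G_l`:

    ∂E²_NMF/∂A^s = 2 W̃ᵀ(W̃A^sW − M^s)Wᵀ
    ∂tr(S_w)/∂A^s = 2 (A^s − Ā_l)
    ∂tr(S_b)/∂A^s = (2/n_l)(Ā_l − Ā) − (2/S) Σ_k (Ā_k − Ā)

## Solvers

All three solvers share uniform(0,1) random initialization (modules
normalized to unit sum), a relative objective-change stopping rule
(default tol 1e-8, max 500 outer iterations), and best-of-n restarts
with per-restart seeds spawned deterministically from the master seed
(selection by lowest E², ties by lowest E²_NMF, then lowest restart
index). Restart counts around 100 are recommended for final fits; the
best-of-restarts cost is non-increasing in the restart budget by
construction.

**Multiplicative (`mult`).** The module updates are the classic
ratio-of-gradient-parts rules applied to the concatenated trial blocks
(with `Q^s = W̃A^s` and `R^s = A^sW`):

    W ← W ∘ (Σ_s Q^sᵀM^s) / (Σ_s Q^sᵀQ^s W)
    W̃ ← W̃ ∘ (Σ_s M^sR^sᵀ) / (W̃ Σ_s R^sR^sᵀ)

The coefficient update splits the gradient of the *full* cost into
positive and negative parts, giving, for `s ∈ G_l`:

    A^s ← A^s ∘ (W̃ᵀM^sWᵀ + γĀ_l + (δ/n_l)Ā_l + (δK/S)Ā)
               / (W̃ᵀ(W̃A^sW)Wᵀ + γA^s + (δ/n_l)Ā + (δ/S)Σ_k Ā_k)

so γ pulls every trial toward its own task mean while δ's cross terms
push task means apart. The split is validated against central finite
differences of E² (unit and acceptance tests; 1e-6 relative).

A small guard (default 1e-12) is added to denominators; an entry that
reaches exactly zero stays zero (multiplicative absorption). Modules are
renormalized to unit sum once per outer iteration — *after* the two
module updates and *before* the coefficient update. The placement
matters: the module updates re-absorb the data's overall scale every
iteration, so normalizing after the coefficient update would cut that
scale out of the iterate before the coefficients can claim it, and the
feasible iterate would permanently under-reconstruct (a limit cycle we
measured at VAF ≈ −1.4 on the toy data). Normalizing before the
coefficient update lets `A` carry the scale and the iteration converges
normally. When γ = δ = 0 the renormalization is *compensated* (the
coefficient slices are multiplied by the inverse factors), which leaves
the reconstruction unchanged, makes E²_NMF provably non-increasing, and
makes the discriminative solver's γ = δ = 0 trajectory bit-identical to
the unsupervised baseline. With active discrimination terms the
constraint is imposed without compensation (the scatter terms are not
scale-invariant, so no compensation can preserve the cost) and
monotonicity of E² is no longer guaranteed — it is not asserted.

**Alternating constrained least squares (`als`, `als_qp`).** The module
subproblems are convex quadratics with linear unit-sum constraints. The
fast path solves the equality-constrained normal equations as a KKT
linear system lifted with Kronecker products, then clips negative
entries to zero and renormalizes (clipping voids the descent guarantee);
a singular KKT system is re-solved with a small ridge and a warning. The
`als_qp` variant instead solves the bound-constrained QP (SLSQP from a
feasible incumbent, keeping the incumbent if no improvement is found),
so its module steps never increase the module objective. Coefficients
keep the multiplicative rule in both variants; how (or whether)
coefficients are re-estimated inside each outer iteration is not pinned
down by the update equations themselves, and reusing the multiplicative
rule is this package's documented choice.

**Nonlinear programming (`nlp`).** All blocks are stacked into
`z = (vec(W̃), vec(A¹)…vec(Aᔆ), vec(W))` (column-major vec throughout)
and E²(z) is minimized with SLSQP using the analytic gradient, bounds
`z ≥ 0` and the unit-sum rows as linear equality constraints. A restart
whose final constraint violation exceeds 1e-6 is discarded; if all
restarts fail, an error carrying the best infeasible iterate is raised.
On the toy problem all three solvers agree in final cost to well under
2% and return matching modules (acceptance test).

**Projection.** New data are mapped onto fixed modules by running only
the γ = δ = 0 coefficient update (labels unused). The subproblem is
convex with a unique minimum whenever the Kronecker factor `Wᵀ ⊗ W̃` has
full column rank; convergence is linear at a rate set by its condition
number, so the default budget is generous (50 000 iterations) and the
stopping rule compares the error change to the *data norm* rather than
the current error — on noise-free data the error decays geometrically to
zero and a purely relative criterion would never fire.

## Evaluation metrics

* **VAF** = 1 − E²_NMF / Σ_s ‖M^s − M̄‖²_F, with `M̄` the across-trial
  mean pattern; 1 for exact reconstruction, negative for models worse
  than the mean, undefined (explicit error) when all trials are
  identical.
* **DEC**: leave-one-out decoding of the task from `vec(A^s)` with a
  Gaussian linear discriminant (pooled within-class covariance,
  empirical priors). A singular pooled covariance is ridge-regularized
  with λ = 1e-6·trace/dim and a warning. A resubstitution variant
  (`lda_decode_resubstitution`) is provided and labelled distinctly;
  leave-one-out is the default everywhere.
* **VDM** = VAF × DEC, with negative VAF clamped to zero so VDM ∈ [0,1].
* **J** = tr(S_w)/tr(S_b); smaller is more discriminable; undefined for
  a single task.
* **CLS**: over repeated stratified train/test splits (default 20),
  modules are fitted on the training trials only, *all* trials are
  projected onto the fixed modules without labels, and a linear SVM
  (C = 1) trained on the training coefficients is scored on the test
  coefficients.
* **Module similarity**: Pearson correlation of matched module pairs
  under the assignment maximizing total correlation (Hungarian
  assignment; an exhaustive-permutation oracle backs it in tests).
  Zero-variance modules yield an undefined correlation, reported as
  missing.

## Tuning and model order

γ and δ are tuned by maximizing VDM: a coarse log-spaced grid including
the pure-reconstruction cell (0,0) — default
{0, 1e-4, 1e-3, 1e-2, 1e-1, 1}² — followed by a Nelder-Mead refinement
in log10 coordinates started at the grid optimum (zeros floored at
1e-8), with fixed fitting seeds so the objective is deterministic and
the refined VDM never falls below the start's. Tuning uses in-sample
decoding deliberately; no nested cross-validation is attempted. The
model order (P, N) is selected by a decoding-plateau rule: the most
compact order (smallest P·N, then P+N, then P) whose DEC is within a
tolerance — default one binomial standard error — of the best over the
searched ranges.

## Synthetic data

The generator emulates trial-to-trial EMG variability in a discrete-task
experiment: per trial of task k, coefficients are drawn entrywise from a
normal with mean `task_mean_coeffs[k]` and SD = cv·mean, truncated at
zero (default cv 0.1); the clean signal `W̃A^sW` is then corrupted as

    observed = max(0, signal·(1 + f·u) + f·σ̄·v)

with `u, v` standard-normal fields, `σ̄` the trial's mean absolute signal
level and `f` the noise fraction — one multiplicative and one additive
component, each scaled to a fraction `f` of the signal (default 0.4).
How a stated overall noise fraction should be split between additive and
multiplicative components, and whether it refers to SD or amplitude, is
underdetermined; this law is the package's documented choice, and the
measured deviation scales linearly with `f` (tested at 0.2 vs 0.4).

Two packaged designs:

* `toy_spec`: T = M = 2, P = N = 2, four tasks × ten trials (S = 40),
  task-mean coefficient matrices pairwise separated by ≥ 5 within-task
  SDs so the tasks are perfectly discriminable from the true
  coefficients by construction, 40% noise.
* `arm_pointing_spec`: T = 50, M = 9, P = 3, N = 4, 16 tasks × 40 trials
  (S = 640); triphasic-inspired temporal modules (early burst, late
  burst, double burst), four sparse muscle groupings, cosine direction
  tuning of the task means over 8 movement directions with the 8
  fast-speed tasks scaled by 1.8.

`recovery_score` matches fitted to true modules by maximal-correlation
assignment and correlates the per-task mean fitted coefficients (under
that pairing) with the realized per-task means of the true coefficients.

**Toy operating point.** `toy_tuned_params()` returns (γ, δ) = (8, 0.1).
The toy dimensions admit a full-rank factorization, so the unsupervised
objective can reach VAF ≈ 1 by absorbing the 40% noise into the
coefficients — which is exactly the failure mode the discriminative
extension addresses, but it also means plain VDM maximization favors
that overfitted solution on this design. The toy weights are therefore
calibrated to the simulation study's goal instead: the smallest within-
task weight that yields perfect leave-one-out decoding robustly across
generator seeds while leaving module recovery intact, with a mild δ that
stays far from the regime where −δ·tr(S_b) distorts reconstruction.

What passing on synthetic data does and does not show: the generator
produces exactly factorizable signals plus unstructured noise, balanced
tasks, and stationary modules. Real EMG has correlated noise,
non-stationarities, imperfect time normalization and modules that may
drift across the session — none of which are modeled — so synthetic
results validate the *algorithms*, not the physiological claims.

## Preprocessing

Raw signed EMG is full-wave rectified and low-pass filtered with a
zero-phase (forward-backward) Butterworth, 3 Hz cut-off, 4th order by
default (the order is configurable; 2nd-order applied twice is common),
output clipped at zero against filter undershoot. Trials are resampled
to 50 time steps by per-muscle linear interpolation, and each muscle is
divided by its maximum over the entire experiment. Note a rectified
carrier retains a DC level (2/π of the amplitude for a sinusoid) by
design — the low-pass removes the oscillation, not the level. Trial
segmentation (movement onset/offset detection) is out of scope; inputs
are pre-segmented trials.

## Numerical and design notes

* Trials are stored in a (S, T, M) array; sample indices in the Python
  API are 0-based storage order.
* vec(·) is column-stacking everywhere (scatter, decoding features,
  gradients, NLP packing).
* Degenerate all-zero modules encountered during normalization are
  replaced by uniform vectors with a warning, with the matching
  coefficient slices zeroed so the reconstruction is preserved.
* Determinism: identical data and options (including seed) reproduce
  bit-identical fit histories on one platform.
* Test problem sizes: unit and acceptance tests run the toy design
  (S = 40, T = M = 2) with up to 100 restarts × 20 generator seeds, and
  the arm-pointing-scale design (S = 640) for single noise-free fits.

## Known limitations

* Discrete task labels only; continuous task parameters are not
  supported.
* No sparsity or smoothness penalties on modules.
* The multiplicative solver's E² descent is not guaranteed under the
  uncompensated unit-sum renormalization (inherent to the formulation);
  use `als_qp` when strict module-step descent is required.
* The projection onto fixed modules uses reconstruction only, so the
  extra task information in discriminatively fitted coefficients does
  not transfer to held-out data; generalization (CLS) of the two
  solvers is therefore expected to be similar.
* LDA assumes shared within-class covariance; heavily unbalanced or
  strongly heteroscedastic designs will degrade DEC as an absolute
  measure (relative comparisons remain meaningful).
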