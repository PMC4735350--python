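# Methods

This note records the models, conventions, parameter choices, and numerical
decisions behind `grouppca`, and what the synthetic studies do and do not
demonstrate.

## Model and conventions

All solvers target the same object: the top-`k` eigenpairs of the group
sample covariance `C = YᵀY/(v−1)` of the temporally concatenated, column-
centered data `Y = [Y_1 … Y_M]` (v rows = voxels/samples, Mp columns). The
nonzero spectrum of `C` equals that of the voxel-dimension covariance
`C^v = YYᵀ/(v−1)`, which is what the iterative solvers implicitly power.

**Whitening convention.** A `PCAResult` always carries (a) the orthonormal
spatial basis `X` (left singular subspace of `Y`), (b) eigenvalues of `C`,
(c) `whitened = X·sqrt(v−1)` so whitened columns have unit *sample variance*
(`whitenedᵀ·whitened/(v−1) = I`), and (d) the back-projection eigenvector
matrix `F = Yᵀ X` with columns normalized to unit L2. Printed formulations of
these solvers are not mutually consistent about the whitening scale (a
`Λ^{−1/2}` column scaling appears in some finalizations); we standardize on
unit sample variance everywhere and keep the orthonormal basis separately.
MPOWIT exposes the literal `X_j W_j Λ_j^{−1/2}` scaling behind
`verbatim_scaling=True` for compatibility.

**Sign convention.** Each basis column is flipped so its largest-magnitude
entry is positive; `F` is flipped jointly. This makes outputs deterministic
across runs and LAPACK backends. Columns inside a degenerate (tied-
eigenvalue) block are only defined up to rotation; tests therefore compare
subspaces by principal angles, never individual tied vectors.

**Centering.** Providers never re-center; `center_columns` is an explicit
pipeline step tracked by a flag, so double-centering cannot happen silently.
NaN/Inf anywhere is an error — missing data is out of scope.

**Voxel order.** Masked voxels are linearized in fixed column-major (Fortran)
grid order on every I/O path, so masks, matrices, and subsampling schemes
always index voxels identically.

## Solver-specific decisions

**Exact EVD.** The covariance is formed in the smaller dimension: the
`Mp × Mp` cross-covariance by subject blocks (two subjects resident at a
time) or the `v × v` subject-covariance sum (one resident, exactly M
dataloads). Hardware-specific RAM guidance is replaced by configurable
dimension caps (default 20000): exceeding both caps raises an error naming
the iterative alternatives. Top-k extraction uses a restricted symmetric
solver (ARPACK, tol 1e−6, 1000 iterations max) for large covariances and a
dense LAPACK subset solver below n = 600 (or when k is a large fraction of
n), where the dense path is faster and exact.

**SVP.** The all-odd/all-even sublattices are defined by 1-based coordinate
parity at depth 2 (an 8× voxel reduction on a full 3-D grid); for non-spatial
fixture data, strided sets with offsets 0 and depth−1. Two printed-formula
corrections were required for internal consistency: (1) the time-dimension
eigenvector estimates `F_a = Y_aᵀ X_a` are column-normalized to unit L2
before projection, matching the eigenvector-matrix convention used
everywhere else — without this the merged eigenvalues come out on a squared
scale; (2) the joint Gram of `[X_a, X_b]` is divided by 2, because both
blocks estimate the *same* covariance (unlike STP's disjoint column groups)
and the raw concatenation double-counts shared variance. With both fixes,
lossless subsampling (odd rows ≡ even rows) reproduces exact EVD
eigenvalues identically and the Rayleigh–Ritz upper bound holds.

**STP.** Groups are formed in input order (a seeded shuffle is available);
merges use variance-weighted (non-whitened) blocks — dropping intermediate
whitening is precisely what distinguishes this method from the older
three-step reduction. The running subspace is truncated to the top k′
columns after every merge (required for bounded memory), and the single
`Λ^{−1/2}` normalization happens once at the end. The first group must
satisfy `g·p ≥ k′`; otherwise k′ is lowered with a warning (that lowering is
what makes the `g = 1` MIGP special case run).

**Back-projection and dataload contracts.** Computing `F = Yᵀ X` costs one
extra pass. STP's single-pass and SVP's two-pass contracts would be broken
by it, so the subsampled solvers return `backproj=None` by default;
`attach_backproj(result, provider)` adds it with an honestly counted pass.
MPOWIT computes `F` by default (counted separately from its `(j+1)·M`
iteration total); EM PCA and Large PCA obtain `F` for free from their
finalization pass.

**Large PCA.** Defaults `b = 170`, `j0 = 6` (random start) and `j0 = 1`
(warm start) are adopted as constants from the published parameter study.
The singular-value convergence check uses the absolute L2 norm over the
top-k values only (a relative option exists): monitoring the small subset of
interest is the point of the convergence-checked variant. Re-
orthogonalization is a full rank-revealing (pivoted) QR of the whole Krylov
matrix at every check — correctness over speed at desk scale — with
numerically dependent columns dropped under warning; on low-rank problems
the basis collapses to the data rank and the method becomes exact. Each
block is scaled to unit Frobenius norm when appended: a scalar per-block
scaling leaves span(Kr), χ, and all Ritz values unchanged while preventing
float overflow from unnormalized covariance powers. If the initial basis
`(j0+1)·b` would not fit the voxel dimension, `b` is reduced with a warning.

**MPOWIT.** Defaults `l = 5`, tol 1e−6, max 1000 iterations; `l·k ≤ 500`
unless explicitly overridden (the small-EVD orthonormalization `orth_evd` —
EVD of the `(lk)²` Gram, then column normalization — is only cheap while the
subspace stays small). Eigenvalue extraction per iteration is a full dense
EVD of the `(lk) × (lk)` projected covariance followed by truncation to k:
at this size a full EVD is cheaper and exact compared to a restricted
solver. The convergence reference starts at `Λ_0 = 0` (cold) or the warm-
start eigenvalues, so a cold run can never stop before the second iteration.
Eigenvalues are evaluated after the covariance product in each iteration,
consistent with the update order of the defining recursions. A single seeded
generator draws the Gaussian start once, so stacked and un-stacked runs with
a shared seed are bit-identical.

**EM PCA.** The raw stopping rule `‖X_j − X_{j−1}‖ < δ` is sign- and
rotation-sensitive (the EM fixed point is a subspace, not a matrix). The
default criterion is therefore the sine of the largest principal angle
between successive iterate subspaces, with the sign-aligned Frobenius and
verbatim variants behind `criterion=`. The default tolerance is 1e−7 rather
than the 1e−6 used by the eigenvalue-based stops: a subspace-change
criterion is *linear* in the remaining subspace error while eigenvalue error
is quadratic in it, so matching the eigenvalue-based solvers' final accuracy
requires a tighter subspace tolerance. Finalization orthonormalizes the
converged subspace and solves the small projected-covariance EVD; the
back-projection matrix falls out of the same pass. The "accelerated EM"
idea (enlarged projecting subspace) is exposed simply as MPOWIT — the two
methods provably traverse identical subspaces per iteration, which
`subspace_equivalence` verifies numerically (angles at machine precision on
the canonical fixture).

## Synthetic data: what it emulates and what it does not

`generate_group` plants a shared orthonormal, zero-mean spatial basis `Q`
(v × r) with per-subject data `Z_i = Q·diag(sqrt(spectrum·(v−1)))·A_iᵀ +
noise`, `A_i` a random orthonormal temporal mixing. Consequences used by the
tests: a noiseless subject's time covariance has eigenvalues exactly
`spectrum`, and the noiseless group covariance has eigenvalues exactly
`M·spectrum` on `span(Q)` — machine-precision recovery targets. Optional
Gaussian smoothing over a synthetic 3-D grid produces the spatial dependence
that motivates voxel subsampling.

The noise model is i.i.d. Gaussian in data space. It does **not** emulate
fMRI temporal autocorrelation, hemodynamics, motion, scanner drift, or
between-subject spatial misalignment. That is deliberate: these solvers are
data-agnostic linear algebra, and what the tests certify is numerical
behavior (accuracy vs the dense oracle, convergence counts, I/O accounting,
invariances) — not neuroscientific validity on real data.

Fixtures run the full two-stage pipeline (subject-level PCA before the group
provider). Subject whitening — an optional step of that pipeline — is off by
default in the fixtures: with a *shared* planted basis, whitening every
subject collapses the group spectrum into a near-degenerate cluster at M
(sum of rank-p projections), leaving top-k subspaces ill-conditioned and
recovery targets unusable. Non-whitened subject scores preserve the planted
spectrum. Whitening itself is tested separately at the subject level.

## Canonical study conditions

The `small` profile defines the conditions used by the acceptance studies
and was fixed before those studies were run: v = 3000, t = 60, M = 10,
p = 20, planted rank r = 20 with spectrum 20…1 (unit gaps), noise σ = 1,
seed 0; solver parameters k = 10, k′ = 50, g = 3. The intermediate model
order keeps the full-scale ratio k′ = 5k (500 at k = 100); the group size
g = 3 both yields several merge steps with M = 10 and satisfies STP's
`g·p ≥ k′` precondition (60 ≥ 50). The `tiny` profile (v = 500, M = 4,
p = 10) supports exhaustive invariant checks with a sub-second dense oracle;
`medium` (v = 8000, M = 40, p = 30) exists for larger streamed runs. All
profiles complete any single solver run in seconds on one CPU.

## Numerical edge cases

* Rank-deficient Grams, group covariances, and Krylov bases drop
  numerically null directions (relative threshold 1e−12) with a warning;
  dropping below k directions is an error ("rank collapse").
* Eigenvalues in (−1e−12, 0) from round-off are clipped to zero; anything
  more negative fails validation.
* Ties: see the sign/degeneracy note above.
* `orth_evd` on a single column reduces to L2 normalization; on an
  orthonormal input it returns an orthonormal basis of the same span
  (possibly rotated).
* Dataload semantics: stacked mode charges M once at materialization;
  un-stacked charges one per subject access. Cross-mode equality is exact
  (not merely within tolerance) because both modes execute the same
  per-subject accumulation loop.

## Known limitations

* No missing-data support; NaN is an error by design.
* The RAM-budget arithmetic behind `select-method` (`8·v·M·p` bytes times a
  working-set factor) is a portable approximation, not a measured model.
* SVP assumes the subsampled lattices are representative (spatial
  smoothness); on spatially white data its eigenvalue error is dominated by
  the half-lattice sampling noise, as the accuracy-ordering study shows.
* No GPU or distributed execution; per-subject granularity is the only
  out-of-core unit (no sub-subject voxel tiling).
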