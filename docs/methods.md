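# Methods

This note documents the models and procedures `hemigrad` implements, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Denoising of parcellated series

Volumes with FD > 0.35 mm or DVARS > 50, plus one volume forward and two
back (clipped at the series bounds), are censored. The pipeline order is:
cubic-spline interpolation of censored volumes over the kept time grid,
linear detrend, first-order Butterworth band-pass (0.01–0.1 Hz) applied
forward-backward (zero phase; phase handling is otherwise unspecified and
zero-phase is standard for resting state), removal of censored volumes,
nuisance regression, per-region z-scoring. Confounds are detrended and
band-passed with the *same* filter before regression so that regression
is orthogonal to filtering — regressing raw confounds after filtering the
data would reintroduce out-of-band variance. Motion-parameter expansions
(e.g. the 24-parameter set) are accepted as a ready-made confound matrix;
the module does not compute them. Subjects with less than 240 s of data
after scrubbing are excluded at the pipeline level.

One caveat discovered while validating GSR: after per-region z-scoring,
the *post-hoc* region mean of the output is a unit-norm contrast of the
residuals (the squared correlations with the output series sum to one by
construction), so it cannot be strictly uncorrelated with every region.
The meaningful invariant — exact orthogonality of every output series to
the global-signal regressor that entered the design — holds to machine
precision and is what the tests assert.

## Hemispheric gradients

Fisher-z FC (correlations clipped to ±(1 − 1e−7); zero diagonal) is cut
into pair-indexed LL/RR/LR/RL blocks, so row *i* of LL and RR refer to
homotopic regions. Each block is column-thresholded to its top 10%
strongest (largest signed z) connections — ties at the cutoff keep the
lower index, deterministically. Seed profiles for the normalized-angle
affinity are the *rows* of the column-sparsified matrix; for LR this
makes left-hemisphere regions the seeds and for RL the right — exactly
the orientation the inter-hemispheric asymmetry index LR − RL requires.
A consequence worth knowing: a region that no column selects has a
zero-norm profile and raises an error naming it; this is essentially
impossible at realistic sizes (k = 20 of 200) but can occur in very small
or very noisy problems. The pipeline treats an affected subject as a
quality-control exclusion (logged); a failure in the group template
aborts the run.

The affinity is embedded by anisotropic diffusion maps with α = 0.5: the
affinity is α-normalized, the random-walk operator is eigendecomposed
through its symmetric conjugate for stability, the trivial stationary
component is divided out and dropped, and nontrivial components are
scaled by λ/(1−λ) (the automatic multi-scale convention; λ^t is available
via `diffusion_time`). Variance explained is reported as λ_k/Σλ over the
retained nontrivial components (the denominator convention is not
otherwise pinned down; this one is documented and tested). Group
templates embed the cohort-mean intra block (per-subject (LL+RR)/2
averaged over subjects — the per-subject symmetrization makes templates
bitwise invariant to hemisphere relabeling) and likewise (LR+RL)/2;
provenance `hc_only` restricts the average to controls. Each subject's
10-component embedding is aligned to the template by a single-pass
orthogonal Procrustes rotation (no centering, no scaling); alignment
absorbs eigenvector sign flips and rotational indeterminacy, which the
tests verify. AI uses only the first 3 aligned components; components
4–10 participate in alignment only. The ratio form (LL−RR)/(LL+RR) is
deliberately not offered: gradient scores are signed and a signed
denominator exaggerates or breaks the index.

## Group statistics

ComBat is the parametric empirical-Bayes location/scale model,
implemented to agree with the canonical R implementation
(cross-checked in the test suite against `sva::ComBat` to ~1e-4): batch
indicator + covariate regression, pooled-variance standardization,
normal/inverse-gamma priors estimated across features, EB conditional
means iterated to a relative tolerance of 1e-4. The group label is *not*
in the ComBat design (only age, sex and mean FD are), matching the
described procedure; callers may pass any covariate matrix. Note that EB
shrinkage makes ComBat only asymptotically idempotent: a second pass
moves features by a residual of the order of the batch-moment sampling
noise times the shrinkage fraction (a few percent of a feature's scale at
n ≈ 100/batch), not by zero.

The MDD–HC comparison per unit (region pair, or Yeo-7 network after
unweighted averaging of member pairs) is a multivariate GLM
`Y = Xβ + E` with `X = [1, group, age, sex, meanFD]` and the G1–G3 AI
triplet as response. The group effect is tested by Hotelling's
T² = b̂ᵀ[(cᵀ(XᵀX)⁻¹c)·Σ̂]⁻¹b̂ with Σ̂ = EᵀE/(n−r), referred to
F(p, n−r−p+1) through the exact transform; BH-FDR is applied across
units separately for intra and inter scopes, and per-gradient post-hoc
t-tests use the threshold p < 0.05/3. Type-I calibration under a
simulated null and the T² = t² identity for p = 1 are verified in the
acceptance suite. Sex enters as a binary indicator; age and mean FD are
untransformed.

## Prediction

The elastic net uses n_splits random 4:1 subject splits; train and test
partitions are ComBat-harmonized *separately* (covariate-aware, fitted
independently per partition), features are z-scored with training
statistics, and an inner 5-fold CV over 20 log-spaced penalties in
[1e-4, 1] picks the minimum-MAE alpha (ties to the smaller penalty).
The target is standardized inside each fit and predictions are mapped
back — this makes the penalty grid scale-free, so the top of the grid
can shrink every coefficient to zero and a signal-free fit degrades to
the training mean rather than fitting noise (without it, the
cross-validated r of a null model is biased visibly negative by
finite-sample train/test anti-correlation). A fully shrunk (constant)
prediction is scored r = 0. The permutation null shuffles the target and
reruns the nested procedure on a shared set of splits (harmonization and
feature scaling do not depend on the target, so they are computed once);
permutation runs default to a reduced outer split count (20) for
tractability, and p = (1 + #{null ≥ observed})/(1 + n_perm).

## Synthetic cohorts

The generator's defaults define the benchmark conditions:

- **Latent structure.** Homotopic pairs carry latent positions
  `g = linspace(−1, 1)`; region covariance is
  `K_ij = exp(−(g_i−g_j)²/2ℓ²)` with ℓ = 0.5, mirrored across
  hemispheres; inter-hemispheric blocks are 0.6·K plus a homotopic boost
  (0.2) entering as a shared per-pair signal on all block diagonals,
  which keeps the matrix positive semidefinite by construction. Five
  equal-norm random "distributed component" loadings (strength 0.5) add
  hub-like bilateral structure; equal norms matter, because unit-diagonal
  normalization would otherwise systematically weaken high-loading
  regions' correlations. With all offsets zero the population FC
  satisfies LL = RR and LR = RLᵀ exactly.
- **Asymmetry.** Baseline left offsets ~ N(0, 0.02) on every pair;
  subject jitter sd 0.04; group effects of nominal size 0.065 planted in
  the default-mode and salience/ventral-attention networks for MDD
  subjects only. Signs alternate in runs of four (disorders shift some
  regions leftward, others rightward; a sign-balanced pattern also avoids
  a first-order amplitude change of the left spectrum). Because the same
  latent shift moves different pairs by very different amounts in the
  embedding, per-pair magnitudes are calibrated against the deterministic
  (noise-free) population pipeline — three damped fixed-point iterations
  equalizing the downstream AI response, with displacements capped at 2×
  the nominal size and shifted positions kept inside the latent range.
  The nominal size was chosen once so that the realized per-gradient
  group difference lands near Cohen's d ≈ 0.5 at n = 100/group with
  region-level detection power around 0.8.
- **Sites and noise.** Per-site additive offset (sd 0.03) and
  multiplicative scale (0.9–1.1) on Fisher-z edges — exactly ComBat's
  location/scale model — plus symmetric edge noise (sd 0.05). Subject
  correlation matrices are projected to the nearest SPD matrix
  (eigenvalue clipping, unit-diagonal rescale) before Cholesky sampling.
- **Covariates and BDI.** Age ~ N(43, 11) truncated to [18, 80]; sex
  Bernoulli(0.5); mean FD from simulated per-volume traces (baseline
  |N(0.10, 0.04)| with 2% spikes) whose mean populates the phenotype.
  BDI-II is a sparse linear function (10% nonzero weights) of the
  per-subject latent asymmetry vector, scaled to an in-sample R² of 0.3,
  mapped to 12 ± 8 and clipped to 0–63.

**What the generator does not emulate.** Time series are temporally
white: there is no autocorrelation, no aliased physiology, and no real
motion artifact structure, so the band-pass stage removes most of a
synthetic subject's variance rather than little of it. Synthetic-cohort
analyses therefore run with `prep=False` (the series are already clean),
and the denoising stage is validated against its own contracts
(filter response, censoring rule, confound orthogonality) instead.
Passing benchmarks here shows the pipeline recovers structure *it is
pointed at*; it does not certify performance on real BOLD data.

**Propagation of planted effects.** A deliberately planted FC-level
perturbation is not confinable: the diffusion embedding is a global
nonlinear map, so "unaffected" pairs acquire genuine (small) group
differences — in the noise-free population pipeline their AI shift is
roughly a quarter of the planted pairs' response on average, with a tail
reaching most of it, varying with the random truth draw. The end-to-end
benchmark reports sensitivity on planted pairs and the flagged fraction
among unplanted pairs with this caveat: the latter is *not* a false-positive
rate against a true null, and FDR behaves accordingly. Sign-balanced
planting, response calibration, and run-length choices reduce but cannot
eliminate the propagation; alternatives we measured (scattered layouts,
coherent per-network shifts, orthogonal latent dimensions, strong modular
localization) were all strictly worse for the signal-to-propagation
ratio or destroyed gradient recoverability.

## Numerical choices and degenerate inputs

- Correlations are clipped to ±(1 − 1e−7) before arctanh; FC diagonals
  are zero.
- Eigen-decompositions use the symmetric conjugate form; component order
  is by descending eigenvalue with ties left to the solver and absorbed
  by alignment. Nontrivial eigenvalues ≥ 1 (numerical) are clipped to
  1 − 1e−12 with a logged warning.
- Zero-variance regions, zero-norm profiles, singular designs, singleton
  batches, and constant prediction targets raise errors naming the
  offending object; the pipeline converts per-subject embedding failures
  into logged exclusions, mirroring quality-control practice.
- Determinism: every stochastic routine takes a seed and uses an
  independent `numpy` Generator; reruns are bitwise identical, and
  written outputs embed the seed and a hash of the scientific
  configuration (the output path is excluded from the hash).

## Problem sizes used in the benchmark suite

Acceptance-style checks run at sizes a single core handles in minutes:
100 homotopic pairs (200 regions) and 240 volumes for the end-to-end
recovery benchmark (20 replicate cohorts of 100 subjects per group over
4 sites), 200 pairs for the feature-space contract, 500 volumes and 20
subjects for latent-gradient recovery, 2000 simulated null datasets for
test calibration, and feature-level cohorts (150 × 60) with 500
permutations for the prediction benchmarks. These sizes are the
package's own benchmark definitions; the library itself has no
size-specific logic.
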