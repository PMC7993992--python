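# Methods

This note documents the generative model, the analysis pipeline, the
parameter choices that matter, and what the synthetic validation does and
does not establish about real data.

## 1. The scientific question and the study design

Conventional connectome-based prediction reduces functional connectivity to
region-pair means ("coarse-grained"). The hypothesis examined here is that
individual differences in a latent trait are carried predominantly by
fine-grained, vertex-level connectivity patterns — patterns that are not
comparable across brains until each person's idiosyncratic cortical
topography is factored out. Connectivity hyperalignment (CHA) does exactly
that with one orthogonal transform per subject and region.

The package tests the *mechanism* end to end on synthetic cohorts with known
ground truth: a trait planted selectively in fine-grained structure must be
recovered best from hyperaligned residual fine-grained profiles, worse from
coarse profiles, and worse from fine profiles left in each subject's native
(merely anatomically aligned) topography.

## 2. Generative model of the synthetic cohort

For subject *i*, region *r* (sizes: `V` vertices, `R` regions, `L` latent
sources per region, `K` global sources, `T` timepoints):

```
x_{i,r}(t) = Q_{i,r} · W_{i,r} · A_r · u(t)  +  1 · γ_{i,r}ᵀ z(t)  +  ε(t)
```

* `u` — `K` global source series shared by the cohort; `A_r` mixes them
  into `L` regional latent sources. Sharing the sources across subjects
  makes the all-effects-zero generator collapse to identical subjects, a
  useful degenerate test case.
* `W_{i,r} = W_r + fine_effect·g_i·D_r + weight_noise·E_{i,r}` — vertex
  weights. The rows of `W_r` are normalized so every vertex has unit signal
  variance (correlation and covariance block means then coincide).
* `γ_{i,r}` — a region-uniform loading on `K_c` dedicated coupling sources
  `z`; the trait and idiosyncratic variation rotate the loading vector by an
  angle `coarse_effect·g_i + coupling_noise·ε_{i,r}` at constant norm.
* `Q_{i,r}` — a mean-preserving orthogonal matrix (`Q·1 = 1`), geodesically
  interpolated from the identity toward a Haar-uniform rotation by
  `rotation_dispersion`, with a reflection composed in with probability
  `dispersion/2`.
* `ε` — white noise with sd `noise_sd`.

### Exact scale separation

The design guarantees, by construction rather than on average, that each
planted effect lives only at its intended scale:

* `D_r` has zero column means → the fine effect never moves region-mean
  time series (the CHA targets) or coarse block means;
* `D_r` rows are orthogonal to `Σ_r w_v` (sample metric) → per-vertex
  variances are trait-free to first order, so *correlation* block means stay
  trait-free, not only covariance block means;
* `D_r` rows are orthogonal to the `R` seed-profile directions → the fine
  trait signal is invisible to the vertex-to-region-mean profiles CHA fits
  on, so fitted transforms are trait-free and alignment cannot absorb
  ("overalign away") the planted signal. This constraint needs
  `n_latent_sources > n_regions + 1`; with fewer latents it is skipped.
* the coupling component is strictly region-uniform and of constant norm →
  block-demeaning removes it from residual profiles exactly, and vertex
  variances do not depend on the trait through it;
* coupling sources are made exactly sample-orthogonal to the global sources
  (and sample-orthonormal) so these statements hold at finite `T`, not just
  in expectation.

Mean preservation of `Q` deserves a note: topographic idiosyncrasy is
modeled as a rearrangement of the fine pattern that leaves the regional mean
signal intact. That is both the physiologically sensible reading (regional
mean time series are robust across individuals) and a necessary one — CHA
uses region means as its shared connectivity targets, and fully
unconstrained rotations would destroy the very targets the method needs.

### Default parameters (the study conditions)

| parameter | default | rationale |
|---|---|---|
| subjects / families | 120 / 53, sizes 1–5 (`{1:10, 2:24, 3:15, 4:3, 5:1}`) | the reference cohort's family-size histogram scaled to 120 subjects |
| regions × vertices | 24 × ~30 (V = 720) | desk scale; keeps the full pipeline ≈ 1 min |
| runs × timepoints | 2 × 300 | desk-scale stand-in for multi-run resting scans |
| `n_latent_sources` / `n_global_sources` | 30 / 36 | regional signal of full rank; must exceed `n_regions+1` for the seed-orthogonal trait direction |
| `fine_effect` / `weight_noise` | 0.35 / 0.35 | trait-linked and idiosyncratic fine variation of equal size: the trait explains ~50% of subject-level fine pattern variance |
| `coarse_effect` / `coupling_noise` | 0.07 / 0.35 | coarse trait effect one fifth of the fine effect, against idiosyncratic coupling variation of the same size as in the fine channel |
| `rotation_dispersion` | 0.5 | halfway between perfect anatomical alignment and fully random topography |
| `noise_sd` | 0.5 | 20% noise variance per vertex; keeps seed profiles informative enough for transform estimation |
| within-family g correlation | 0.4 | relatives resemble each other enough that ignoring family structure would be consequential |

Bifactor test-score generator: ten tests, g loadings 0.80…0.55, three group
factors with loadings 0.45, residual sd 0.5. This yields regression g-score
determinacy ≈ 0.92 at large n (the order of well-constructed batteries) and
g carrying ≈ 70% of the common variance.

Effect sizes are free parameters of the synthetic design, not calibrated to
any empirical dataset; a "task-like" (stronger effect) versus "rest-like"
(weaker effect) contrast can be emulated by scaling `fine_effect`.

## 3. Pipeline choices

**Preprocessing.** Fixed order: percent signal change → Gaussian low-pass
(σ = 1 timepoint, kernel truncated at ±4σ and renormalized so DC gain is
exactly 1, reflection boundaries) of data *and* regressors → least-squares
nuisance removal. Motion derivatives are backward differences with a leading
zero per run; tissue PCs are computed per run on column-centered signals;
the global signal is the vertex mean of the PSC data (computed after PSC).

**Hyperalignment.** Per region, two-pass template construction: pass 1
aligns subjects sequentially to a running average seeded by the first
subject; pass 2 re-aligns everyone to the pass-1 mean and averages; final
transforms are re-fit to that template. Deterministic given subject order
(recorded in the model). Seed profiles are z-scored per vertex before
fitting — this removes scale leverage without introducing any scaling into
the transform itself, and profiles are recomputed on untouched data
afterward. The Procrustes solution comes from the SVD of
`source·templateᵀ`; sign conventions make degenerate subspaces
deterministic. When there are fewer targets than vertices the optimum is
not unique: the unconstrained subspace is completed with the *minimal*
rotation (transform as close to the identity as the data allow), so no
direction is scrambled arbitrarily. Transforms fit on one dataset are never
applied to another unless cross-dataset alignment is explicitly requested.

**Profiles.** Raw Pearson correlations (no Fisher z). The seed region's own
block, including its exact 1.0 self-correlations, is retained — constant
features vanish under PCA centering downstream. Coarse profiles are
computed on the same (hyperaligned or identity) data as fine profiles.
Under mean-preserving remixing, coarse profiles are nearly (not exactly)
invariant: correlations renormalize per vertex, so invariance is asserted
empirically at tolerance rather than algebraically.

**Prediction.** PCA with centering only (profiles share units), ridge on PC
scores with intercept. Because fine-profile feature matrices are tall
(features ≫ subjects), the entire cross-validation engine runs on the
subjects × subjects Gram matrix: training PCA by eigendecomposition of the
doubly centered training block, test scores by centered cross-products, and
the closed-form ridge path (PC scores have diagonal covariance) evaluates
the full 81-point α grid at negligible cost. A dedicated test proves the
Gram route equal to the explicit PCA+ridge fit to 1e-8. Outer folds leave
out one family (or repeated family-grouped 10-fold); inner selection uses
three family-aware sub-folds, maximizes inner cross-validated R², and
breaks ties toward fewer PCs, then larger α. Default desk-scale PC grid
`(10, 20, 40, all)`; the canonical grid `(10, 20, 40, 80, 160, 320, all)`
is available where cohort size supports it.

**Inference.** Permutation p-values use `(1 + #{perm ≥ obs}) / (1 + n)`.
Block permutation shuffles within families and exchanges whole families
only among families of identical size (singletons form their own stratum);
the *entire* pipeline, nested selection included, is re-run per
permutation. Bootstrap CIs resample only the evaluation subjects (with
their per-subject training-mean nulls); trained models are never refit,
because training-set size and duplicate training instances would otherwise
bias the sampling distribution. Default 10,000 resamples (configurable;
reduced in the orchestrated contrast to keep runtimes short). Degenerate
resamples (zero null-model sum of squares) are redrawn and counted. The
idiosyncrasy index is the mean pairwise Frobenius distance between
subjects' transforms, residualized by OLS on √(region size), since the raw
norm is dominated by matrix dimension.

**g extraction.** Constrained maximum-likelihood bifactor fit (each test
loads on g and exactly one of three group factors, all factors orthogonal)
by L-BFGS-B on the Gaussian discrepancy, multiple jittered starts,
uniquenesses floored at 0.005 with a warning (Heywood protection). Scores
by the regression (Thurstone) method, standardized. Scores are internally
standardized, so any affine rescaling of a test column is irrelevant.

## 4. What the synthetic validation shows — and what it does not

Passing tests establish that the *pipeline* behaves as designed: transforms
are orthogonal and recover planted rotations; profile identities hold to
1e-10; the cross-validated R² equation and its null model are exact; the
permutation scheme is calibrated (null rejection ≈ 5% at α = 0.05); the
bootstrap covers a known VAF difference at ≈ 95%; and a trait planted in
fine-grained structure is recovered in the planted order
(hyperaligned-fine > coarse, hyperaligned-fine > identity-fine, margins
exceeding the across-region SE).

The generator deliberately omits much of real fMRI: no hemodynamics, no
spatial autocorrelation or surface geometry, no motion or physiological
artifacts, no scanner drift beyond polynomial trends, vertex variances
equalized by construction, and source time courses shared across subjects.
Real misalignment is also not a linear orthogonal transform of a common
pattern. Consequently the absolute R² values here (≈ 60–70% for the fine
condition) say nothing about attainable performance on real cohorts — only
the *orderings* and the *calibration* of the inferential machinery
transfer.

## 5. Numerical conventions and degenerate inputs

* Zero-variance vertices or targets raise errors naming the offender;
  single-subject cohorts get `g ≡ 0` rather than an undefined
  standardization.
* Eigenvalues below `1e-10 × λ_max` are treated as null directions in the
  Gram PCA; requested PC counts clip to the available rank with a warning.
* `α = 0` with all PCs reproduces OLS exactly; `α = 1e20` reproduces the
  training mean.
* All randomness flows through explicit integer seeds (`numpy` Generators);
  reruns are bit-identical.
* Runtimes on one CPU: full default experiment ≈ 1 min; acceptance script
  ≈ 2 min; test suite ≈ 2 min.
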