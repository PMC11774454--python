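# Methods

This note documents the models, the numerical choices and the limitations
behind `iobound`. It is written for someone who wants to understand what
the package actually computes before trusting its numbers.

## The detection framework

All quantities derive from a binary signal-detection task on simulated
multi-coil MRI measurements. An object `f` (a 2-D image) is measured
through a SENSE system,

    g_i = Phi F S_i f + n_i ,   i = 1..C,

where `S_i` are complex coil-sensitivity maps, `F` is the unitary,
DC-centered 2-D DFT, `Phi` keeps a subset of phase-encode lines (rows), and
`n_i` is complex Gaussian noise with standard deviation `sigma` per real and
imaginary component of every sampled entry. The task is to decide between

    H0: g = b + n          (background only)
    H1: g = b + s + n      (background plus signal)

with `b` and `s` the noiseless measurements of the background and of a small
Gaussian signal (default amplitude 0.7, width 2 mm on a 1 mm grid).

The ideal observer (IO) computes the likelihood ratio of `g` and maximizes
the ROC AUC over all observers. Acting on the raw measurements, its AUC
bounds what any reconstruction-plus-observer pipeline can achieve — the
package's central quantity.

## Analytic observers (BKE tasks)

When the background is known exactly, the log-likelihood ratio is available
in closed form:

* SKE (known signal): `t(g) = Re<s, g-b>/sigma^2 - ||s||^2/(2 sigma^2)`,
  with the inner product over sampled entries.
* SKS over a finite location set `{s_j}` with prior `p_j`:
  `log Lambda = logsumexp_j [log p_j + Re<s_j, g-b>/sigma^2 -
  ||s_j||^2/(2 sigma^2)]`.

The SKE detectability is `d'^2 = 2 * sum_sampled |s_k|^2 / sigma^2` and
`AUC = Phi(d'/2)`. The factor 2 is the complex-data bookkeeping: with noise
std `sigma` per real/imaginary component, the statistic's SNR is
`sqrt(sum|s_k|^2)/sigma` and `AUC = Phi(SNR/sqrt(2))`; both conventions
describe the same observer, and the package pins `d' = sqrt(2) * SNR` so
the `Phi(d'/2)` form is exact. The Monte-Carlo suite verifies this to
±0.01 at 10^4 draws.

Because equispaced masks with offset 0 nest across divisible accelerations
(R = 8 lines are a subset of R = 4 of R = 2), the sampled signal energy —
and hence `d'` — is exactly non-increasing in R. This is an algebraic fact,
not a statistical one, and is tested as such.

## Object models

The diffusion-model brain ensemble that motivated this framework is out of
scope; two parametric stochastic object models stand in for it:

* **Lumpy background**: `dc_offset` plus a Poisson number (mean 60) of
  Gaussian lumps (amplitude 8, width 4 mm) centered uniformly over the
  grid. Lumps are truncated at the grid edge (no wraparound); the test
  oracle for the ensemble mean integrates the truncated kernel explicitly.
* **Stylized brain**: head ellipse, cortical rim, white-matter interior,
  ventricle-like cavities and a few randomized internal structures, lightly
  smoothed; the white-matter region (minus cavities and structures) is the
  tissue mask from which signal locations are drawn.

Intensity scale. The defaults put the background around 30–60 intensity
units against noise sigma = 1.5. This is deliberate: the rSOS magnitude
operation is linear in the signal only when the underlying intensity
dominates the noise. If background ~ noise, the signal enters the magnitude
image only quadratically (random-phase Rician regime) and every image-space
observer sits at chance, which makes the bound-vs-reconstruction comparison
degenerate rather than merely pessimistic. `d'` itself is unchanged by the
background level (BKE), so the data-space bound is unaffected. The noise
level sigma = 1.5 is chosen so the reference signal gives d' = 2.34
(AUC 0.879) at full sampling — mid-range detectability where AUC
differences are informative. `NoiseModel`'s own default remains sigma = 15;
any study that uses it must scale object intensities accordingly.

What these generators do not emulate: anatomical variability between
subjects, partial-volume and texture statistics of real brain MRI, coupling
between tissue class and signal contrast. Passing tests therefore show the
*framework* is correct (bounds, observers, estimators), not that the
absolute AUC values transfer to clinical data.

## Coil model and sampling

Eight coils (configurable) sit on the circle circumscribing the grid at
angles `2 pi i / C`; magnitude falls off as a Gaussian of distance to the
coil center and phase grows linearly with that distance — a stylization,
not a field simulation. Normalization scales the maps so
`sum_i |S_i|^2 = 1` pixelwise, which makes rSOS at full sampling exactly
`|f|`. Masks are equispaced over DC-centered row indices with offset 0 by
default so that nesting (and exact bound monotonicity) holds; a
center_fraction option adds fully sampled central lines for conventional
variable-density-style sampling, at the cost of exact nesting.

## Reconstruction baselines

* **rSOS**: per-coil zero-filled inverse DFT, root-sum-of-squares across
  coils.
* **CG-SENSE**: Tikhonov-regularized normal equations
  `(A^H A + lam I) x = A^H g` solved with the conjugate-*residual* variant
  of CG. CR has the same per-iteration cost and fixed point as CG but
  guarantees a monotonically non-increasing residual norm on Hermitian
  positive-definite systems; plain CG is monotone only in the error A-norm
  and its residual trace oscillates on these problems. Non-convergence is
  reported in the result object, never raised.
* **Learned reconstructor**: a small encoder-decoder (two resolution
  levels, ~5k parameters) trained per acceleration factor on (noisy
  undersampled rSOS, true object) pairs with MSE loss. It predicts the
  reference image directly; two alternatives were evaluated and
  rejected for training stability at this scale — residual
  (input-minus-reference) regression stalls at the zero-correction
  plateau on smooth-dominated inputs, and an added full-resolution skip
  path makes convergence strongly initialization-dependent, while the
  plain encoder-decoder converges reliably across seeds. It is a
  CPU-scale analog of deep-learning reconstruction methods — enough to
  reproduce their characteristic behavior (large RMSE/SSIM gains, loss of
  small signals) — not a reproduction of any published network. Half of
  its training objects carry a signal at a random tissue-mask location so
  the network is not explicitly signal-blind.

## Trainable observers

Both follow a statsmodels-style Model/Results pattern: construct with the
training data, `fit()`, then use the results object.

**Hotelling observer.** Template
`w = Sigma_shrunk^{-1} (mean_H1 - mean_H0)` on real-stacked features, with
the pooled sample covariance shrunk toward its diagonal
(`Sigma_shrunk = (1-gamma) Sigma + gamma diag(Sigma)`, default
gamma = 0.01). Shrinkage is what makes desk-scale sample sizes workable;
for Gaussian data the Hotelling observer coincides with the IO, which the
tests exploit as an independent cross-check. Image-space evaluations crop a
region of interest around the (known) signal location before fitting: this
only reduces the observer's performance, so it cannot manufacture a bound
violation, and it keeps covariance estimation well-conditioned.

**CNN-approximated IO.** A sigmoid-output convolutional classifier trained
with binary cross-entropy; at the optimum its logit is a monotone transform
of the likelihood ratio, so its ranking performance approaches the IO's
from below. Architecture: a lossless space-to-depth rearrangement brings
any input to ≤16×16 spatial size with a proportionally larger channel
count (a pure CPU-efficiency device — on this problem numpy convolutions
are GEMM-bound and small spatial grids with many channels are an order of
magnitude faster); then `depth` 3×3 conv/ReLU layers (16 channels), two
2× average poolings, and a dense logit. Depth starts at 2 and grows by 1
per stage; a stage trains 14 epochs of Adam (lr 2e-3, halved every 5
epochs, decoupled weight decay 5e-3) and the procedure stops when the
validation-AUC improvement falls below 0.005 for one stage, or after 5
stages. Validation AUC, not loss, is the convergence criterion.

Two estimator details matter at these sample sizes:

* *Standardization*: inputs are standardized using training-set statistics,
  with the mean removed per location and the scale per channel. Removing
  the mean per location is what keeps a bright deterministic background
  component (see intensity scale above) from swamping the input; it is
  information-free since the constant is the same for both classes.
* *Checkpoint ensemble*: each stage returns the average of z-scored logits
  over its five best epochs (by validation AUC) rather than a single
  checkpoint. This is a small variance reduction (+0.002–0.004 AUC
  measured) and keeps the statistic a deterministic function of the data.

On the reference 64×64 SKE/BKE task (4000 training, 2000 validation pairs)
the CNN-IO reaches validation AUC ≈ 0.863 against the analytic 0.879 — a
shortfall of ~0.016 attributable to finite training data, and safely on
the correct side of the bound. The multi-coil k-space input convention is
2C real channels, coil-major, (real, imag) interleaved.

## ROC and AUC estimation

AUC is the Mann-Whitney two-sample rank statistic with ties counted one
half; its standard error is the Hanley-McNeil closed form, with a seeded
bootstrap available as a cross-check. The empirical ROC is built at every
distinct statistic value (calling a case positive when its statistic is
≥ the threshold), so its trapezoidal area equals the rank estimator to
machine precision — the tests assert this equivalence as a duality check.

## The acceleration sweep

`run_acceleration_sweep` evaluates, per acceleration factor: the analytic
data-space bound; Hotelling observers on each requested reconstruction
type (fitted on fresh training realizations, evaluated on held-out ones);
and mean RMSE/SSIM of the reconstructions against the true object. The
task is SKE/BKE with one fixed background realization so the data-space
bound is exact. `compare_bounds` tabulates `bound - image AUC` gaps with
combined standard errors and flags any gap below `-2 SE` as a violation —
none should occur, by the data-processing inequality, and a flagged row
indicates a defect, not a discovery. Default problem sizes (500–800
samples per class per R, 96 reconstruction training pairs, 64 images for
metric means) are desk-scale choices that keep a full sweep in the
low minutes on one CPU; all sizes are config fields.

A reproducible qualitative finding of the sweep: the learned reconstructor
improves RMSE and SSIM over rSOS at *every* acceleration while its
image-space detection AUC does not improve and at R ≥ 4 falls clearly
below the data-space bound (and at times below rSOS). Cleaner-looking
images do not imply preserved task information; that dissociation is the
point of task-based assessment.

## Numerical conventions and degenerate inputs

* DFTs are unitary and DC-centered (`fftshift . fft2(norm='ortho') .
  ifftshift`); Parseval holds to 1e-9 and the adjoint identity to 1e-10 in
  the tests.
* Noise is added only on sampled lines; unsampled lines are exactly zero,
  and `KspaceData` rejects anything else.
* SSIM uses a pinned convention (Gaussian window sigma 1.5 truncated at
  3 sigma, edge-replicate padding, population moments, mean over all
  pixels) so direct-formula oracles agree to 1e-9. The dynamic range
  defaults to the reference image's max-min and must be positive —
  constant references require an explicit value.
* Signals narrower than half a pixel are rejected as unrepresentable;
  empty tissue masks, degenerate training labels, non-normalized priors
  and zero noise in likelihood ratios raise immediately.
* All randomness flows through explicit integer seeds; identical
  configuration and seeds reproduce every number bit-exactly, including
  network training.

## Known limitations

* The Gaussian analytic machinery covers BKE tasks; for BKS backgrounds
  the true IO is unknown and the CNN-IO output is an *estimated* bound
  with a standard error, never a certified one.
* Coil maps and phases are stylized; no field inhomogeneity, relaxation,
  or trajectory effects.
* The learned components are deliberately small; their absolute RMSE/SSIM
  values are not comparable to published full-scale networks, only their
  orderings and their relation to the bound are meaningful.
* 2-D only, single slice, single contrast.
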