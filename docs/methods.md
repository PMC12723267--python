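# Methods

This note records the models implemented in `diffdot`, the choices made
where the design was genuinely open, and what the synthetic benchmark does
and does not demonstrate.

## Forward model

Photon transport in the frequency domain is modelled by the diffusion
approximation, valid when reduced scattering dominates absorption
(μs′ ≫ μa, the regime of near-infrared light in soft tissue):

    (−∇·D∇ + μa − iω/c) Φ(r) = S(r),      D = 1 / (3 (μa + μs′))

with Φ the complex photon density, ω = 2πf the angular modulation
frequency and c the speed of light in the medium. Units are mm, ns and
mm⁻¹ (f supplied in MHz, converted to rad/ns), which keeps system-matrix
entries O(1). The boundary carries a Robin condition Φ + 2AD ∂Φ/∂n = 0;
A is derived from the refractive-index mismatch (Groenhuis polynomial,
default n = 1.33 → A ≈ 2.8) and can be overridden.

Discretization uses linear (P1) triangles. The disk is meshed from
concentric near-hexagonal point rings triangulated with Delaunay; the
outer ring count is a multiple of 16 so boundary nodes sit symmetrically
relative to the probe ring. Element coefficients are the means of the
three nodal values; this choice makes the discrete sensitivity of the
system matrix to a nodal parameter exactly 1/3 of the element matrices,
so adjoint gradients are exact for the discrete system (the
finite-difference cross-check in the tests agrees to ~1e-7 relative).

Each of the 16 sources is an isotropic point source placed one transport
mean free path 1/μs′ beneath its boundary position — the standard
diffusion-approximation replacement for a collimated source. Detectors are the other 15 of the 16 equidistant
boundary positions. Because a point exactly on the circle lies outside
the chordal mesh boundary, detector evaluation points are pulled to 0.99
of the radius; interpolation is barycentric, with ties broken by the
point locator's triangle choice. One sparse LU factorization per phantom
serves all 16 right-hand sides.

Default mesh density is diameter/25 (≈ 500–700 nodes), the element size
used for both data generation and inversion throughout the scaled study;
mesh-refinement convergence of the simulated disk area and boundary data
is exercised in the tests.

## Synthetic phantom data

Phantoms are circular, 60–150 mm in diameter, with background
μa ∈ [0.005, 0.03] mm⁻¹, μs′ ∈ [0.5, 3] mm⁻¹ and modulation frequency
10–100 MHz, all uniform. 1% of samples are homogeneous, 44% carry one
and 55% two circular inclusions with radii 2–30 mm and independent μa/μs′
contrast factors 1.5–8. Inclusions are rejection-sampled until they fit
inside the disk (with a 2% radius margin, so an inclusion never touches
the probe ring) and do not overlap; the full set is redrawn when an
unlucky large first inclusion blocks the second. This conditioning on
feasibility slightly trims the largest radii in the smallest phantoms —
unavoidable for any rejection scheme.

Per sample the pipeline is: 16-source FEM solve; 15% noise —
multiplicative Gaussian on amplitude (relative σ = 0.15, clipped
positive) and additive Gaussian on phase with σ = 0.15 × the per-sample
phase spread (the noise model's channel split is a package choice; only
the 15% level is given); calibration against the noise-free homogeneous
phantom with the same diameter, background and frequency (channels
ln A − ln A_ref and φ − φ_ref); per-sample min–max scaling of each channel
to [0, 1]. Ground truth is rasterized to 64×64×2 by pixel-center
membership; pixels outside the disk carry the background value so that
image metrics are not dominated by a mask, and the disk mask is stored
separately. Targets are normalized for training by per-channel min/max
over the training split; the inverse map (and a positivity floor) is
applied at prediction.

What the generator does *not* emulate: instrument response, source/
detector coupling variability, phantom fabrication tolerances, or
model mismatch between tissue and the diffusion approximation. Passing
the benchmark therefore demonstrates correct inversion of the stated
observation model under calibrated noise, not instrument-grade
performance.

## Tikhonov-regularized Gauss-Newton inversion

The inverse solver minimizes ‖JΔx − ΔΦ‖² + λ²‖Δx‖² iteratively, with the
residual and Jacobian expressed in (log-amplitude, phase) — matching the
calibrated data representation and keeping everything real — and the
unknowns the nodal absorption μa and diffusion coefficient D. The
Jacobian is assembled by the adjoint method: by reciprocity the 16
detector functionals double as adjoint sources, so one LU factorization
yields all 480 × 2n sensitivities.

The update is computed in *log-parameters*: the raw (μa, D)
parameterization with an identity regularizer is badly scaled (the D
block dominates diag(JᵀJ), leaving μa effectively unregularized, and
additive steps slam nodes into the positivity floor); multiplicative
updates put both blocks on one scale, guarantee positivity, and recover
a noise-free homogeneous background to ≈0.2% where the additive form
stalled at ≈15%. λ² is scaled to `lambda_relative` (default 0.01) times
max diag(JᵀJ) of the scaled Jacobian. Steps are accepted under a
halving line search (≤10 halvings; the regularized Gauss-Newton
direction is a descent direction, so acceptance is near-certain);
three consecutive rejected steps flag divergence and return the best
iterate. Stopping: relative residual change < 1e-3 or 20 iterations.

The homogeneous starting point is estimated by a two-parameter
least-squares fit to the data, with the probe layout rebuilt for every
trial μs′ so the effective source depth stays consistent with the
candidate background. Nodal results are barycentrically interpolated to
the 64×64 grid, with the background estimate filling pixels outside the
disk.

## The channel-attention fusion reconstructor

The learned reconstructor maps the 16×15×2 calibrated data directly to
the 64×64×2 property images:

1. **Domain transform** — two fully connected tanh layers
   (480 → width → 4096) reshaped to 64×64×1. The published architecture
   does not fix the internals; the default width is 1024, the desk-scale
   profile uses 256.
2. **Feature extraction block (FEB)** — twice (conv k×k, 8 filters →
   batch norm → ReLU); kernel 3 for the stand-alone FEB.
3. **Fusion block** — FEBs with 1×1, 3×3 and 5×5 kernels in parallel,
   plus a 3×3 stride-1 max-pool branch refined by a 1×1 convolution with
   ReLU; concatenated to 32 channels. The number of fusion blocks is
   configurable (default 2, profile 1).
4. **Channel attention block (CAB)** — per channel, the spatial mean
   (GAP, which suppresses i.i.d. pixel-noise variance by H×W) and
   maximum (GMP) are summed and passed through a shared two-layer MLP
   (C → C/4 → C, ReLU between the layers); a sigmoid yields gates
   w_c ∈ (0, 1) that rescale the channels. With a zero MLP every gate is
   exactly σ(0) = 0.5. The gate bias is initialized at +2 (σ ≈ 0.88) so
   the block starts near pass-through — the usual open-gate convention
   of gated architectures; a 0.5-gated start halves every feature map
   and measurably slows early training.
5. **Head** — a 1×1 convolution to 2 channels, split into the μa and μs′
   maps.

Ablation variants: FEB-only, FEB+fusion (≡ "without CAB"), and
"without FEB" (fusion + CAB directly on the domain transform).

The layers are implemented in numpy with manual backpropagation.
3×3/5×5 convolutions are evaluated through real FFTs (zero-padded to the
next fast length): with only 8 output channels, im2col GEMMs are
memory-bound and measured ~4× slower on one core; the im2col path is
retained as an independent reference and the two are cross-checked to
float32 precision in the tests. Convolutions feeding a batch-norm layer
carry no bias. Batch norm uses batch statistics in training and running
averages (momentum 0.99) at inference.

Training: Adam (lr 0.001, β₁ = 0.5), batch 64, loss = 0.5·MSE(μa) +
0.5·MSE(μs′) on normalized targets (the published "weighted sum" leaves
the weights open; equal weights are the symmetric default). Weight
initialization and shuffling are driven by seeded generators, so runs
are bit-reproducible on one machine.

After training, the weights of the best-validation-loss epoch are
restored (the validation split's standard purpose; disable with
`restore_best=False`). At short budgets with a constant learning rate
the test metrics otherwise degrade measurably past their mid-run peak.

Two initialization choices matter at short training budgets, where a
randomly initialized head otherwise projects feature noise straight
into the output (predictions start as full-scale speckle whose
high-frequency energy takes many epochs to unlearn and ruins SSIM):
the 1×1 head starts at zero (the first predictions are flat images and
structure is learned on top) and the image-forming dense layer of the
domain transform starts at 0.3× its Glorot scale. Both are no-ops for a
fully converged network and markedly improve short-run quality.

## Evaluation

MSE, PSNR (peak 1) and SSIM are computed on images normalized by the
dataset's target statistics. SSIM uses the standard 11×11 Gaussian
window (σ 1.5) with stabilizers C1 = (0.01)², C2 = (0.03)²; the
literal printed constants (0.0012, 0.0022) are accepted via arguments —
they are read as squared constants with lost superscripts, since the
standard values reproduce conventional SSIM behaviour. Images smaller
than the window fall back to single-window global statistics.

Resolution indices compare reconstructions inside the known inclusion
disks: contrast resolution is the inclusion-max/background-min dynamic
range ratio of reconstruction vs truth, folded (2 − r) when the raw
ratio exceeds 1; raw size resolution is 1 − RMSE(recon, truth)/
RMSE(truth, homogeneous baseline) over zone pixels, clipped to [0, 1].
Composite indices use the geometric mean — the composition that
reproduces the published tables from their own printed components; the
plain product form is available behind a flag. The fold condition is
applied to the raw (unfolded) ratio.

Attention diagnostics histogram feature activations before/after the CAB
into 256 shared bins spanning both stacks and report Shannon entropy in
bits; shared bins make the gate's contraction of activations register as
an entropy reduction. Cross-validation partitions the train+val pool
into k seeded folds and reports per-fold reconstruction MSE with mean
and standard deviation.

## Desk-scale profile and problem sizes

The `paper-scaled` profile runs the whole study on one CPU: 1,000
samples (850/100/50), mesh diameter/25, 30 training epochs (with an
epoch-20 snapshot for the ablation comparison, evaluated under the same
best-validation selection as a finished 20-epoch fit), domain-transform
width 256 with one fusion block, a 20-phantom Tikhonov baseline, and
seeds {11, 13, 17} for data, weights and shuffling. These sizes are the
package's reproduction setting; the published experiments used 10,000
samples, 100 epochs, and a GPU.

Scaled-down metrics approach, not match, the published table values:
at ~420 Adam steps (vs ~13,000 at full scale) the learned reconstructor
reaches μa SSIM ≈ 0.6–0.7 and PSNR ≈ 22–23 dB on the held-out split —
clearly above the Tikhonov baseline (PSNR ≈ 21 dB, itself inside the
published band) but short of the full-scale 0.90 / 35 dB. Likewise the
three-way ablation at 20 epochs ranks FEB-only last but cannot yet
separate the full network from FEB+fusion (the published gap, 0.75 vs
0.48, emerges at ~10× more optimization); the corresponding check in
the test suite records this honestly. Localization analysis estimates
the μa peak from a σ = 1 px Gaussian-smoothed map restricted to the
phantom disk; at this scale ~70% of held-out single-inclusion phantoms
with contrast ≥ 3 are localized within one inclusion radius.

## Known limitations

- 2-D circular geometries only; no transport-equation solver, no 3-D.
- The inverse crime is only partly avoided: inversion uses the same
  element size as generation (though a different mesh object and noisy
  data).
- The published parameter count (8.2M, 152 layers) is not reproducible
  from the text; `count_parameters` is a diagnostic, not a constraint.
- One printed resolution row (second simulation case, μs′ size index)
  is not consistent with any composition of its own printed components;
  the worked examples asserted in tests are the self-consistent ones.
- Histogram entropy depends on binning; only the before/after reduction
  is meaningful, not the absolute bit values.
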