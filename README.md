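# diffdot

Frequency-domain diffuse optical tomography (DOT) at desk scale: a
finite-element forward simulator for circular tissue phantoms, a
Tikhonov-regularized Gauss-Newton inverse solver, and a channel-attention
fusion network (CAFNet) that reconstructs optical-property images
directly from boundary measurements — plus the evaluation suite
(MSE/PSNR/SSIM and contrast/size/CSD resolution indices) to compare them.

**Who it is for.** Researchers in near-infrared diffuse optical imaging
who want a self-contained, CPU-only reference implementation of the
classical and learned reconstruction pipelines on simulated data: no
external datasets, no GPU, no deep-learning framework.

## The problem and the models

Near-infrared light in tissue is strongly scattering, so photon density
Φ obeys the frequency-domain diffusion equation

    (−∇·D∇ + μa − iω/c) Φ = S,      D = 1 / (3 (μa + μs′)),

where μa (mm⁻¹) is absorption, μs′ (mm⁻¹) reduced scattering, and ω the
angular modulation frequency. A P1 finite-element discretization gives
`A Φ = b`; 16 sources and 15 detectors per source on the phantom
boundary yield 240 amplitude and 240 phase values per sample.

Reconstruction recovers the interior (μa, μs′) maps from those 480
numbers — a severely ill-posed inverse problem. Two routes are
implemented:

- **Tikhonov / Gauss-Newton**: iteratively minimize
  `‖J Δx − ΔΦ‖² + λ²‖Δx‖²` with an adjoint-method Jacobian
  `J = [∂Φ/∂μa, ∂Φ/∂D]` in (log-amplitude, phase) form.
- **CAFNet**: a learned map from the 16×15×2 calibrated data to the
  64×64×2 property images — a fully connected domain transform, a
  feature-extraction block (conv→BN→ReLU ×2), multi-kernel (1/3/5)
  fusion blocks with a max-pool branch, a channel-attention gate
  `w_c = σ(MLP(GAP_c + GMP_c))`, and a 1×1 head split into the two
  property maps. Implemented in pure numpy with manual backprop
  (FFT-based convolutions), trained with Adam (lr 0.001, β₁ = 0.5).

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

```python
import numpy as np
from diffdot import (Phantom, Inclusion, simulate, add_noise,
                     TikhonovReconstruction)

phantom = Phantom(diameter=60, background_mu_a=0.006,
                  background_mu_s_prime=1.0, frequency_mhz=50,
                  inclusions=(Inclusion((10.0, 5.0), 10.0, 4.0, 2.0),))
data = add_noise(simulate(phantom), level=0.15, rng=1)
result = TikhonovReconstruction(data, diameter=60).fit()
print(result.summary())
img = result.property_image
iy, ix = np.unravel_index(np.argmax(img.mu_a), img.mu_a.shape)
print("mu_a peak at", (-30 + img.pixel_pitch * (ix + 0.5),
                       -30 + img.pixel_pitch * (iy + 0.5)))
```

prints (numbers vary with the noise seed):

```
Tikhonov-regularized Gauss-Newton reconstruction
================================================
iterations run        : 15
converged             : True
flagged divergent     : False
initial data misfit   : 10.311
final data misfit     : 1.71572
background estimate   : mu_a=0.0091678 mm^-1, mu_s'=0.90065 mm^-1
mu_a peak at (13.59375, 5.15625)
```

The data misfit drops from 10.3 to 1.7 — the 15% noise floor of the 480
measurements. The homogeneous background estimate is biased upward in
μa (0.0092 vs the true 0.006) because the absorbing inclusion raises
the phantom's apparent average absorption; the nodal reconstruction
then concentrates that absorption, and the μa peak lands 3.6 mm from
the true inclusion center (10, 5) — well inside the 10 mm inclusion.

Training the learned reconstructor end to end:

```bash
diffdot generate --n 1000 --seed 11 --out dataset.h5
diffdot train --dataset dataset.h5 --epochs 30 --seed 13 --out model
diffdot predict --model model --dataset dataset.h5 --index 0
diffdot run --profile paper-scaled --seed 0 --out runs/scaled
```

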