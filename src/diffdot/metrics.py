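"""Image-quality metrics for reconstructed optical-property maps.

All three metrics operate on images normalized to [0, 1] by the dataset's
target statistics: MSE is the plain mean squared pixel difference, PSNR is
``10 log10(1 / MSE)`` (peak fixed at 1), and SSIM uses the standard
11x11 Gaussian window with sigma 1.5.  For images smaller than the window
the SSIM falls back to single-window global statistics.
"""

from __future__ import annotations

import numpy as np
from skimage.metrics import structural_similarity

#: standard SSIM stabilizers (0.01^2 and 0.03^2 for unit dynamic range)
C1_DEFAULT = 0.01**2
C2_DEFAULT = 0.03**2


def _check_pair(image, reference):
    image = np.asarray(image, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if image.shape != reference.shape:
        raise ValueError(
            f"shape mismatch: {image.shape} vs {reference.shape}"
        )
    return image, reference


def mse(image, reference) -> float:
    """Mean squared error over all pixels."""
    image, reference = _check_pair(image, reference)
    return float(np.mean((image - reference) ** 2))


def psnr(image, reference, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; infinite for identical images."""
    err = mse(image, reference)
    if err == 0.0:
        return float("inf")
    return float(10.0 * np.log10(peak**2 / err))


def ssim_global(image, reference, c1=C1_DEFAULT, c2=C2_DEFAULT) -> float:
    """Single-window SSIM from global means/variances/covariance."""
    image, reference = _check_pair(image, reference)
    mu1, mu2 = image.mean(), reference.mean()
    v1, v2 = image.var(), reference.var()
    cov = ((image - mu1) * (reference - mu2)).mean()
    return float(
        ((2 * mu1 * mu2 + c1) * (2 * cov + c2))
        / ((mu1**2 + mu2**2 + c1) * (v1 + v2 + c2))
    )


def ssim(
    image,
    reference,
    c1: float = C1_DEFAULT,
    c2: float = C2_DEFAULT,
    win_size: int = 11,
    sigma: float = 1.5,
) -> float:
    """Mean local SSIM with a Gaussian weighting window.

    ``c1``/``c2`` are the additive stabilizing constants for unit dynamic
    range (configurable; defaults are the standard (0.01)^2, (0.03)^2).
    """
    image, reference = _check_pair(image, reference)
    if min(image.shape[:2]) < win_size:
        return ssim_global(image, reference, c1, c2)
    return float(
        structural_similarity(
            reference,
            image,
            win_size=win_size,
            gaussian_weights=True,
            sigma=sigma,
            use_sample_covariance=False,
            K1=np.sqrt(c1),
            K2=np.sqrt(c2),
            data_range=1.0,
        )
    )


def metric_report(image, reference) -> dict:
    """MSE/PSNR/SSIM for one normalized image pair (any shape)."""
    return {
        "mse": mse(image, reference),
        "psnr_db": psnr(image, reference),
        "ssim": ssim(image, reference),
        "n_pixels": int(np.asarray(image).size),
    }
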