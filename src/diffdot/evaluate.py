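"""Aggregate evaluation: per-sample metrics, method comparison tables and
k-fold cross-validation of the learned reconstructor.

Metrics are always computed on images normalized to [0, 1] with the
dataset's per-channel target statistics, so PSNR's peak is 1 and results
are comparable across methods and phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from .cafnet import CAFNet, NetworkConfig, TrainConfig
from .datasets import DatasetSplit
from .metrics import mse, psnr, ssim

CHANNEL_NAMES = ("mu_a", "mu_s_prime")


def normalize_with(stats: dict, images: np.ndarray) -> np.ndarray:
    lo = np.asarray(stats["target_min"])
    hi = np.asarray(stats["target_max"])
    return (np.asarray(images, dtype=float) - lo) / (hi - lo)


def evaluate_images(
    predictions: np.ndarray,
    truths: np.ndarray,
    stats: dict,
) -> Dict[str, np.ndarray]:
    """Per-sample MSE/PSNR/SSIM per property channel.

    ``predictions`` and ``truths`` are (N, 64, 64, 2) arrays in physical
    units; both are normalized with the dataset statistics first.
    """
    pred = normalize_with(stats, predictions)
    true = normalize_with(stats, truths)
    n = len(pred)
    out = {}
    for ch, name in enumerate(CHANNEL_NAMES):
        out[f"mse_{name}"] = np.array(
            [mse(pred[i, ..., ch], true[i, ..., ch]) for i in range(n)]
        )
        out[f"psnr_{name}"] = np.array(
            [psnr(pred[i, ..., ch], true[i, ..., ch]) for i in range(n)]
        )
        out[f"ssim_{name}"] = np.array(
            [ssim(pred[i, ..., ch], true[i, ..., ch]) for i in range(n)]
        )
    return out


def summarize(metrics: Dict[str, np.ndarray]) -> Dict[str, dict]:
    """Mean and standard deviation of each per-sample metric."""
    return {
        key: {"mean": float(np.mean(v)), "std": float(np.std(v))}
        for key, v in metrics.items()
    }


def compare_methods(per_method: Dict[str, Dict[str, np.ndarray]]) -> list:
    """Comparison table rows (one per method).

    MSE is reported in units of 1e-3 as in the published tables.  Methods
    whose metrics are missing are listed as absent rather than failing.
    """
    rows = []
    for method, metrics in per_method.items():
        if metrics is None:
            rows.append({"method": method, "absent": True})
            continue
        row = {"method": method, "absent": False}
        for ch in CHANNEL_NAMES:
            m = metrics[f"mse_{ch}"]
            row[f"mse_1e3_{ch}"] = f"{np.mean(m) * 1e3:.2f} ± {np.std(m) * 1e3:.2f}"
            p = metrics[f"psnr_{ch}"]
            row[f"psnr_db_{ch}"] = f"{np.mean(p):.1f} ± {np.std(p):.1f}"
            s = metrics[f"ssim_{ch}"]
            row[f"ssim_{ch}"] = f"{np.mean(s):.2f} ± {np.std(s):.2f}"
        rows.append(row)
    return rows


@dataclass
class CrossValidationResult:
    fold_mse: list
    mean_mse: float
    std_mse: float

    def summary(self) -> str:
        folds = ", ".join(f"{m:.4g}" for m in self.fold_mse)
        return (
            f"{len(self.fold_mse)}-fold CV  MSE per fold: [{folds}]  "
            f"mean {self.mean_mse:.4g} ± {self.std_mse:.4g}"
        )


def cross_validate(
    dataset: DatasetSplit,
    k: int = 5,
    network_config: Optional[NetworkConfig] = None,
    train_config: Optional[TrainConfig] = None,
    seed: int = 0,
) -> CrossValidationResult:
    """k-fold cross-validation of CAFNet on the train+val pool.

    Folds partition the pool exactly (a fixed seeded permutation); each
    fold serves once as the held-out set while the remainder trains a
    fresh model.  Reports the per-fold MSE of normalized reconstructions.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    tc = train_config or TrainConfig(epochs=5)
    x = np.concatenate(
        [dataset["train"]["inputs"], dataset["val"]["inputs"]]
    ).astype(np.float32)
    y = dataset.normalize_targets(
        np.concatenate([dataset["train"]["targets"], dataset["val"]["targets"]])
    ).astype(np.float32)
    n = len(x)
    if n // k < 1:
        raise ValueError("dataset too small for the requested folds")
    if n // k < tc.batch_size and n - n // k < tc.batch_size:
        raise ValueError("fold smaller than one batch")
    order = np.random.default_rng(seed).permutation(n)
    folds = np.array_split(order, k)
    fold_mse = []
    for i, hold in enumerate(folds):
        train_idx = np.concatenate([f for j, f in enumerate(folds) if j != i])
        model = CAFNet(network_config or NetworkConfig(), seed=seed + i)
        model.fit_arrays(
            x[train_idx], y[train_idx], train_config=tc
        )
        pred = model.forward(x[hold], training=False)
        fold_mse.append(float(np.mean((pred - y[hold]) ** 2)))
    return CrossValidationResult(
        fold_mse=fold_mse,
        mean_mse=float(np.mean(fold_mse)),
        std_mse=float(np.std(fold_mse)),
    )
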