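"""End-to-end orchestration: generate -> train -> predict -> evaluate.

The ``paper-scaled`` profile is the package's desk-scale stand-in for the
published 10,000-sample / 100-epoch GPU runs: 1,000 samples, 30 training
epochs, element size diameter/25, a narrowed domain-transform width (256)
with one fusion block, and fixed seeds {11, 13, 17} for data, weights and
shuffling.  All stages are deterministic given the configuration.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .cafnet import CAFNet, NetworkConfig, TrainConfig
from .datasets import DatasetSplit, generate_dataset, load_dataset
from .evaluate import evaluate_images, summarize
from .tikhonov import TikhonovReconstruction, TRConfig


@dataclass
class RunConfig:
    """Serializable configuration of one full pipeline run."""

    n_samples: int = 1000
    noise_level: float = 0.15
    mesh_rel_size: float = 1.0 / 25.0
    dataset_seed: int = 11
    model_seed: int = 13
    train_seed: int = 17
    epochs: int = 30
    variant: str = "full"
    automap_hidden_width: int = 256
    n_fusion_blocks: int = 1
    lambda_relative: float = 0.01
    tr_max_iterations: int = 20
    n_tr_samples: int = 20
    out_dir: str = "runs/latest"

    def network_config(self) -> NetworkConfig:
        return NetworkConfig(
            automap_hidden_width=self.automap_hidden_width,
            n_fusion_blocks=self.n_fusion_blocks,
            variant=self.variant,
        )

    def train_config(self, epochs: Optional[int] = None) -> TrainConfig:
        return TrainConfig(
            epochs=epochs or self.epochs, seed=self.train_seed
        )

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = (
            json.loads(text)
            if str(path).endswith(".json")
            else yaml.safe_load(text)
        )
        return cls(**data)


def paper_scaled_profile(seed: int = 0, **overrides) -> RunConfig:
    """The desk-scale reproduction profile; ``seed`` offsets every stream.

    With seed 0 the canonical profile seeds {11, 13, 17} are used
    unchanged; other seeds shift them deterministically.
    """
    base = RunConfig(
        dataset_seed=(11 + 1_000_003 * seed) % 2**31,
        model_seed=(13 + 1_000_033 * seed) % 2**31,
        train_seed=(17 + 1_000_037 * seed) % 2**31,
    )
    for key, value in overrides.items():
        setattr(base, key, value)
    return base


def reconstruct_tr_batch(
    dataset: DatasetSplit,
    split: str = "test",
    indices=None,
    config: Optional[TRConfig] = None,
    mesh_rel_size: float = 1.0 / 25.0,
) -> np.ndarray:
    """Tikhonov-reconstruct dataset samples; returns (N, 64, 64, 2)."""
    if indices is None:
        indices = range(dataset.n(split))
    out = []
    for idx in indices:
        phantom = dataset.phantom(split, idx)
        meas = dataset.measurement(split, idx)
        result = TikhonovReconstruction(
            meas,
            phantom.diameter,
            config=config,
            mesh_rel_size=mesh_rel_size,
        ).fit()
        out.append(result.property_image.values)
    return np.stack(out)


def localization_rate(
    model: CAFNet,
    dataset: DatasetSplit,
    split: str = "test",
    min_contrast: float = 3.0,
) -> dict:
    """Fraction of held-out single-inclusion phantoms (absorption contrast
    >= ``min_contrast``) whose predicted mu_a peak falls within one
    inclusion radius of the true center."""
    stats = dataset.normalization_statistics
    hits = 0
    total = 0
    for idx in range(dataset.n(split)):
        phantom = dataset.phantom(split, idx)
        if len(phantom.inclusions) != 1:
            continue
        inc = phantom.inclusions[0]
        if inc.contrast_a < min_contrast:
            continue
        pred = model.predict(dataset[split]["inputs"][idx], stats)
        # robust peak estimate: mild smoothing before the argmax, and the
        # search restricted to the disk (inclusions cannot sit outside it)
        mu_a = gaussian_filter(pred[..., 0], 1.0)
        mu_a = np.where(dataset[split]["masks"][idx], mu_a, -np.inf)
        iy, ix = np.unravel_index(np.argmax(mu_a), mu_a.shape)
        pitch = phantom.diameter / pred.shape[0]
        x = -phantom.diameter / 2 + pitch * (ix + 0.5)
        y = -phantom.diameter / 2 + pitch * (iy + 0.5)
        total += 1
        hits += np.hypot(x - inc.center[0], y - inc.center[1]) <= inc.radius
    return {"rate": hits / total if total else float("nan"), "n": total}


def scaled_study(
    seed: int = 0,
    include_ablation: bool = False,
    log=None,
) -> dict:
    """The desk-scale headline study: dataset, CAFNet, Tikhonov baseline.

    Generates the profile dataset, trains the full network for the profile's
    30 epochs (recording test metrics from the epoch-20 snapshot, the
    budget used by the ablation comparison), reconstructs the first
    ``n_tr_samples`` test phantoms with the Gauss-Newton solver, and — when
    ``include_ablation`` is set — trains the FEB-only and FEB+Fusion
    variants for 20 epochs under identical settings.

    Returns a dict of metric summaries per method/variant.
    """
    def say(msg):
        if log:
            log(msg)

    cfg = paper_scaled_profile(seed)
    t0 = time.time()
    dataset = generate_dataset(
        n=cfg.n_samples,
        seed=cfg.dataset_seed,
        noise_level=cfg.noise_level,
        mesh_rel_size=cfg.mesh_rel_size,
    )
    say(f"dataset generated ({time.time() - t0:.0f}s)")
    stats = dataset.normalization_statistics
    test_inputs = dataset["test"]["inputs"]
    test_targets = dataset["test"]["targets"]

    def test_metrics(model):
        pred = model.predict(test_inputs, stats)
        return summarize(evaluate_images(pred, test_targets, stats))

    snapshots = {}

    def snapshot(epoch, model):
        # the 20-epoch state under the same best-validation selection a
        # finished 20-epoch fit would apply (identical ablation protocol)
        if epoch == 20:
            snapshots["epoch20"] = model.evaluate_best_so_far(test_metrics)
            say("epoch-20 snapshot evaluated")

    model = CAFNet(cfg.network_config(), seed=cfg.model_seed)
    t1 = time.time()
    model.fit(dataset, cfg.train_config(), epoch_callback=snapshot)
    say(f"full model trained ({time.time() - t1:.0f}s)")
    results = {
        "cafnet": test_metrics(model),
        "cafnet_epoch20": snapshots["epoch20"],
        "n_test": dataset.n("test"),
    }
    results["localization"] = localization_rate(
        model, dataset, min_contrast=3.0
    )
    t2 = time.time()
    tr_indices = range(min(cfg.n_tr_samples, dataset.n("test")))
    tr_pred = reconstruct_tr_batch(
        dataset, "test", tr_indices, mesh_rel_size=cfg.mesh_rel_size
    )
    results["tikhonov"] = summarize(
        evaluate_images(
            tr_pred, test_targets[: len(tr_pred)], stats
        )
    )
    results["n_tr"] = len(tr_pred)
    say(f"Tikhonov baseline reconstructed ({time.time() - t2:.0f}s)")
    if include_ablation:
        for variant in ("feb_fusion", "feb_only"):
            t3 = time.time()
            net_cfg = cfg.network_config()
            net_cfg.variant = variant
            m = CAFNet(net_cfg, seed=cfg.model_seed)
            m.fit(dataset, cfg.train_config(epochs=20))
            results[variant] = test_metrics(m)
            say(f"{variant} trained ({time.time() - t3:.0f}s)")
    return results


def run_pipeline(config: RunConfig, dataset: Optional[DatasetSplit] = None) -> dict:
    """Execute the full pipeline and write its four artifacts.

    Writes the dataset container, the model checkpoint, a JSON metric
    report and a manifest (config, hash, seeds, timing) under
    ``config.out_dir``.  Returns the report as a dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = {}
    t0 = time.time()
    try:
        if dataset is None:
            dataset = generate_dataset(
                n=config.n_samples,
                seed=config.dataset_seed,
                noise_level=config.noise_level,
                mesh_rel_size=config.mesh_rel_size,
                out=str(out / "dataset.h5"),
            )
        stages["generate"] = time.time() - t0
    except Exception as exc:
        raise RuntimeError(f"stage 'generate' failed: {exc}") from exc
    try:
        t1 = time.time()
        model = CAFNet(config.network_config(), seed=config.model_seed)
        model.fit(dataset, config.train_config())
        model.save(str(out / "model"))
        stages["train"] = time.time() - t1
    except Exception as exc:
        raise RuntimeError(f"stage 'train' failed: {exc}") from exc
    try:
        t2 = time.time()
        pred = model.predict(
            dataset["test"]["inputs"], dataset.normalization_statistics
        )
        stages["predict"] = time.time() - t2
    except Exception as exc:
        raise RuntimeError(f"stage 'predict' failed: {exc}") from exc
    try:
        t3 = time.time()
        metrics = evaluate_images(
            pred,
            dataset["test"]["targets"],
            dataset.normalization_statistics,
        )
        report = {
            "summary": summarize(metrics),
            "n_test": dataset.n("test"),
            "variant": config.variant,
        }
        (out / "metrics.json").write_text(json.dumps(report, indent=1))
        stages["evaluate"] = time.time() - t3
    except Exception as exc:
        raise RuntimeError(f"stage 'evaluate' failed: {exc}") from exc
    manifest = {
        "config": asdict(config),
        "config_hash": config.hash(),
        "stage_seconds": {k: round(v, 2) for k, v in stages.items()},
        "n_parameters": model.count_parameters(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return report
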