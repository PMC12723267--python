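"""Channel-attention fusion network for direct DOT image reconstruction.

The network maps 16x15x2 calibrated boundary data straight to 64x64x2
optical-property images: a learned fully connected domain transform
(sensor domain -> image domain), a feature-extraction block (FEB), one or
more multi-kernel fusion blocks, a channel attention block (CAB) and a
1x1-convolution head whose two channels are split into the mu_a and mu_s'
maps.  Ablation variants drop individual blocks.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Callable, Optional

import numpy as np

from . import nn
from .datasets import DatasetSplit
from .phantoms import GRID, NormalizedInput, PropertyImage

VARIANTS = ("full", "feb_only", "feb_fusion", "no_cab", "no_feb")


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    The published architecture leaves the domain-transform width and the
    number of fusion blocks open; both are configurable (the desk-scale
    profile narrows them for CPU training).
    """

    automap_hidden_width: int = 1024
    feb_filters: int = 8
    feb_kernel: int = 3
    fusion_kernel_set: tuple = (1, 3, 5)
    fusion_refine_filters: int = 8
    n_fusion_blocks: int = 2
    cab_reduction_ratio: int = 4
    variant: str = "full"
    use_batchnorm: bool = True

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.feb_filters < 1 or self.fusion_refine_filters < 1:
            raise ValueError("filter counts must be >= 1")

    @property
    def fusion_out_channels(self) -> int:
        return (
            len(self.fusion_kernel_set) * self.feb_filters
            + self.fusion_refine_filters
        )


@dataclass
class TrainConfig:
    """Optimization settings: Adam(lr 0.001, beta1 0.5), batch 64, weighted
    sum of per-channel MSE on min-max-normalized targets."""

    learning_rate: float = 1e-3
    beta1: float = 0.5
    batch_size: int = 64
    epochs: int = 100
    loss_weights: tuple = (0.5, 0.5)
    seed: int = 0
    #: restore the best-validation-epoch weights after training (the val
    #: split's purpose); ignored when no validation data is supplied
    restore_best: bool = True

    def __post_init__(self):
        w = self.loss_weights
        if min(w) < 0 or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("loss weights must be >= 0 and sum to 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def _feb(rng, c_in, cfg, kernel=None) -> nn.Sequential:
    k = kernel if kernel is not None else cfg.feb_kernel
    f = cfg.feb_filters
    bias = not cfg.use_batchnorm  # redundant under batch normalization
    return nn.Sequential(
        [
            nn.Conv2D(rng, k, c_in, f, bias=bias),
            nn.BatchNorm2D(f, enabled=cfg.use_batchnorm),
            nn.ReLU(),
            nn.Conv2D(rng, k, f, f, bias=bias),
            nn.BatchNorm2D(f, enabled=cfg.use_batchnorm),
            nn.ReLU(),
        ]
    )


def _fusion(rng, c_in, cfg) -> nn.Parallel:
    branches = [_feb(rng, c_in, cfg, kernel=k) for k in cfg.fusion_kernel_set]
    branches.append(
        nn.Sequential(
            [
                nn.MaxPool3x3(),
                nn.Conv2D(rng, 1, c_in, cfg.fusion_refine_filters),
                nn.ReLU(),
            ]
        )
    )
    return nn.Parallel(branches)


def _automap(rng, cfg) -> nn.Sequential:
    image_dense = nn.Dense(rng, cfg.automap_hidden_width, GRID * GRID)
    # damp the image-forming layer at init: the first image-domain maps
    # start low-amplitude and smooth instead of full-scale random texture
    image_dense.w.value *= 0.3
    return nn.Sequential(
        [
            nn.Reshape((480,)),
            nn.Dense(rng, 480, cfg.automap_hidden_width),
            nn.Tanh(),
            image_dense,
            nn.Tanh(),
            nn.Reshape((GRID, GRID, 1)),
        ]
    )


def build_model(config: NetworkConfig, seed: int = 0) -> "CAFNet":
    """Construct a network variant with seeded Glorot initialization."""
    return CAFNet(config, seed=seed)


class CAFNet:
    """The reconstruction model: build with a config, then ``fit`` on a
    :class:`~diffdot.datasets.DatasetSplit` and ``predict`` per sample."""

    def __init__(self, config: NetworkConfig = None, seed: int = 0):
        self.config = config or NetworkConfig()
        self.seed = seed
        rng = np.random.default_rng(seed)
        cfg = self.config
        stages = []
        self.cab = None
        if cfg.variant != "no_automap":
            stages.append(("automap", _automap(rng, cfg)))
        if cfg.variant in ("full", "feb_only", "feb_fusion", "no_cab"):
            stages.append(("feb", _feb(rng, 1, cfg)))
            c = cfg.feb_filters
        else:  # no_feb
            c = 1
        if cfg.variant != "feb_only":
            for i in range(cfg.n_fusion_blocks):
                stages.append((f"fusion{i}", _fusion(rng, c, cfg)))
                c = cfg.fusion_out_channels
        if cfg.variant in ("full", "no_feb"):
            self.cab = nn.ChannelAttention(rng, c, cfg.cab_reduction_ratio)
            stages.append(("cab", self.cab))
        head = nn.Conv2D(rng, 1, c, 2)
        # zero-initialized head: the network starts from a flat image and
        # learns structure, instead of projecting feature noise into the
        # output from step one
        head.w.value[...] = 0.0
        stages.append(("head", head))
        self.stages = stages
        self.net = nn.Sequential([s for _, s in stages])

    # -- architecture building blocks (usable standalone) -----------------

    def automap_transform(self, x: np.ndarray) -> np.ndarray:
        """Sensor-domain (N,16,15,2) -> image-domain (N,64,64,1) map."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != (16, 15, 2):
            raise ValueError("automap input must be 16x15x2")
        stage = dict(self.stages).get("automap")
        if stage is None:
            raise RuntimeError("this variant has no domain transform")
        return stage.forward(x, training=False)

    # -- training ---------------------------------------------------------

    def params(self):
        return self.net.params()

    def count_parameters(self) -> int:
        return nn.count_parameters(self.net)

    def forward(self, x, training=False):
        return self.net.forward(np.asarray(x, dtype=np.float32), training)

    def forward_with_cab_maps(self, x):
        """Forward pass returning (output, features before CAB, after CAB)."""
        x = np.asarray(x, dtype=np.float32)
        before = after = None
        for name, stage in self.stages:
            if name == "cab":
                before = x
                x = stage.forward(x, training=False)
                after = x
            else:
                x = stage.forward(x, training=False)
        return x, before, after

    def _loss_and_grad(self, pred, target, weights):
        diff = pred - target
        n = diff[..., 0].size
        w = np.asarray(weights, dtype=np.float32)
        per_channel = (diff**2).mean(axis=(0, 1, 2))
        loss = float(w @ per_channel)
        grad = (2.0 / n) * diff * w[None, None, None, :]
        return loss, grad.astype(np.float32)

    def evaluate_loss(self, inputs, targets_norm, weights=(0.5, 0.5)):
        pred = self.forward(inputs, training=False)
        loss, _ = self._loss_and_grad(pred, targets_norm.astype(np.float32), weights)
        return loss

    def fit(
        self,
        dataset: DatasetSplit,
        train_config: TrainConfig = None,
        epoch_callback: Optional[Callable] = None,
    ) -> "CAFNetResults":
        """Train on the dataset's train split, monitoring the val split.

        ``epoch_callback(epoch, model)`` runs after each epoch (used for
        snapshot evaluations).  Returns a results object; the model itself
        is trained in place.
        """
        tc = train_config or TrainConfig()
        for split in ("train", "val"):
            if dataset.n(split) == 0:
                raise ValueError(f"empty {split} split")
        x_train = dataset["train"]["inputs"].astype(np.float32)
        y_train = dataset.normalize_targets(
            dataset["train"]["targets"]
        ).astype(np.float32)
        x_val = dataset["val"]["inputs"].astype(np.float32)
        y_val = dataset.normalize_targets(dataset["val"]["targets"]).astype(
            np.float32
        )
        return self.fit_arrays(
            x_train, y_train, x_val, y_val, tc, epoch_callback
        )

    def fit_arrays(
        self,
        x_train,
        y_train,
        x_val=None,
        y_val=None,
        train_config: TrainConfig = None,
        epoch_callback: Optional[Callable] = None,
    ) -> "CAFNetResults":
        tc = train_config or TrainConfig()
        rng = np.random.default_rng(tc.seed)
        opt = nn.Adam(self.params(), lr=tc.learning_rate, beta1=tc.beta1)
        n = len(x_train)
        history = {"train_loss": [], "val_loss": []}
        best = (np.inf, None, 0)
        self._running_best = None
        track_best = (
            tc.restore_best and x_val is not None and len(x_val) > 0
        )
        for epoch in range(tc.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, tc.batch_size):
                idx = order[start : start + tc.batch_size]
                xb, yb = x_train[idx], y_train[idx]
                opt.zero_grad()
                pred = self.net.forward(xb, training=True)
                loss, grad = self._loss_and_grad(pred, yb, tc.loss_weights)
                self.net.backward(grad)
                opt.step()
                losses.append(loss)
            history["train_loss"].append(float(np.mean(losses)))
            if x_val is not None and len(x_val):
                val_loss = self.evaluate_loss(x_val, y_val, tc.loss_weights)
                history["val_loss"].append(val_loss)
                if track_best and val_loss < best[0]:
                    best = (val_loss, self._state_copy(), epoch + 1)
                    self._running_best = best
            if epoch_callback is not None:
                epoch_callback(epoch + 1, self)
        if track_best and best[1] is not None:
            self._state_restore(best[1])
        return CAFNetResults(
            model=self,
            history=history,
            train_config=tc,
            best_epoch=best[2] if track_best else len(history["train_loss"]),
        )

    def evaluate_best_so_far(self, fn):
        """Run ``fn(self)`` with the best-validation weights seen so far
        temporarily restored (used for mid-training snapshot evaluation
        under the same model-selection protocol as a finished fit)."""
        best = getattr(self, "_running_best", None)
        if best is None or best[1] is None:
            return fn(self)
        current = self._state_copy()
        self._state_restore(best[1])
        try:
            return fn(self)
        finally:
            self._state_restore(current)

    def _bn_layers(self):
        return [
            layer
            for _, stage in self.stages
            for layer in _iter_layers(stage)
            if isinstance(layer, nn.BatchNorm2D) and layer.enabled
        ]

    def _state_copy(self):
        params = [p.value.copy() for p in self.params()]
        bn = [
            (layer.running_mean.copy(), layer.running_var.copy())
            for layer in self._bn_layers()
        ]
        return params, bn

    def _state_restore(self, state):
        params, bn = state
        for p, saved in zip(self.params(), params):
            p.value[...] = saved
        for layer, (mean, var) in zip(self._bn_layers(), bn):
            layer.running_mean[...] = mean
            layer.running_var[...] = var

    # -- inference --------------------------------------------------------

    def predict(self, inputs, statistics) -> np.ndarray:
        """Reconstruct physical-unit (N,64,64,2) images.

        ``statistics`` is the dataset normalization dict (or a
        DatasetSplit); the per-channel inverse min-max map is applied to
        the network output.
        """
        if isinstance(inputs, NormalizedInput):
            inputs = inputs.array
        x = np.asarray(inputs, dtype=np.float32)
        squeeze = x.ndim == 3
        if squeeze:
            x = x[None]
        if isinstance(statistics, DatasetSplit):
            statistics = statistics.normalization_statistics
        if statistics is None or "target_min" not in statistics:
            raise ValueError("normalization statistics are required")
        out = self.forward(x, training=False).astype(np.float64)
        lo = np.asarray(statistics["target_min"])
        hi = np.asarray(statistics["target_max"])
        out = out * (hi - lo) + lo
        # optical properties are strictly positive
        out = np.maximum(out, 1e-5)
        return out[0] if squeeze else out

    def predict_image(self, inputs, statistics, diameter: float) -> PropertyImage:
        values = self.predict(inputs, statistics)
        pitch = diameter / GRID
        c = -diameter / 2 + pitch * (np.arange(GRID) + 0.5)
        xx, yy = np.meshgrid(c, c, indexing="xy")
        return PropertyImage(
            values=values,
            pixel_pitch=pitch,
            domain_mask=np.hypot(xx, yy) <= diameter / 2,
        )

    # -- persistence ------------------------------------------------------

    def save(self, path_prefix: str) -> None:
        """Write weights (npz) and a JSON architecture manifest."""
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params())}
        bn_layers = [
            layer
            for _, stage in self.stages
            for layer in _iter_layers(stage)
            if isinstance(layer, nn.BatchNorm2D) and layer.enabled
        ]
        for i, layer in enumerate(bn_layers):
            arrays[f"bn_{i:04d}_mean"] = layer.running_mean
            arrays[f"bn_{i:04d}_var"] = layer.running_var
        np.savez(path_prefix + ".npz", **arrays)
        manifest = {
            "config": asdict(self.config),
            "seed": self.seed,
            "n_parameters": self.count_parameters(),
            "stages": [name for name, _ in self.stages],
        }
        with open(path_prefix + ".json", "w") as fh:
            json.dump(manifest, fh, indent=1)

    @classmethod
    def load(cls, path_prefix: str) -> "CAFNet":
        with open(path_prefix + ".json") as fh:
            manifest = json.load(fh)
        cfg = NetworkConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in manifest["config"].items()
        })
        model = cls(cfg, seed=manifest["seed"])
        data = np.load(path_prefix + ".npz")
        for i, p in enumerate(model.params()):
            p.value[...] = data[f"p{i}"]
        bn_keys = [k for k in data.files if k.startswith("bn_")]
        bn_layers = [
            layer
            for _, stage in model.stages
            for layer in _iter_layers(stage)
            if isinstance(layer, nn.BatchNorm2D) and layer.enabled
        ]
        means = sorted(k for k in bn_keys if k.endswith("_mean"))
        for layer, key in zip(bn_layers, means):
            layer.running_mean[...] = data[key]
            layer.running_var[...] = data[key[:-5] + "_var"]
        return model


def _iter_layers(stage):
    if isinstance(stage, nn.Sequential):
        for sub in stage.layers:
            yield from _iter_layers(sub)
    elif isinstance(stage, nn.Parallel):
        for sub in stage.branches:
            yield from _iter_layers(sub)
    else:
        yield stage


@dataclass
class CAFNetResults:
    """Fitted-model handle with its training history."""

    model: CAFNet
    history: dict
    train_config: TrainConfig
    best_epoch: int = 0

    def summary(self) -> str:
        h = self.history
        lines = [
            "CAFNet training results",
            "=" * 40,
            f"variant               : {self.model.config.variant}",
            f"trainable parameters  : {self.model.count_parameters():,}",
            f"epochs run            : {len(h['train_loss'])}",
            f"final train loss (MSE): {h['train_loss'][-1]:.6g}",
        ]
        if h["val_loss"]:
            lines.append(f"final val loss (MSE)  : {h['val_loss'][-1]:.6g}")
            lines.append(f"selected epoch        : {self.best_epoch}")
        return "\n".join(lines)


def count_parameters(model) -> int:
    """Trainable parameter count of a model or raw layer."""
    if isinstance(model, CAFNet):
        return model.count_parameters()
    return nn.count_parameters(model)
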