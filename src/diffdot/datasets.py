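"""Paired simulation datasets for training and evaluating reconstructors.

A dataset is a HDF5 container with groups ``train/``, ``val/`` and ``test``,
each holding network inputs (N x 16 x 15 x 2), physical-unit targets
(N x 64 x 64 x 2), domain masks, the raw noisy boundary measurements and the
per-sample phantom metadata needed for resolution analysis.  Target
normalization statistics (per-channel min/max over the training split) are
stored as file attributes and applied at prediction time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Tuple

import h5py
import numpy as np

from .forward import MeasurementSet
from .phantoms import (
    DEFAULT_RANGES,
    Inclusion,
    Phantom,
    add_noise,
    calibrate,
    rasterize,
    sample_phantom,
    simulate,
)
from .physics import PhysicsConstants

SPLIT_NAMES = ("train", "val", "test")
DEFAULT_RATIOS = (0.85, 0.10, 0.05)


def split_sizes(n: int, ratios: Tuple[float, float, float] = DEFAULT_RATIOS):
    """Partition ``n`` samples by the train/val/test ratios (85/10/5)."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    train = int(round(n * ratios[0]))
    val = int(round(n * ratios[1]))
    test = n - train - val
    if min(train, val, test) < 1:
        raise ValueError("every split must receive at least one sample")
    return train, val, test


def phantom_to_json(p: Phantom) -> str:
    return json.dumps(
        {
            "diameter": p.diameter,
            "background_mu_a": p.background_mu_a,
            "background_mu_s_prime": p.background_mu_s_prime,
            "frequency_mhz": p.frequency_mhz,
            "inclusions": [
                {
                    "center": list(i.center),
                    "radius": i.radius,
                    "contrast_a": i.contrast_a,
                    "contrast_s": i.contrast_s,
                }
                for i in p.inclusions
            ],
        }
    )


def phantom_from_json(s: str) -> Phantom:
    d = json.loads(s)
    return Phantom(
        diameter=d["diameter"],
        background_mu_a=d["background_mu_a"],
        background_mu_s_prime=d["background_mu_s_prime"],
        frequency_mhz=d["frequency_mhz"],
        inclusions=tuple(
            Inclusion(
                center=tuple(i["center"]),
                radius=i["radius"],
                contrast_a=i["contrast_a"],
                contrast_s=i["contrast_s"],
            )
            for i in d["inclusions"]
        ),
    )


@dataclass
class DatasetSplit:
    """In-memory view of the dataset container."""

    splits: dict                 # name -> dict of arrays
    normalization_statistics: dict  # target per-channel min/max
    seed: int
    noise_level: float

    def __getitem__(self, name):
        return self.splits[name]

    def n(self, name) -> int:
        return len(self.splits[name]["inputs"])

    def normalize_targets(self, targets: np.ndarray) -> np.ndarray:
        lo = np.asarray(self.normalization_statistics["target_min"])
        hi = np.asarray(self.normalization_statistics["target_max"])
        return (targets - lo) / (hi - lo)

    def denormalize_targets(self, targets: np.ndarray) -> np.ndarray:
        lo = np.asarray(self.normalization_statistics["target_min"])
        hi = np.asarray(self.normalization_statistics["target_max"])
        return targets * (hi - lo) + lo

    def phantom(self, split: str, index: int) -> Phantom:
        return phantom_from_json(self.splits[split]["phantoms"][index])

    def measurement(self, split: str, index: int) -> MeasurementSet:
        g = self.splits[split]
        return MeasurementSet(
            amplitude=g["amplitude"][index],
            phase=g["phase"][index],
            frequency_mhz=float(g["frequency"][index]),
        )


def generate_dataset(
    n: int = 10000,
    ratios: Tuple[float, float, float] = DEFAULT_RATIOS,
    seed: int = 0,
    out: Optional[str] = None,
    noise_level: float = 0.15,
    mesh_rel_size: float = 1.0 / 25.0,
    ranges: Optional[dict] = None,
    constants: PhysicsConstants = PhysicsConstants(),
) -> DatasetSplit:
    """Sample, simulate, noise, calibrate and rasterize ``n`` phantoms.

    Calibration references are noise-free simulations of the homogeneous
    phantom with the same diameter, background and frequency.  Returns the
    in-memory split and, when ``out`` is given, persists the HDF5 container.
    """
    if n < 20:
        raise ValueError("need at least 20 samples to split")
    sizes = split_sizes(n, ratios)
    rng = np.random.default_rng(seed)
    inputs = np.empty((n, 16, 15, 2), dtype=np.float32)
    targets = np.empty((n, 64, 64, 2), dtype=np.float32)
    masks = np.empty((n, 64, 64), dtype=bool)
    amplitude = np.empty((n, 16, 15), dtype=np.float64)
    phase = np.empty((n, 16, 15), dtype=np.float64)
    frequency = np.empty(n, dtype=np.float64)
    phantoms = []
    for i in range(n):
        phantom = sample_phantom(rng, ranges)
        clean = simulate(phantom, mesh_rel_size, constants)
        if phantom.inclusions:
            reference = simulate(phantom.homogeneous(), mesh_rel_size, constants)
        else:
            reference = clean
        noisy = add_noise(clean, noise_level, rng)
        inputs[i] = calibrate(noisy, reference).array
        img = rasterize(phantom)
        targets[i] = img.values
        masks[i] = img.domain_mask
        amplitude[i] = noisy.amplitude
        phase[i] = noisy.phase
        frequency[i] = phantom.frequency_mhz
        phantoms.append(phantom_to_json(phantom))

    splits = {}
    start = 0
    for name, size in zip(SPLIT_NAMES, sizes):
        sl = slice(start, start + size)
        splits[name] = {
            "inputs": inputs[sl],
            "targets": targets[sl],
            "masks": masks[sl],
            "amplitude": amplitude[sl],
            "phase": phase[sl],
            "frequency": frequency[sl],
            "phantoms": phantoms[sl],
        }
        start += size
    train_targets = splits["train"]["targets"]
    stats = {
        "target_min": train_targets.reshape(-1, 2).min(axis=0).astype(float).tolist(),
        "target_max": train_targets.reshape(-1, 2).max(axis=0).astype(float).tolist(),
    }
    ds = DatasetSplit(
        splits=splits,
        normalization_statistics=stats,
        seed=seed,
        noise_level=noise_level,
    )
    if out is not None:
        save_dataset(ds, out, ranges=ranges)
    return ds


def save_dataset(ds: DatasetSplit, path: str, ranges: Optional[dict] = None) -> None:
    try:
        with h5py.File(path, "w", track_order=False) as f:
            f.attrs["seed"] = ds.seed
            f.attrs["noise_level"] = ds.noise_level
            f.attrs["target_min"] = ds.normalization_statistics["target_min"]
            f.attrs["target_max"] = ds.normalization_statistics["target_max"]
            f.attrs["ranges"] = json.dumps(ranges or DEFAULT_RANGES)
            for name in SPLIT_NAMES:
                g = f.create_group(name)
                split = ds.splits[name]
                for key in (
                    "inputs",
                    "targets",
                    "masks",
                    "amplitude",
                    "phase",
                    "frequency",
                ):
                    g.create_dataset(key, data=split[key], track_times=False)
                g.create_dataset(
                    "phantoms",
                    data=np.array(split["phantoms"], dtype=h5py.string_dtype()),
                    track_times=False,
                )
    except OSError as exc:  # pragma: no cover - I/O failure path
        raise OSError(f"failed to write dataset container {path}: {exc}") from exc


def load_dataset(path: str) -> DatasetSplit:
    try:
        with h5py.File(path, "r") as f:
            splits = {}
            for name in SPLIT_NAMES:
                g = f[name]
                splits[name] = {
                    "inputs": g["inputs"][...],
                    "targets": g["targets"][...],
                    "masks": g["masks"][...],
                    "amplitude": g["amplitude"][...],
                    "phase": g["phase"][...],
                    "frequency": g["frequency"][...],
                    "phantoms": [s.decode() for s in g["phantoms"][...]],
                }
            stats = {
                "target_min": list(f.attrs["target_min"]),
                "target_max": list(f.attrs["target_max"]),
            }
            return DatasetSplit(
                splits=splits,
                normalization_statistics=stats,
                seed=int(f.attrs["seed"]),
                noise_level=float(f.attrs["noise_level"]),
            )
    except OSError as exc:
        raise OSError(f"failed to read dataset container {path}: {exc}") from exc
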