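"""Shared training plumbing: augmentation, convergence, checkpoints.

Augmentation follows the acquisition-side recipe used for both
depth-from-defocus networks: random rotations, random cropping and
additive Gaussian noise with standard deviation 0.1 (on [0, 1]
intensities); the siamese variant adds random translations and zoom.
Targets are always computed before augmentation, so augmentation never
changes a label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .nn import Sequential


@dataclass(frozen=True)
class AugmentationSpec:
    rotations: bool = True           # uniform-angle in-plane rotation
    crop_fraction: float = 0.9       # lower bound of the random crop side
    noise_std: float = 0.1           # additive Gaussian noise on [0,1] intensities
    translations: float = 0.0        # max |shift| in px (siamese variant)
    zoom: float = 0.0                # max relative zoom, e.g. 0.1 -> [0.9, 1.1]

    def __post_init__(self):
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")
        if not 0 < self.crop_fraction <= 1:
            raise ValueError("crop_fraction must be in (0, 1]")


@dataclass(frozen=True)
class ConvergenceRule:
    """Operationalises "train until convergence": stop after ``patience``
    epochs without at least ``min_delta`` improvement of the monitored loss."""

    max_epochs: int = 60
    patience: int = 10
    min_delta: float = 0.0

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


def augment_batch(images: np.ndarray, spec: AugmentationSpec,
                  rng: np.random.Generator) -> np.ndarray:
    """Augment a (N, H, W) batch; every image gets independent transforms.

    Rotation uses bilinear interpolation with nearest-edge fill; the random
    crop resamples all images of the batch to a common side so they still
    stack.  Noise is added last.
    """
    n, h, w = images.shape
    out = np.empty_like(images)
    for i in range(n):
        img = images[i]
        if spec.rotations:
            angle = rng.uniform(0.0, 360.0)
            img = ndimage.rotate(img, angle, reshape=False, order=1,
                                 mode="nearest")
        if spec.zoom > 0:
            f = 1.0 + rng.uniform(-spec.zoom, spec.zoom)
            zoomed = ndimage.zoom(img, f, order=1, mode="nearest")
            zh, zw = zoomed.shape
            if zh >= h:
                r0 = (zh - h) // 2
                c0 = (zw - w) // 2
                img = zoomed[r0:r0 + h, c0:c0 + w]
            else:
                pr, pc = h - zh, w - zw
                img = np.pad(zoomed, ((pr // 2, pr - pr // 2),
                                      (pc // 2, pc - pc // 2)), mode="edge")
        if spec.translations > 0:
            dy = rng.integers(-int(spec.translations), int(spec.translations) + 1)
            dx = rng.integers(-int(spec.translations), int(spec.translations) + 1)
            img = np.roll(np.roll(img, dy, axis=0), dx, axis=1)
        out[i] = img
    if spec.crop_fraction < 1.0:
        side = int(round(h * rng.uniform(spec.crop_fraction, 1.0)))
        side = max(side, 8)
        cropped = np.empty((n, side, side), dtype=out.dtype)
        for i in range(n):
            r0 = rng.integers(0, h - side + 1)
            c0 = rng.integers(0, w - side + 1)
            cropped[i] = out[i, r0:r0 + side, c0:c0 + side]
        out = cropped
    if spec.noise_std > 0:
        out = out + rng.normal(0.0, spec.noise_std,
                               size=out.shape).astype(np.float32)
    return out.astype(np.float32)


class TrainedModel:
    """A trained network bundle: named nets + config + per-epoch log.

    Serialized as a single ``.npz`` archive with the config and log embedded
    as JSON, so a checkpoint is self-describing and reloadable without any
    side files.
    """

    def __init__(self, kind: str, config: dict, nets: dict[str, Sequential],
                 log: list[dict] | None = None):
        self.kind = kind
        self.config = config
        self.nets = nets
        self.log = log or []

    def save(self, path) -> None:
        arrays = {}
        for name, net in self.nets.items():
            for key, arr in net.state_arrays().items():
                arrays[f"{name}__{key}"] = arr
        meta = json.dumps({"kind": self.kind, "config": self.config,
                           "log": self.log, "net_names": list(self.nets)})
        np.savez_compressed(path, __meta__=np.frombuffer(
            meta.encode(), dtype=np.uint8), **arrays)

    @staticmethod
    def load(path) -> "TrainedModel":
        from . import beadnet, siamese, vae  # local import to avoid cycles
        builders = {"bead_regressor": beadnet.build_nets,
                    "siamese": siamese.build_nets,
                    "factor_vae": vae.build_nets}
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            nets = builders[meta["kind"]](meta["config"],
                                          np.random.default_rng(0))
            for name, net in nets.items():
                arrays = {k.split("__", 1)[1]: data[k] for k in data.files
                          if k.startswith(name + "__")}
                net.load_state_arrays(arrays)
        return TrainedModel(meta["kind"], meta["config"], nets, meta["log"])


def derive_seed(seed: int, label: str) -> int:
    """Deterministic per-stage sub-seed below 2^31."""
    h = np.uint64(1469598103934665603)
    for b in f"{seed}:{label}".encode():
        h = np.uint64((int(h) ^ b) * 1099511628211 % (1 << 64))
    return int(h % (1 << 31))


def train_val_split(n: int, val_frac: float, rng: np.random.Generator):
    idx = rng.permutation(n)
    n_val = max(int(round(n * val_frac)), 1) if val_frac > 0 else 0
    return idx[n_val:], idx[:n_val]


def augmentation_to_dict(spec: AugmentationSpec) -> dict:
    return asdict(spec)


def convergence_to_dict(rule: ConvergenceRule) -> dict:
    return asdict(rule)
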