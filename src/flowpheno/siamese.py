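"""Siamese z-distance regression between pairs of single-cell images.

Heterogeneous cells defeat absolute depth-from-defocus regression — a
large blurred cell and a small sharp one can look alike — so the signed
z-distance between two images of the *same* cell is learned instead.
Both images pass through one weight-shared convolutional embedding
module; the two embeddings are concatenated and a small perceptron maps
them to the signed distance in µm.  Weight sharing plus the global
embedding bottleneck discourage pixel-by-pixel comparison.

Training pairs are drawn within single-cell z-stacks only, with target
``(slice_a - slice_b) * spacing`` computed before augmentation (random
rotations, translations, zoom and Gaussian noise, sigma 0.1).  Adam with
initial learning rate 1e-4, until convergence.

At apply time, in-flow crops are compared against one well-focused
reference cell and the resulting distance distribution is median-centred,
reproducing how a flowing population's z-profile is measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detect import laplacian_sharpness
from .nn import (Adam, BatchNorm2d, Conv2d, GlobalAvgPool2d, LeakyReLU,
                 Linear, ReLU, Sequential, mse_loss)
from .beadnet import DisplacementSummary, summarize_displacements
from .synth import ZStack
from .train import (AugmentationSpec, ConvergenceRule, TrainedModel,
                    augment_batch, augmentation_to_dict, convergence_to_dict)


@dataclass(frozen=True)
class SiameseConfig:
    widths: tuple[int, ...] = (12, 24, 48)     # shared embedding trunk
    head_hidden: int = 64
    leaky_alpha: float = 0.1
    learning_rate: float = 1e-4                # initial; halved every lr_step epochs
    lr_step: int = 20
    batch_size: int = 32
    pairs_per_stack: int = 64                  # ordered pairs drawn per stack per epoch
    val_stack_fraction: float = 0.2
    augmentation: AugmentationSpec = field(
        default_factory=lambda: AugmentationSpec(rotations=True,
                                                 crop_fraction=1.0,
                                                 noise_std=0.1,
                                                 translations=3.0,
                                                 zoom=0.1))
    convergence: ConvergenceRule = field(
        default_factory=lambda: ConvergenceRule(max_epochs=40, patience=8))
    seed: int = 0

    def to_dict(self) -> dict:
        return {"widths": list(self.widths), "head_hidden": self.head_hidden,
                "leaky_alpha": self.leaky_alpha,
                "learning_rate": self.learning_rate, "lr_step": self.lr_step,
                "batch_size": self.batch_size,
                "pairs_per_stack": self.pairs_per_stack,
                "val_stack_fraction": self.val_stack_fraction,
                "augmentation": augmentation_to_dict(self.augmentation),
                "convergence": convergence_to_dict(self.convergence),
                "seed": self.seed}


def build_nets(config: dict, rng: np.random.Generator) -> dict[str, Sequential]:
    widths = config["widths"]
    alpha = config.get("leaky_alpha", 0.1)
    layers = []
    prev = 1
    for w in widths:
        layers += [Conv2d(prev, w, 3, stride=2, pad=1, rng=rng),
                   BatchNorm2d(w), LeakyReLU(alpha)]
        prev = w
    layers += [GlobalAvgPool2d()]
    embed = Sequential(*layers)
    hidden = config.get("head_hidden", 64)
    head = Sequential(Linear(2 * prev, hidden, rng=rng), ReLU(),
                      Linear(hidden, 1, rng=rng))
    return {"embed": embed, "head": head}


@dataclass
class SiamesePairSample:
    image_a: np.ndarray
    image_b: np.ndarray
    target: float                    # signed µm: (slice_a - slice_b) * spacing
    stack_id: int = -1
    slice_a: int = -1
    slice_b: int = -1


def make_pair_dataset(stacks: list[ZStack], n_pairs_per_stack: int,
                      rng: np.random.Generator,
                      augmentation: AugmentationSpec | None = None
                      ) -> list[SiamesePairSample]:
    """Draw ordered slice pairs within each stack; targets precede augmentation.

    Single-slice stacks only ever contribute zero-distance pairs (allowed).
    Exact antisymmetry target(a, b) = -target(b, a) holds by construction.
    """
    samples: list[SiamesePairSample] = []
    for sid, stack in enumerate(stacks):
        n = len(stack.slices)
        ia = rng.integers(0, n, size=n_pairs_per_stack)
        ib = rng.integers(0, n, size=n_pairs_per_stack)
        for a, b in zip(ia, ib):
            img_a = stack.slices[a]
            img_b = stack.slices[b]
            target = float((a - b) * stack.spacing)
            if augmentation is not None:
                img_a = augment_batch(img_a[None], augmentation, rng)[0]
                img_b = augment_batch(img_b[None], augmentation, rng)[0]
            samples.append(SiamesePairSample(img_a, img_b, target,
                                             sid, int(a), int(b)))
    return samples


def save_pair_dataset(path_prefix, pairs: list[SiamesePairSample]) -> None:
    """Cache a pair dataset as a multi-page TIFF (images interleaved
    a0, b0, a1, b1, ...) plus a CSV of pair metadata and targets."""
    import pandas as pd
    import tifffile
    stacked = np.stack([img for p in pairs for img in (p.image_a, p.image_b)])
    tifffile.imwrite(f"{path_prefix}.tif", stacked.astype(np.float32))
    pd.DataFrame({"pair_id": np.arange(len(pairs)),
                  "stack_id": [p.stack_id for p in pairs],
                  "slice_a": [p.slice_a for p in pairs],
                  "slice_b": [p.slice_b for p in pairs],
                  "target_um": [p.target for p in pairs]}
                 ).to_csv(f"{path_prefix}.csv", index=False)


def load_pair_dataset(path_prefix) -> list[SiamesePairSample]:
    import pandas as pd
    import tifffile
    stacked = np.asarray(tifffile.imread(f"{path_prefix}.tif"),
                         dtype=np.float32)
    meta = pd.read_csv(f"{path_prefix}.csv")
    return [SiamesePairSample(stacked[2 * i], stacked[2 * i + 1],
                              float(r.target_um), int(r.stack_id),
                              int(r.slice_a), int(r.slice_b))
            for i, r in meta.iterrows()]


def _forward_pairs(nets, xa, xb, train):
    """Shared-trunk forward: both images through one stacked pass."""
    both = np.concatenate([xa, xb], axis=0)[:, None]
    emb = nets["embed"].forward(both, train=train)
    n = len(xa)
    fused = np.concatenate([emb[:n], emb[n:]], axis=1)
    return nets["head"].forward(fused, train=train)[:, 0], n


def _backward_pairs(nets, grad_out, n, emb_dim):
    gf = nets["head"].backward(grad_out[:, None])
    gemb = np.concatenate([gf[:, :emb_dim], gf[:, emb_dim:]], axis=0)
    nets["embed"].backward(gemb)


def train_siamese(stacks: list[ZStack], cfg: SiameseConfig = SiameseConfig()
                  ) -> TrainedModel:
    """Train the pair-distance network until convergence.

    Each epoch draws ``pairs_per_stack`` fresh augmented ordered pairs from
    every training stack; validation pairs come from held-out stacks and
    are fixed (unaugmented slices) across epochs.
    """
    rng = np.random.default_rng(cfg.seed)
    nets = build_nets(cfg.to_dict(), rng)
    params = nets["embed"].params() + nets["head"].params()
    opt = Adam(params, lr=cfg.learning_rate)
    emb_dim = cfg.widths[-1]

    order = rng.permutation(len(stacks))
    n_val = max(int(round(len(stacks) * cfg.val_stack_fraction)), 1)
    val_stacks = [stacks[i] for i in order[:n_val]]
    tr_stacks = [stacks[i] for i in order[n_val:]]
    val_pairs = make_pair_dataset(val_stacks, cfg.pairs_per_stack,
                                  np.random.default_rng(cfg.seed + 1))

    best = np.inf
    best_state = None
    stall = 0
    log: list[dict] = []
    rule = cfg.convergence
    for epoch in range(rule.max_epochs):
        if cfg.lr_step > 0:
            opt.lr = cfg.learning_rate * 0.5 ** (epoch // cfg.lr_step)
        pairs = make_pair_dataset(tr_stacks, cfg.pairs_per_stack, rng,
                                  augmentation=cfg.augmentation)
        perm = rng.permutation(len(pairs))
        ep_loss, n_b = 0.0, 0
        for start in range(0, len(perm), cfg.batch_size):
            sel = perm[start:start + cfg.batch_size]
            xa = np.stack([pairs[i].image_a for i in sel])
            xb = np.stack([pairs[i].image_b for i in sel])
            y = np.array([pairs[i].target for i in sel], dtype=np.float32)
            pred, n = _forward_pairs(nets, xa, xb, train=True)
            loss, grad = mse_loss(pred, y)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"siamese training diverged at epoch {epoch}")
            opt.zero_grad()
            _backward_pairs(nets, grad, n, emb_dim)
            opt.step()
            ep_loss += loss
            n_b += 1
        val_mse = _eval_pairs_mse(nets, val_pairs, cfg.batch_size)
        log.append({"epoch": epoch, "train_mse": ep_loss / max(n_b, 1),
                    "val_mse": val_mse})
        if val_mse < best - rule.min_delta:
            best = val_mse
            best_state = {name: {k: v.copy() for k, v in net.state_arrays().items()}
                          for name, net in nets.items()}
            stall = 0
        else:
            stall += 1
            if stall >= rule.patience:
                break
    if best_state is not None:
        for name, net in nets.items():
            net.load_state_arrays(best_state[name])
    return TrainedModel("siamese", cfg.to_dict(), nets, log)


def _eval_pairs_mse(nets, pairs, batch_size):
    se, n_tot = 0.0, 0
    for start in range(0, len(pairs), batch_size):
        chunk = pairs[start:start + batch_size]
        xa = np.stack([p.image_a for p in chunk])
        xb = np.stack([p.image_b for p in chunk])
        y = np.array([p.target for p in chunk], dtype=np.float32)
        pred, _ = _forward_pairs(nets, xa, xb, train=False)
        se += float(((pred - y) ** 2).sum())
        n_tot += len(chunk)
    return se / max(n_tot, 1)


def predict_distance(model: TrainedModel, images: np.ndarray,
                     reference: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Signed z-distance (µm) of each image relative to the reference.

    The contract (not a guarantee) is approximate antisymmetry under
    swapping image and reference.
    """
    x = np.asarray(images, dtype=np.float32)
    single = x.ndim == 2
    if single:
        x = x[None]
    ref = np.asarray(reference, dtype=np.float32)
    if ref.shape != x.shape[1:]:
        raise ValueError(f"reference shape {ref.shape} != image shape {x.shape[1:]}")
    out = []
    for start in range(0, len(x), batch_size):
        chunk = x[start:start + batch_size]
        refs = np.broadcast_to(ref, chunk.shape).copy()
        pred, _ = _forward_pairs(model.nets, chunk, refs, train=False)
        out.append(pred)
    res = np.concatenate(out).astype(np.float64)
    return res[0] if single else res


def choose_reference(crops: np.ndarray, species: np.ndarray | None = None,
                     target_species: str | None = None) -> int:
    """Index of the sharpest (best-focused) crop, optionally within a species.

    Operationalises picking "a well-focused reference cell" by maximum
    Laplacian-of-Gaussian sharpness.
    """
    idx = np.arange(len(crops))
    if species is not None and target_species is not None:
        idx = idx[np.asarray(species) == target_species]
        if idx.size == 0:
            raise ValueError(f"no crops of species {target_species!r}")
    scores = [laplacian_sharpness(crops[i]) for i in idx]
    return int(idx[int(np.argmax(scores))])


def flow_displacement_distribution(model: TrainedModel, crops: np.ndarray,
                                   reference: np.ndarray,
                                   bin_width: float = 0.5
                                   ) -> DisplacementSummary:
    """Population z-profile of in-flow crops relative to a reference cell.

    Distances-to-reference are computed for every crop and the histogram is
    centred on the distribution median, so the profile is reported relative
    to where the population actually sits rather than to the (arbitrary)
    reference offset.
    """
    if len(crops) == 0:
        raise ValueError("empty crop set")
    d = predict_distance(model, crops, reference)
    return summarize_displacements(d, bin_width=bin_width,
                                   center=float(np.median(d)))
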