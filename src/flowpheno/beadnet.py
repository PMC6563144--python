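"""Depth-from-defocus regression for microspheres.

A three-block convolutional network maps a single bead crop to its signed
z-displacement (µm) from the focal plane.  Each block is a 3x3
convolution with stride-2 downsampling, batch normalization and leaky
ReLU; a global average pool and a linear head produce the scalar, so the
network accepts any input size no smaller than its receptive field.
Training follows mean-squared-error regression with Adam (initial
learning rate 1e-4) on z-stacks of static beads, augmented by random
rotations, random crops and Gaussian noise of standard deviation 0.1.

The signed target is only learnable because the image formation carries a
through-focus asymmetry; with a symmetric blur model the network can at
best recover |z| (a documented negative control in the test-suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (Adam, BatchNorm2d, Conv2d, GlobalAvgPool2d, LeakyReLU,
                 Linear, Sequential, mse_loss)
from .synth import ZStack
from .train import (AugmentationSpec, ConvergenceRule, TrainedModel,
                    augment_batch, augmentation_to_dict, convergence_to_dict,
                    train_val_split)


@dataclass(frozen=True)
class BeadRegressorConfig:
    widths: tuple[int, ...] = (12, 24, 48)     # one width per conv block
    leaky_alpha: float = 0.1
    learning_rate: float = 1e-4                # initial; halved every lr_step epochs
    lr_step: int = 20
    batch_size: int = 32
    val_fraction: float = 0.2
    augmentation: AugmentationSpec = field(default_factory=AugmentationSpec)
    convergence: ConvergenceRule = field(
        default_factory=lambda: ConvergenceRule(max_epochs=60, patience=10))
    n_restarts: int = 6                        # validation-selected re-inits
    restart_val_target: float = 0.5            # stop restarting below this val MSE
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")

    def to_dict(self) -> dict:
        return {"widths": list(self.widths), "leaky_alpha": self.leaky_alpha,
                "learning_rate": self.learning_rate, "lr_step": self.lr_step,
                "batch_size": self.batch_size,
                "val_fraction": self.val_fraction,
                "n_restarts": self.n_restarts,
                "restart_val_target": self.restart_val_target,
                "augmentation": augmentation_to_dict(self.augmentation),
                "convergence": convergence_to_dict(self.convergence),
                "seed": self.seed}


def build_nets(config: dict, rng: np.random.Generator) -> dict[str, Sequential]:
    """Three conv blocks -> global average pool -> linear scalar head."""
    widths = config["widths"]
    alpha = config.get("leaky_alpha", 0.1)
    layers = []
    prev = 1
    for w in widths:
        layers += [Conv2d(prev, w, 3, stride=2, pad=1, rng=rng),
                   BatchNorm2d(w), LeakyReLU(alpha)]
        prev = w
    layers += [GlobalAvgPool2d(), Linear(prev, 1, rng=rng)]
    return {"regressor": Sequential(*layers)}


def make_bead_training_set(zstacks: list[ZStack]):
    """Flatten labelled z-stacks into (images, signed z targets in µm)."""
    images, targets = [], []
    for stack in zstacks:
        if getattr(stack, "z_labels", None) is None:
            raise ValueError("z-stack without z labels cannot be used for training")
        if len(stack.z_labels) != len(stack.slices):
            raise ValueError("z label count does not match slice count")
        images.append(np.asarray(stack.slices, dtype=np.float32))
        targets.append(np.asarray(stack.z_labels, dtype=np.float32))
    return np.concatenate(images), np.concatenate(targets)


def train_bead_regressor(images: np.ndarray, targets: np.ndarray,
                         cfg: BeadRegressorConfig = BeadRegressorConfig()
                         ) -> TrainedModel:
    """Train until convergence (validation-MSE patience); deterministic per seed.

    Small networks on small datasets occasionally land in a poor basin;
    up to ``n_restarts`` re-initialisations are trained and the one with
    the best validation MSE is kept (restarting stops as soon as a run
    reaches ``restart_val_target``).  Model selection uses only the
    validation split, never held-out data.
    """
    best_model = None
    best_val = np.inf
    for k in range(max(cfg.n_restarts, 1)):
        run_seed = cfg.seed + 1000 * k
        model, val = _train_once(images, targets, cfg, run_seed)
        if val < best_val or best_model is None:
            best_val, best_model = val, model
        if best_val <= cfg.restart_val_target:
            break
    return best_model


def _train_once(images, targets, cfg: BeadRegressorConfig, run_seed: int):
    rng = np.random.default_rng(run_seed)
    nets = build_nets(cfg.to_dict(), rng)
    net = nets["regressor"]
    opt = Adam(net.params(), lr=cfg.learning_rate)

    tr_idx, va_idx = train_val_split(len(images), cfg.val_fraction, rng)
    x_tr, y_tr = images[tr_idx], targets[tr_idx]
    x_va, y_va = images[va_idx], targets[va_idx]

    best = np.inf
    best_state = None
    stall = 0
    log: list[dict] = []
    rule = cfg.convergence
    for epoch in range(rule.max_epochs):
        if cfg.lr_step > 0:
            opt.lr = cfg.learning_rate * 0.5 ** (epoch // cfg.lr_step)
        order = rng.permutation(len(x_tr))
        ep_loss, n_batches = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            batch = augment_batch(x_tr[sel], cfg.augmentation, rng)
            pred = net.forward(batch[:, None], train=True)[:, 0]
            loss, grad = mse_loss(pred, y_tr[sel])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"bead training diverged at epoch {epoch} (loss={loss})")
            opt.zero_grad()
            net.backward(grad[:, None])
            opt.step()
            ep_loss += loss
            n_batches += 1
        val_mse = _eval_mse(net, x_va, y_va, cfg.batch_size)
        log.append({"epoch": epoch, "train_mse": ep_loss / max(n_batches, 1),
                    "val_mse": val_mse})
        if val_mse < best - rule.min_delta:
            best = val_mse
            best_state = {k: v.copy() for k, v in net.state_arrays().items()}
            stall = 0
        else:
            stall += 1
            if stall >= rule.patience:
                break
    if best_state is not None:
        net.load_state_arrays(best_state)
    return TrainedModel("bead_regressor", cfg.to_dict(), nets, log), best


def _eval_mse(net: Sequential, x: np.ndarray, y: np.ndarray,
              batch_size: int) -> float:
    if len(x) == 0:
        return np.nan
    se = 0.0
    for start in range(0, len(x), batch_size):
        pred = net.forward(x[start:start + batch_size][:, None],
                           train=False)[:, 0]
        se += float(((pred - y[start:start + batch_size]) ** 2).sum())
    return se / len(x)


def predict_z(model: TrainedModel, crops: np.ndarray,
              batch_size: int = 64) -> np.ndarray:
    """Signed z-displacement (µm) for each crop, order-preserving."""
    x = np.asarray(crops, dtype=np.float32)
    if x.ndim == 2:
        x = x[None]
    if x.ndim != 3:
        raise ValueError(f"expected (N, H, W) crops, got shape {x.shape}")
    net = model.nets["regressor"]
    out = []
    for start in range(0, len(x), batch_size):
        out.append(net.forward(x[start:start + batch_size][:, None],
                               train=False)[:, 0])
    return np.concatenate(out).astype(np.float64)


@dataclass
class DisplacementSummary:
    """Histogram summary of a population's z-displacements (µm)."""

    displacements: np.ndarray
    bin_width: float
    counts: np.ndarray
    edges: np.ndarray
    center: float = 0.0              # subtracted before binning (0 = raw)

    def fraction_within(self, tol: float) -> float:
        """Fraction of objects with |displacement - center| <= tol µm."""
        return float(np.mean(np.abs(self.displacements - self.center) <= tol))


def summarize_displacements(displacements, bin_width: float = 0.5,
                            center: float = 0.0) -> DisplacementSummary:
    """Bin displacements into a fixed-width histogram (counts sum to n).

    Bin edges are aligned to integer multiples of ``bin_width`` around
    ``center`` so histograms from different populations share a grid.
    """
    d = np.asarray(displacements, dtype=np.float64)
    if d.size == 0:
        raise ValueError("empty displacement list")
    rel = d - center
    lo = np.floor(rel.min() / bin_width) * bin_width
    hi = np.ceil(rel.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(rel, bins=edges)
    return DisplacementSummary(d, bin_width, counts, edges, center)
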