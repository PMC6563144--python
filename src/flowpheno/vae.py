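"""Total-correlation-penalised variational autoencoder (FactorVAE).

The generative model assumes a single-cell crop ``x`` arises from a
10-dimensional latent ``z`` with standard-normal prior p(z) and a
convolutional decoder likelihood p_theta(x|z); a convolutional encoder
yields the variational posterior q_theta(z|x) = N(mu(x), diag(sigma2(x)))
via the reparameterization trick.  Training maximises the evidence lower
bound (reconstruction - KL(q || p)) plus a penalty

    gamma * TC(q(z)),      TC = KL( q(z) || prod_j q(z_j) ),

the latent total correlation, zero iff latent dimensions are independent;
this is what pushes the code toward one factor of variation per
dimension.  TC is estimated with the density-ratio trick: an MLP
discriminator learns to tell encoded batches from batches whose latent
dimensions were independently permuted across the batch (a sample from
the factored distribution), and the mean logit difference is the TC
estimate entering the gamma-weighted term.  Encoder/decoder and
discriminator alternate in a two-player schedule, both trained with Adam
(VAE initial learning rate 5e-4, gamma = 10 by default).

The observation model is Gaussian with a scalar variance sigma_obs^2 that
is, by default, re-calibrated each epoch to the maximum-likelihood value
(the mean squared residual).  The reconstruction term is then
sum(err^2) / (2 sigma_obs^2) per image: early in training the effective
KL weight is high (smooth, heavily regularised codes), and it anneals
automatically as reconstructions sharpen.  A fixed sigma_obs = 1
(plain per-pixel squared error) is available via ``sigma_mode="fixed"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (Adam, BatchNorm2d, Conv2d, ConvTranspose2d, Flatten, Linear,
                 ReLU, Reshape, Sequential, Sigmoid, softmax_cross_entropy)
from .train import ConvergenceRule, TrainedModel, convergence_to_dict


@dataclass(frozen=True)
class VaeArchitecture:
    """Encoder/decoder geometry.

    Six 3x3 convolutions with the configured feature widths; layers
    downsample by stride 2 until the feature map reaches
    ``min_spatial`` and use stride 1 after that.  A small
    fully-connected hidden layer sits between the conv stack and the
    posterior head (and mirrored in the decoder).  The reduced 64x64
    preset with widths (8, ..., 256) is the CPU-scale default;
    ``full_preset`` gives the full-resolution 128x128 network, widths (16, ..., 512).
    """

    input_size: int = 64
    widths: tuple[int, ...] = (8, 16, 32, 64, 128, 256)
    latent_dim: int = 10
    min_spatial: int = 2
    fc_hidden: int = 128
    output_activation: str = "linear"      # "linear" | "sigmoid"

    def strides(self) -> tuple[int, ...]:
        out = []
        size = self.input_size
        for _ in self.widths:
            if size // 2 >= self.min_spatial:
                out.append(2)
                size //= 2
            else:
                out.append(1)
        return tuple(out)

    @property
    def final_spatial(self) -> int:
        size = self.input_size
        for s in self.strides():
            size //= s
        return size

    @staticmethod
    def full_preset() -> "VaeArchitecture":
        return VaeArchitecture(128, (16, 32, 64, 128, 256, 512), 10,
                               output_activation="sigmoid")


@dataclass(frozen=True)
class DiscriminatorConfig:
    hidden: int = 64
    n_hidden_layers: int = 2
    learning_rate: float = 1e-3
    beta1: float = 0.5
    steps_per_vae_step: int = 2


@dataclass(frozen=True)
class VaeConfig:
    arch: VaeArchitecture = field(default_factory=VaeArchitecture)
    disc: DiscriminatorConfig = field(default_factory=DiscriminatorConfig)
    gamma: float = 10.0
    learning_rate: float = 5e-4            # initial; cosine-annealed to 0
    batch_size: int = 64
    sigma_mode: str = "calibrated"         # "calibrated" | "fixed"
    convergence: ConvergenceRule = field(
        default_factory=lambda: ConvergenceRule(max_epochs=25, patience=20))
    seed: int = 0

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.sigma_mode not in ("calibrated", "fixed"):
            raise ValueError("sigma_mode must be 'calibrated' or 'fixed'")

    def to_dict(self) -> dict:
        return {"input_size": self.arch.input_size,
                "widths": list(self.arch.widths),
                "latent_dim": self.arch.latent_dim,
                "min_spatial": self.arch.min_spatial,
                "fc_hidden": self.arch.fc_hidden,
                "output_activation": self.arch.output_activation,
                "disc_hidden": self.disc.hidden,
                "disc_layers": self.disc.n_hidden_layers,
                "disc_lr": self.disc.learning_rate,
                "disc_beta1": self.disc.beta1,
                "disc_steps": self.disc.steps_per_vae_step,
                "gamma": self.gamma, "learning_rate": self.learning_rate,
                "batch_size": self.batch_size, "sigma_mode": self.sigma_mode,
                "convergence": convergence_to_dict(self.convergence),
                "seed": self.seed}


@dataclass
class LatentCode:
    """Posterior parameters and a reparameterized sample for a batch."""

    mu: np.ndarray                   # (n, latent_dim)
    log_var: np.ndarray
    z: np.ndarray                    # mu + exp(log_var / 2) * eps


def _arch_from_config(config: dict) -> VaeArchitecture:
    return VaeArchitecture(config["input_size"], tuple(config["widths"]),
                           config["latent_dim"],
                           config.get("min_spatial", 2),
                           config.get("fc_hidden", 128),
                           config.get("output_activation", "linear"))


def build_nets(config: dict, rng: np.random.Generator) -> dict[str, Sequential]:
    arch = _arch_from_config(config)
    widths = list(arch.widths)
    strides = arch.strides()
    latent = arch.latent_dim
    fs = arch.final_spatial
    hid = arch.fc_hidden

    enc_layers = []
    prev = 1
    for w, s in zip(widths, strides):
        enc_layers += [Conv2d(prev, w, 3, stride=s, pad=1, rng=rng),
                       BatchNorm2d(w), ReLU()]
        prev = w
    enc_layers += [Flatten(), Linear(prev * fs * fs, hid, rng=rng), ReLU(),
                   Linear(hid, 2 * latent, rng=rng)]
    encoder = Sequential(*enc_layers)

    dec_layers = [Linear(latent, hid, rng=rng), ReLU(),
                  Linear(hid, widths[-1] * fs * fs, rng=rng),
                  Reshape((widths[-1], fs, fs))]
    rev_w = widths[::-1]
    rev_s = strides[::-1]
    for i, (w_in, w_out) in enumerate(zip(rev_w[:-1], rev_w[1:])):
        if rev_s[i] == 2:
            dec_layers += [ConvTranspose2d(w_in, w_out, 3, stride=2, pad=1,
                                           rng=rng)]
        else:
            dec_layers += [Conv2d(w_in, w_out, 3, stride=1, pad=1, rng=rng)]
        dec_layers += [BatchNorm2d(w_out), ReLU()]
    if rev_s[-1] == 2:
        dec_layers += [ConvTranspose2d(rev_w[-1], 1, 3, stride=2, pad=1, rng=rng)]
    else:
        dec_layers += [Conv2d(rev_w[-1], 1, 3, stride=1, pad=1, rng=rng)]
    if arch.output_activation == "sigmoid":
        dec_layers += [Sigmoid()]
    decoder = Sequential(*dec_layers)

    hidden = config.get("disc_hidden", 64)
    n_hidden = config.get("disc_layers", 2)
    d_layers = []
    prev_d = latent
    for _ in range(n_hidden):
        d_layers += [Linear(prev_d, hidden, rng=rng), ReLU()]
        prev_d = hidden
    d_layers += [Linear(prev_d, 2, rng=rng)]
    discriminator = Sequential(*d_layers)
    return {"encoder": encoder, "decoder": decoder,
            "discriminator": discriminator}


# ------------------------------------------------------------- primitives

def kl_to_prior(mu: np.ndarray, log_var: np.ndarray):
    """KL( N(mu, diag(exp(log_var))) || N(0, I) ), summed over dimensions.

    Closed form: sum_j 0.5 (mu_j^2 + sigma_j^2 - 1 - log sigma_j^2); always
    >= 0, zero iff mu = 0 and log_var = 0.  Scalar for a single code,
    per-sample vector for a batch.
    """
    mu = np.asarray(mu, dtype=np.float64)
    log_var = np.asarray(log_var, dtype=np.float64)
    kl = 0.5 * (mu ** 2 + np.exp(log_var) - 1.0 - log_var).sum(axis=-1)
    return float(kl) if kl.ndim == 0 else kl


def permute_latents(z_batch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample from the factored distribution prod_j q(z_j): permute each
    latent dimension independently across the batch.  Per-dimension value
    multisets are preserved exactly."""
    z = np.asarray(z_batch)
    if z.ndim != 2 or z.shape[0] < 2:
        raise ValueError("permute_latents needs a batch of size >= 2")
    out = np.empty_like(z)
    for j in range(z.shape[1]):
        out[:, j] = z[rng.permutation(z.shape[0]), j]
    return out


def tc_estimate(discriminator: Sequential, z_batch: np.ndarray) -> float:
    """Density-ratio TC estimate: mean (logit_joint - logit_factored)."""
    logits = discriminator.forward(np.asarray(z_batch, dtype=np.float32),
                                   train=False)
    return float(np.mean(logits[:, 0] - logits[:, 1]))


def estimate_tc_from_samples(z: np.ndarray, seed: int = 0, epochs: int = 60,
                             batch_size: int = 128, hidden: int = 64):
    """Train a fresh discriminator on joint-vs-permuted samples of ``z`` and
    return the TC estimate on a held-out half.

    A standalone density-ratio estimator: for latents with a known joint
    (e.g. a correlated Gaussian, TC = -1/2 log det R), this recovers the
    analytic total correlation, which the tests exploit as an oracle.  The
    train/estimate split matters: logits evaluated on the discriminator's
    own training points are overconfident and bias the estimate upward.
    """
    z = np.asarray(z, dtype=np.float32)
    rng = np.random.default_rng(seed)
    half = len(z) // 2
    perm = rng.permutation(len(z))
    halves = (z[perm[:half]], z[perm[half:]])
    dim = z.shape[1]

    def _fit_and_estimate(z_fit, z_est):
        disc = Sequential(Linear(dim, hidden, rng=rng), ReLU(),
                          Linear(hidden, hidden, rng=rng), ReLU(),
                          Linear(hidden, 2, rng=rng))
        opt = Adam(disc.params(), lr=1e-3, beta1=0.5)
        val_perm = permute_latents(z_est, rng)
        best_ce, best_est = np.inf, 0.0
        for _ in range(epochs):
            order = rng.permutation(len(z_fit))
            for start in range(0, len(z_fit), batch_size):
                zb = z_fit[order[start:start + batch_size]]
                if len(zb) < 2:
                    continue
                zp = permute_latents(zb, rng)
                batch = np.concatenate([zb, zp])
                labels = np.concatenate([np.zeros(len(zb), int),
                                         np.ones(len(zp), int)])
                logits = disc.forward(batch, train=True)
                _, grad = softmax_cross_entropy(logits, labels)
                opt.zero_grad()
                disc.backward(grad)
                opt.step()
            # keep the estimate from the epoch generalising best
            val_batch = np.concatenate([z_est, val_perm])
            val_labels = np.concatenate([np.zeros(len(z_est), int),
                                         np.ones(len(val_perm), int)])
            ce, _ = softmax_cross_entropy(
                disc.forward(val_batch, train=False), val_labels)
            if ce < best_ce:
                best_ce = ce
                best_est = tc_estimate(disc, z_est)
        return best_est

    # cross-fitting: each half is scored by a discriminator trained on the
    # other; averaging halves the estimator variance
    est_a = _fit_and_estimate(halves[0], halves[1])
    est_b = _fit_and_estimate(halves[1], halves[0])
    return 0.5 * (est_a + est_b)


def encode(model, crops: np.ndarray, rng: np.random.Generator | None = None,
           eps: np.ndarray | None = None, batch_size: int = 256) -> LatentCode:
    """Map crops to posterior (mu, log_var) and a reparameterized sample.

    ``z`` is deterministic given (mu, log_var, eps); pass ``eps`` or a
    seeded ``rng`` for reproducible samples.
    """
    nets = model.nets if isinstance(model, TrainedModel) else model
    x = np.asarray(crops, dtype=np.float32)
    if x.ndim == 2:
        x = x[None]
    outs = []
    for start in range(0, len(x), batch_size):
        outs.append(nets["encoder"].forward(x[start:start + batch_size][:, None],
                                            train=False))
    out = np.concatenate(outs)
    if not np.isfinite(out).all():
        raise FloatingPointError("non-finite encoder activations")
    latent = out.shape[1] // 2
    mu, log_var = out[:, :latent], out[:, latent:]
    if eps is None:
        rng = rng or np.random.default_rng(0)
        eps = rng.standard_normal(mu.shape).astype(np.float32)
    z = mu + np.exp(0.5 * log_var) * eps
    return LatentCode(mu.astype(np.float64), log_var.astype(np.float64),
                      z.astype(np.float64))


def decode(model, z: np.ndarray) -> np.ndarray:
    """Decode latent vectors to images; deterministic given z."""
    nets = model.nets if isinstance(model, TrainedModel) else model
    zz = np.asarray(z, dtype=np.float32)
    single = zz.ndim == 1
    if single:
        zz = zz[None]
    latent = nets["decoder"].layers[0].w.value.shape[1]
    if zz.shape[1] != latent:
        raise ValueError(f"latent length {zz.shape[1]} != {latent}")
    imgs = nets["decoder"].forward(zz, train=False)[:, 0]
    return imgs[0] if single else imgs


# ------------------------------------------------------------ training

def vae_training_step(x_vae: np.ndarray, x_disc: np.ndarray, nets: dict,
                      opt_vae: Adam, opt_disc: Adam, gamma: float,
                      rng: np.random.Generator, sigma2: float = 1.0,
                      disc_steps: int = 1) -> dict:
    """One alternating update.

    VAE phase: minimise recon + KL + gamma * TC-estimate on ``x_vae``,
    where recon = sum(err^2) / (2 sigma2) per image (Gaussian likelihood
    with observation variance ``sigma2``).  Discriminator phase: encode
    ``x_disc`` and take ``disc_steps`` cross-entropy steps on encoded
    versus dimension-permuted latents.  With gamma = 0 the TC term
    contributes exactly nothing to the VAE gradient.

    Returns the loss components; ``total == recon + kl + gamma * tc`` holds
    exactly as logged, and ``raw_mse`` is the unweighted per-image summed
    squared error (used for sigma re-calibration and convergence).
    """
    n = len(x_vae)
    if n < 2 or len(x_disc) < 2:
        raise ValueError("batches of size >= 2 required (permutation)")
    encoder, decoder, disc = nets["encoder"], nets["decoder"], nets["discriminator"]
    latent = decoder.layers[0].w.value.shape[1]

    out = encoder.forward(x_vae[:, None], train=True)
    mu, log_var = out[:, :latent], out[:, latent:]
    eps = rng.standard_normal(mu.shape).astype(np.float32)
    sigma = np.exp(0.5 * log_var)
    z = mu + sigma * eps
    xhat = decoder.forward(z, train=True)[:, 0]
    err = xhat - x_vae

    raw_mse = float((err ** 2).sum() / n)
    recon = raw_mse / (2.0 * sigma2)
    kl = float(np.mean(kl_to_prior(mu, log_var)))
    d_logits = disc.forward(z, train=False)
    tc = float(np.mean(d_logits[:, 0] - d_logits[:, 1]))
    total = recon + kl + gamma * tc
    if not np.isfinite(total):
        raise FloatingPointError(
            f"non-finite VAE loss (recon={recon}, kl={kl}, tc={tc})")

    opt_vae.zero_grad()
    d_xhat = err / (n * sigma2)
    dz = decoder.backward(d_xhat[:, None, :, :])
    if gamma > 0:
        g_logits = np.zeros_like(d_logits)
        g_logits[:, 0] = gamma / n
        g_logits[:, 1] = -gamma / n
        disc.forward(z, train=False)
        dz = dz + disc.backward(g_logits)
        for p in disc.params():                 # discard D grads from this phase
            p.grad[...] = 0.0
    d_mu = dz + mu / n
    d_logvar = dz * eps * sigma * 0.5 + (np.exp(log_var) - 1.0) / (2 * n)
    encoder.backward(
        np.concatenate([d_mu, d_logvar], axis=1).astype(np.float32))
    opt_vae.step()

    out2 = encoder.forward(x_disc[:, None], train=True)
    mu2, lv2 = out2[:, :latent], out2[:, latent:]
    z2 = (mu2 + np.exp(0.5 * lv2)
          * rng.standard_normal(mu2.shape).astype(np.float32))
    d_loss = 0.0
    for _ in range(max(disc_steps, 1)):
        z_perm = permute_latents(z2, rng)
        batch = np.concatenate([z2, z_perm]).astype(np.float32)
        labels = np.concatenate([np.zeros(len(z2), dtype=int),
                                 np.ones(len(z_perm), dtype=int)])
        logits = disc.forward(batch, train=True)
        d_loss, d_grad = softmax_cross_entropy(logits, labels)
        opt_disc.zero_grad()
        disc.backward(d_grad)
        opt_disc.step()

    return {"recon": recon, "kl": kl, "tc": tc, "total": total,
            "raw_mse": raw_mse, "disc_ce": d_loss}


def train_vae(crops: np.ndarray, cfg: VaeConfig = VaeConfig()) -> TrainedModel:
    """Train encoder/decoder/discriminator until convergence.

    Requires at least 100 crops (sanity floor for unsupervised training).
    The VAE learning rate follows a cosine schedule from the configured
    initial value; convergence is monitored on the per-epoch mean raw
    reconstruction error with the configured patience.  On divergence the
    last completed epoch's weights are restored and the log records the
    abort.
    """
    x = np.asarray(crops, dtype=np.float32)
    if x.ndim != 3:
        raise ValueError(f"expected (N, H, W) crops, got {x.shape}")
    if len(x) < 100:
        raise ValueError("need >= 100 crops to train the VAE")
    if x.shape[1] != cfg.arch.input_size or x.shape[2] != cfg.arch.input_size:
        raise ValueError(
            f"crops {x.shape[1:]} do not match input_size {cfg.arch.input_size}")
    rng = np.random.default_rng(cfg.seed)
    nets = build_nets(cfg.to_dict(), rng)
    opt_vae = Adam(nets["encoder"].params() + nets["decoder"].params(),
                   lr=cfg.learning_rate)
    opt_disc = Adam(nets["discriminator"].params(),
                    lr=cfg.disc.learning_rate, beta1=cfg.disc.beta1)

    n_px = cfg.arch.input_size ** 2
    sigma2 = 1.0
    best = np.inf
    stall = 0
    log: list[dict] = []
    last_good = None
    rule = cfg.convergence
    bs = cfg.batch_size
    for epoch in range(rule.max_epochs):
        opt_vae.lr = cfg.learning_rate * 0.5 * (
            1.0 + np.cos(np.pi * epoch / rule.max_epochs))
        order = rng.permutation(len(x))
        order_d = rng.permutation(len(x))
        sums = {"recon": 0.0, "kl": 0.0, "tc": 0.0, "total": 0.0,
                "raw_mse": 0.0, "disc_ce": 0.0}
        n_steps = 0
        try:
            for start in range(0, len(x) - 1, bs):
                xv = x[order[start:start + bs]]
                xd = x[order_d[start:start + bs]]
                if len(xv) < 2 or len(xd) < 2:
                    continue
                losses = vae_training_step(
                    xv, xd, nets, opt_vae, opt_disc, cfg.gamma, rng,
                    sigma2=sigma2, disc_steps=cfg.disc.steps_per_vae_step)
                for k in sums:
                    sums[k] += losses[k]
                n_steps += 1
        except FloatingPointError:
            if last_good is not None:
                for name, net in nets.items():
                    net.load_state_arrays(last_good[name])
            log.append({"epoch": epoch, "aborted": True})
            break
        entry = {"epoch": epoch, "sigma2": sigma2}
        entry.update({k: v / max(n_steps, 1) for k, v in sums.items()})
        log.append(entry)
        if cfg.sigma_mode == "calibrated":
            sigma2 = max(entry["raw_mse"] / n_px, 1e-3)
        last_good = {name: {k: v.copy() for k, v in net.state_arrays().items()}
                     for name, net in nets.items()}
        if entry["raw_mse"] < best - rule.min_delta:
            best = entry["raw_mse"]
            stall = 0
        else:
            stall += 1
            if stall >= rule.patience:
                break
    return TrainedModel("factor_vae", cfg.to_dict(), nets, log)


def standardize_crops(crops: np.ndarray):
    """Dataset-global standardization used before VAE training.

    Per-crop scaling would amplify noise in defocused (low-contrast) crops
    and erase the defocus-amplitude cue, so one mean/std pair is computed
    over the whole dataset.  Returns (standardized array, mean, std).
    """
    x = np.asarray(crops, dtype=np.float32)
    mean = float(x.mean())
    std = float(x.std())
    if std < 1e-8:
        return np.zeros_like(x), mean, 1.0
    return (x - mean) / std, mean, std
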