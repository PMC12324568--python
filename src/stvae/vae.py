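"""Convolutional VAEs over multi-plane transcript crops and stain crops.

Five configurations are supported through one class: transcripts-only,
stains-only, and multimodal double-decoder variants in which both modalities
are channel-concatenated into a single encoder and reconstructed by two
separate decoders. Encoder blocks are (conv k3 s2 valid -> leaky-ReLU(0.1) ->
batch-norm); decoders mirror the chain with transposed convolutions, using
output padding to reproduce the exact encoder size chain.

The transcript reconstruction objective is a weighted combination of per-gene
soft Dice and pixel focal loss (default 0.8 : 0.4, applied literally, not
renormalised); stain reconstruction uses plain L2. The KL term is weighted by
``beta_kl`` and is off (0) by default: the latent space is used for downstream
analysis, so reconstruction fidelity is prioritised over regularisation.
Training is transductive — every cell is in the training set — with random
orthogonal rotation as the only augmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .preprocess import random_orthogonal_rotation

__all__ = [
    "VAEConfig",
    "VAE",
    "TrainedVAE",
    "LatentMatrix",
    "GeneWeights",
    "build_model",
    "conv_size_chain",
    "min_crop_size",
    "dice_loss",
    "focal_loss",
    "gene_weights",
    "gaussian_kl",
    "composite_loss",
    "train",
    "extract_latent",
]

_EPS = 1e-7


def min_crop_size(n_blocks: int) -> int:
    """Smallest crop admitting ``n_blocks`` stride-2 valid k3 convolutions
    with spatial dim >= 3 entering every block."""
    return 2 ** (n_blocks + 1) - 1


def conv_size_chain(crop_size: int, n_blocks: int) -> list[int]:
    """Spatial sizes through the encoder, e.g. 100 -> 49 -> 24 -> 11 -> 5 -> 2."""
    sizes = [crop_size]
    for _ in range(n_blocks):
        if sizes[-1] < 3:
            raise ValueError(
                f"crop size {crop_size} collapses after {len(sizes) - 1} blocks; "
                f"minimum admissible crop size for {n_blocks} blocks is "
                f"{min_crop_size(n_blocks)}"
            )
        sizes.append((sizes[-1] - 3) // 2 + 1)
    return sizes


@dataclass
class VAEConfig:
    modality: str = "tc"                  # "tc" | "stains" | "both"
    n_genes: int = 0                      # TC plane count (0 for stains-only)
    n_stain_channels: int = 2
    crop_size: int = 100
    n_conv_blocks: int = 5
    channels: tuple[int, ...] | None = None
    latent_dim: int = 50
    spot_padding: int = 3
    learning_rate: float = 5e-4
    batch_size: int = 8
    epochs: int = 15
    adam_eps: float = 1e-8
    weight_decay: float = 0.0
    w_dice: float = 0.8
    w_focal: float = 0.4
    w_stain_l2: float = 1.0
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0
    beta_kl: float = 0.0
    dice_smooth: float = 1.0
    gene_weight_bounds: tuple[float, float] = (1.0, 10.0)
    use_gene_weights: bool = True
    # initial bias of the log-variance head; 0 starts the posterior at unit
    # variance, whose sampling noise doubles as useful training regularisation
    logvar_bias_init: float = 0.0
    # global gradient-norm clip (0 disables) and log-variance clamp: with
    # beta_kl=0 nothing else bounds the posterior parameters
    grad_clip: float = 5.0
    logvar_clamp: float = 8.0
    # initial bias of the sigmoid (TC) output layer: the logit of a sparse
    # foreground prior, so training starts from "mostly background" instead
    # of spending epochs learning it
    tc_output_bias_init: float = -4.0
    seed: int = 0

    def __post_init__(self):
        if self.modality not in ("tc", "stains", "both"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.modality != "stains" and self.n_genes < 1:
            raise ValueError("n_genes must be >= 1 for TC input")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.w_dice < 0 or self.w_focal < 0:
            raise ValueError("loss weights must be non-negative")
        conv_size_chain(self.crop_size, self.n_conv_blocks)  # raises if invalid
        if self.channels is None:
            base = (16, 32, 64, 128, 256, 512)
            self.channels = base[: self.n_conv_blocks]
        if len(self.channels) != self.n_conv_blocks:
            raise ValueError("channels must have one entry per conv block")

    @property
    def in_channels(self) -> int:
        if self.modality == "tc":
            return self.n_genes
        if self.modality == "stains":
            return self.n_stain_channels
        return self.n_genes + self.n_stain_channels


# presets mirroring the five studied configurations (crop sizes shared per
# model; gene count is data-dependent via the tissue-total filter)
def preset(name: str, n_genes: int, **overrides) -> VAEConfig:
    table = {
        "vae1": dict(modality="tc", crop_size=100, spot_padding=3,
                     learning_rate=5e-4, batch_size=8, epochs=15, adam_eps=1e-8),
        "vae2": dict(modality="stains", crop_size=300, learning_rate=5e-5,
                     batch_size=16, epochs=500, adam_eps=1e-8),
        "vae3": dict(modality="both", crop_size=150, spot_padding=4,
                     learning_rate=5e-4, batch_size=16, epochs=20, adam_eps=1e-6),
        "vae4": dict(modality="both", crop_size=200, spot_padding=4,
                     learning_rate=5e-4, batch_size=16, epochs=30, adam_eps=1e-6),
        "vae5": dict(modality="both", crop_size=200, spot_padding=4,
                     learning_rate=5e-4, batch_size=20, epochs=30, adam_eps=1e-6,
                     weight_decay=1e-5),
    }
    if name not in table:
        raise ValueError(f"unknown preset {name!r}")
    kw = dict(table[name])
    kw["n_genes"] = 0 if kw["modality"] == "stains" else n_genes
    kw.update(overrides)
    return VAEConfig(**kw)


@dataclass
class LatentMatrix:
    values: np.ndarray                  # cells x d
    mode: str = "posterior-sample"
    seed: int = 0
    model_id: str = ""

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("latent matrix contains non-finite values")


@dataclass
class GeneWeights:
    """Per-gene reconstruction weights: inverse expression, rescaled per cell
    to its total count, averaged over the batch (or per class), then min-max
    rescaled into ``bounds``."""

    values: np.ndarray                  # (G,) batch-averaged, rescaled
    per_class: dict = field(default_factory=dict)
    bounds: tuple[float, float] = (1.0, 10.0)

    def check_anti_monotone(self, batch_gene_totals: np.ndarray, tol: float = 1e-9) -> bool:
        order = np.argsort(batch_gene_totals, kind="stable")
        w = self.values[order]  # expression ascending -> weights must not increase
        return bool(np.all(np.diff(w) <= tol))


def gene_weights(batch_counts: np.ndarray,
                 class_labels: np.ndarray | None = None,
                 bounds: tuple[float, float] = (1.0, 10.0)) -> GeneWeights:
    counts = np.asarray(batch_counts, dtype=np.float64)
    if counts.ndim != 2 or counts.shape[0] == 0:
        raise ValueError("batch_counts must be a non-empty (cells x genes) array")
    inv = 1.0 / (counts + 1.0)          # +1 pseudocount for zero-count genes
    totals = counts.sum(axis=1, keepdims=True)
    w = inv * totals / inv.sum(axis=1, keepdims=True)

    def finalize(avg_w, group_counts):
        # project onto weights non-increasing in group expression (pool-
        # adjacent-violators), then min-max rescale into bounds; per-cell
        # averaging alone does not guarantee the anti-monotone property
        from sklearn.isotonic import IsotonicRegression

        expr = group_counts.sum(axis=0).astype(np.float64)
        iso = IsotonicRegression(increasing=False)
        order = np.argsort(expr, kind="stable")
        v = np.empty_like(avg_w)
        v[order] = iso.fit_transform(np.arange(len(expr)), avg_w[order])
        lo, hi = bounds
        vmin, vmax = v.min(), v.max()
        if vmax - vmin < 1e-12:
            return np.full_like(v, lo)
        return lo + (v - vmin) * (hi - lo) / (vmax - vmin)

    per_class = {}
    if class_labels is not None:
        labels = np.asarray(class_labels)
        for lab in np.unique(labels):
            sel = labels == lab
            per_class[lab] = finalize(w[sel].mean(axis=0), counts[sel])
    return GeneWeights(values=finalize(w.mean(axis=0), counts),
                       per_class=per_class, bounds=bounds)


# ---------------------------------------------------------------------------
# losses (public closed forms + internal gradient versions)

def _as_batched(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=np.float64)
    return a[None] if a.ndim == 3 else a


def dice_loss(pred_probs: np.ndarray, target_binary: np.ndarray,
              gene_weights: np.ndarray | None = None,
              smooth: float = 0.0) -> float:
    """Per-gene soft Dice 1 - (2*sum(p*t) + s) / (sum(p) + sum(t) + s),
    combined across planes by a (gene-weights-weighted) mean, then averaged
    over the batch."""
    loss, _ = _dice_loss_grad(pred_probs, target_binary, gene_weights, smooth)
    return loss


def _dice_loss_grad(pred, target, w=None, smooth=0.0):
    p = _as_batched(pred)
    t = _as_batched(target)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if smooth < 0:
        raise ValueError("smooth must be >= 0")
    B, G = p.shape[:2]
    P = p.sum(axis=(2, 3))
    T = t.sum(axis=(2, 3))
    I = (p * t).sum(axis=(2, 3))
    denom = P + T + smooth
    if smooth == 0.0 and np.any(denom == 0):
        raise ValueError("empty prediction and target with smooth=0")
    d = 1.0 - (2.0 * I + smooth) / denom                      # (B, G)
    if w is None:
        wn = np.full(G, 1.0 / G)
    else:
        w = np.asarray(w, dtype=np.float64)
        wn = w / w.sum()
    loss = float((d * wn).sum(axis=1).mean())
    # d(d_bg)/dp = -(2*t*denom - (2I + s)) / denom^2
    coef = (wn[None, :] / B)[:, :, None, None]
    dd = -(2.0 * t * denom[:, :, None, None] - (2.0 * I + smooth)[:, :, None, None]) \
        / (denom ** 2)[:, :, None, None]
    return loss, coef * dd if pred.ndim == 4 else (coef * dd)[0]


def focal_loss(pred_probs: np.ndarray, target_binary: np.ndarray,
               alpha: float = 0.25, gamma: float = 2.0) -> float:
    """Mean over pixels of -alpha_t (1 - p_t)^gamma log p_t."""
    loss, _ = _focal_loss_grad(pred_probs, target_binary, alpha, gamma)
    return loss


def _focal_loss_grad(pred, target, alpha=0.25, gamma=2.0):
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    p = np.clip(np.asarray(pred, dtype=np.float64), _EPS, 1.0 - _EPS)
    t = np.asarray(target, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    pt = np.where(t == 1, p, 1.0 - p)
    at = np.where(t == 1, alpha, 1.0 - alpha)
    one_m = 1.0 - pt
    log_pt = np.log(pt)
    loss = float(np.mean(-at * one_m ** gamma * log_pt))
    # dL/dpt = -a_t [ (1-pt)^g / pt - g (1-pt)^(g-1) log pt ]
    if gamma == 0:
        dpt = -at / pt
    else:
        dpt = -at * (one_m ** gamma / pt - gamma * one_m ** (gamma - 1) * log_pt)
    sign = np.where(t == 1, 1.0, -1.0)
    grad = dpt * sign / p.size
    return loss, grad


def gaussian_kl(mu: np.ndarray, logvar: np.ndarray) -> float:
    """Closed-form KL(q(z|x) || N(0, I)), averaged over the batch."""
    return float(0.5 * np.sum(mu ** 2 + np.exp(logvar) - logvar - 1.0) / mu.shape[0])


def composite_loss(model_outputs: dict, targets: dict, config: VAEConfig,
                   weights: GeneWeights | None = None) -> tuple[float, dict]:
    """Total = w_dice*Dice + w_focal*Focal (TC) + w_stain_l2*MSE (stains)
    + beta_kl*KL; components reported separately."""
    comps: dict[str, float] = {}
    total = 0.0
    has_tc = "tc" in model_outputs
    has_st = "stains" in model_outputs
    if has_tc != ("tc" in targets) or has_st != ("stains" in targets):
        raise ValueError("modalities of outputs and targets do not match")
    if has_tc:
        w = weights.values if weights is not None else None
        comps["dice"] = dice_loss(model_outputs["tc"], targets["tc"], w,
                                  smooth=config.dice_smooth)
        comps["focal"] = focal_loss(model_outputs["tc"], targets["tc"],
                                    config.focal_alpha, config.focal_gamma)
        total += config.w_dice * comps["dice"] + config.w_focal * comps["focal"]
    if has_st:
        diff = np.asarray(model_outputs["stains"], dtype=np.float64) - \
            np.asarray(targets["stains"], dtype=np.float64)
        comps["stain_l2"] = float(np.mean(diff ** 2))
        total += config.w_stain_l2 * comps["stain_l2"]
    if "mu" in model_outputs and "logvar" in model_outputs:
        comps["kl"] = gaussian_kl(model_outputs["mu"], model_outputs["logvar"])
        total += config.beta_kl * comps["kl"]
    comps["total"] = total
    return total, comps


# ---------------------------------------------------------------------------
# model

class VAE:
    """Shared-encoder VAE with one decoder per configured modality."""

    def __init__(self, config: VAEConfig):
        self.config = config
        rng = np.random.default_rng([config.seed, 101])
        ch = config.channels
        sizes = conv_size_chain(config.crop_size, config.n_conv_blocks)
        self.sizes = sizes
        enc_layers: list[nn.Layer] = []
        c_prev = config.in_channels
        for c in ch:
            enc_layers += [nn.Conv2d(c_prev, c, rng=rng), nn.LeakyReLU(0.1),
                           nn.BatchNorm2d(c)]
            c_prev = c
        self.encoder = nn.Sequential(enc_layers)
        flat = ch[-1] * sizes[-1] * sizes[-1]
        self.head_mu = nn.Dense(flat, config.latent_dim, rng=rng)
        self.head_logvar = nn.Dense(flat, config.latent_dim, rng=rng)
        self.head_logvar.b.value[...] = config.logvar_bias_init

        self.decoders: dict[str, tuple[nn.Dense, nn.Sequential, str]] = {}
        if config.modality in ("tc", "both"):
            self.decoders["tc"] = self._make_decoder(config.n_genes, "sigmoid", rng)
        if config.modality in ("stains", "both"):
            self.decoders["stains"] = self._make_decoder(
                config.n_stain_channels, "linear", rng)
        self.trained = False
        self.training_log: list[dict] = []

    def _make_decoder(self, out_channels, activation, rng):
        cfg, ch, sizes = self.config, self.config.channels, self.sizes
        dense = nn.Dense(cfg.latent_dim, ch[-1] * sizes[-1] ** 2, rng=rng)
        layers: list[nn.Layer] = []
        rev_ch = list(ch[::-1]) + [out_channels]
        rev_sz = sizes[::-1]
        for i in range(cfg.n_conv_blocks):
            op = rev_sz[i + 1] - ((rev_sz[i] - 1) * 2 + 3)
            layers.append(nn.ConvTranspose2d(rev_ch[i], rev_ch[i + 1],
                                             output_padding=op, rng=rng))
            if i < cfg.n_conv_blocks - 1:
                layers += [nn.LeakyReLU(0.1), nn.BatchNorm2d(rev_ch[i + 1])]
        if activation == "sigmoid":
            layers[-1].b.value[...] = cfg.tc_output_bias_init
        return dense, nn.Sequential(layers), activation

    @property
    def n_decoders(self) -> int:
        return len(self.decoders)

    def params(self) -> list[nn.Param]:
        ps = self.encoder.params() + self.head_mu.params() + self.head_logvar.params()
        for dense, seq, _ in self.decoders.values():
            ps += dense.params() + seq.params()
        return ps

    # -- forward / backward ------------------------------------------------
    def encode(self, x: np.ndarray, train: bool = True):
        h = self.encoder.forward(x, train=train)
        self._h_shape = h.shape
        flat = h.reshape(h.shape[0], -1)
        mu = self.head_mu.forward(flat, train=train)
        logvar = self.head_logvar.forward(flat, train=train)
        # hard clamp far outside the operating range; keeps exp() finite
        c = self.config.logvar_clamp
        return mu, np.clip(logvar, -c, c)

    def decode(self, z: np.ndarray, train: bool = True) -> dict:
        out = {}
        self._dec_caches = {}
        cfg, ch, sizes = self.config, self.config.channels, self.sizes
        for name, (dense, seq, act) in self.decoders.items():
            h = dense.forward(z, train=train)
            h = h.reshape(z.shape[0], ch[-1], sizes[-1], sizes[-1])
            y = seq.forward(h, train=train)
            if act == "sigmoid":
                y = nn.sigmoid(y)
            self._dec_caches[name] = y if act == "sigmoid" else None
            out[name] = y
        return out

    def forward(self, x: np.ndarray, rng: np.random.Generator | None = None,
                train: bool = True, sample: bool = True) -> dict:
        mu, logvar = self.encode(x, train=train)
        if sample:
            eps = (rng or np.random.default_rng(0)).standard_normal(
                mu.shape).astype(np.float32)
            z = mu + np.exp(0.5 * logvar) * eps
            self._eps = eps
        else:
            z = mu
            self._eps = np.zeros_like(mu)
        self._mu, self._logvar = mu, logvar
        out = self.decode(z, train=train)
        out["mu"], out["logvar"], out["z"] = mu, logvar, z
        return out

    def backward(self, grads: dict, beta_kl: float = 0.0) -> None:
        """Backpropagate per-modality output grads (w.r.t. decoder outputs,
        post-activation) through the whole model."""
        cfg, ch, sizes = self.config, self.config.channels, self.sizes
        gz = np.zeros_like(self._mu)
        for name, (dense, seq, act) in self.decoders.items():
            g = grads[name].astype(np.float32)
            if act == "sigmoid":
                y = self._dec_caches[name]
                g = g * y * (1.0 - y)
            g = seq.backward(g)
            g = g.reshape(g.shape[0], -1)
            gz += dense.backward(g)
        B = self._mu.shape[0]
        gmu = gz.copy()
        glv = gz * self._eps * 0.5 * np.exp(0.5 * self._logvar)
        if beta_kl:
            gmu += beta_kl * self._mu / B
            glv += beta_kl * 0.5 * (np.exp(self._logvar) - 1.0) / B
        gflat = self.head_mu.backward(gmu) + self.head_logvar.backward(glv)
        self.encoder.backward(gflat.reshape(self._h_shape))


TrainedVAE = VAE  # the same object before/after fitting; ``trained`` flags it


def build_model(config: VAEConfig) -> VAE:
    return VAE(config)


def _batch_input(cfg: VAEConfig, tc, stains):
    if cfg.modality == "tc":
        return tc.astype(np.float32)
    if cfg.modality == "stains":
        return stains.astype(np.float32)
    return np.concatenate([tc.astype(np.float32), stains.astype(np.float32)], axis=1)


def train(model: VAE, tc_crops: np.ndarray | None = None,
          stain_crops: np.ndarray | None = None,
          counts: np.ndarray | None = None,
          class_labels: np.ndarray | None = None,
          verbose: bool = False) -> VAE:
    """Transductive training over the full crop set with per-sample rotation
    augmentation; per-epoch loss components are recorded in
    ``model.training_log``."""
    cfg = model.config
    needs_tc = cfg.modality in ("tc", "both")
    needs_st = cfg.modality in ("stains", "both")
    if needs_tc and tc_crops is None:
        raise ValueError("model requires TC crops")
    if needs_st and stain_crops is None:
        raise ValueError("model requires stain crops")
    n = len(tc_crops) if needs_tc else len(stain_crops)
    rng = np.random.default_rng([cfg.seed, 211])
    opt = nn.Adam(model.params(), lr=cfg.learning_rate, eps=cfg.adam_eps,
                  weight_decay=cfg.weight_decay)

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        sums: dict[str, float] = {}
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            tc_b = st_b = None
            if needs_tc:
                tc_b = np.empty((len(idx),) + tc_crops.shape[1:], dtype=np.float32)
            if needs_st:
                st_b = np.empty((len(idx),) + stain_crops.shape[1:], dtype=np.float32)
            for j, i in enumerate(idx):
                t = tc_crops[i] if needs_tc else np.zeros((1, 1, 1))
                s = stain_crops[i] if needs_st else None
                t_r, s_r, _ = random_orthogonal_rotation(t, s, rng)
                if needs_tc:
                    tc_b[j] = t_r
                if needs_st:
                    st_b[j] = s_r

            x = _batch_input(cfg, tc_b, st_b)
            out = model.forward(x, rng=rng, train=True, sample=True)
            grads: dict[str, np.ndarray] = {}
            comps: dict[str, float] = {}
            total = 0.0
            if needs_tc:
                w = None
                if cfg.use_gene_weights and counts is not None:
                    gw = gene_weights(counts[idx], class_labels[idx] if
                                      class_labels is not None else None,
                                      cfg.gene_weight_bounds)
                    w = gw.values
                dl, dgrad = _dice_loss_grad(out["tc"], tc_b, w, cfg.dice_smooth)
                fl, fgrad = _focal_loss_grad(out["tc"], tc_b, cfg.focal_alpha,
                                             cfg.focal_gamma)
                comps["dice"], comps["focal"] = dl, fl
                total += cfg.w_dice * dl + cfg.w_focal * fl
                grads["tc"] = cfg.w_dice * dgrad + cfg.w_focal * fgrad
            if needs_st:
                diff = out["stains"] - st_b
                comps["stain_l2"] = float(np.mean(diff.astype(np.float64) ** 2))
                total += cfg.w_stain_l2 * comps["stain_l2"]
                grads["stains"] = cfg.w_stain_l2 * 2.0 * diff / diff.size
            comps["kl"] = gaussian_kl(out["mu"], out["logvar"])
            total += cfg.beta_kl * comps["kl"]
            comps["total"] = total
            if not np.isfinite(total):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}: try lowering the learning "
                    f"rate; weight decay can also limit gradient magnitude")

            opt.zero_grad()
            model.backward(grads, beta_kl=cfg.beta_kl)
            if cfg.grad_clip > 0:
                gnorm = np.sqrt(sum(float(np.sum(p.grad.astype(np.float64) ** 2))
                                    for p in opt.params))
                if gnorm > cfg.grad_clip:
                    scale = cfg.grad_clip / gnorm
                    for p in opt.params:
                        p.grad *= scale
            opt.step()
            for k, v in comps.items():
                sums[k] = sums.get(k, 0.0) + v
            n_batches += 1

        entry = {"epoch": epoch, **{k: v / n_batches for k, v in sums.items()}}
        model.training_log.append(entry)
        if verbose:
            print(f"epoch {epoch}: " + ", ".join(
                f"{k}={v:.5f}" for k, v in entry.items() if k != "epoch"))
    if cfg.epochs > 0:
        model.trained = True
    return model


def extract_latent(model: VAE, tc_crops: np.ndarray | None = None,
                   stain_crops: np.ndarray | None = None,
                   mode: str = "posterior-sample", seed: int = 0,
                   batch_size: int = 64) -> LatentMatrix:
    """One latent vector per cell: a single posterior draw z = mu + sigma*eps
    (seeded) or the posterior mean."""
    if mode not in ("posterior-sample", "mean"):
        raise ValueError(f"unknown mode {mode!r}")
    if not model.trained:
        warnings.warn("extracting latents from an untrained model")
    cfg = model.config
    needs_tc = cfg.modality in ("tc", "both")
    n = len(tc_crops) if needs_tc else len(stain_crops)
    rng = np.random.default_rng([seed, 307])
    rows = []
    for start in range(0, n, batch_size):
        sl = slice(start, min(start + batch_size, n))
        x = _batch_input(cfg,
                         tc_crops[sl] if needs_tc else None,
                         stain_crops[sl] if stain_crops is not None else None)
        mu, logvar = model.encode(x, train=False)
        if mode == "posterior-sample":
            eps = rng.standard_normal(mu.shape).astype(np.float32)
            z = mu + np.exp(0.5 * logvar) * eps
        else:
            z = mu
        rows.append(z)
    return LatentMatrix(values=np.vstack(rows).astype(np.float64), mode=mode,
                        seed=seed, model_id=cfg.modality)
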