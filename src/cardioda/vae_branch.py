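"""Dual-VAE domain-alignment branch.

Two variational auto-encoders — one per imaging domain — map standardised
axial slices to spatial Gaussian latent maps (mu, sigma); a shared
pixel-wise classifier consumes encoder features from either domain. The
objective combines per-domain reconstruction (L1), the closed-form KL
divergence of each posterior against a standard-normal prior, an explicit
discrepancy loss pulling the two domains' latent statistics together, the
source segmentation loss, and — the semi-supervised extension — a target
segmentation loss on labelled slices plus ground-truth-conditioned target
reconstruction where labels exist (predicted soft label maps condition the
decoder otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .core import N_CLASSES
from .gan_branch import LossBreakdown, TrainBatch
from .nn import Tensor

__all__ = [
    "VaeModelSpec", "VaeLossWeights", "LatentCode", "VaeComponents",
    "build_components", "encode", "reparameterize", "kl_divergence",
    "latent_discrepancy", "reconstruct", "total_loss", "VaeTrainer",
]


@dataclass
class VaeModelSpec:
    input_size: int = 192
    n_classes: int = N_CLASSES
    width: int = 16
    latent_channels: int = 8
    discrepancy: str = "mean_sq"  # or "mmd"

    def __post_init__(self):
        if self.input_size % 4 != 0:
            raise ValueError("input_size must be divisible by 4")
        if self.discrepancy not in ("mean_sq", "mmd"):
            raise ValueError("discrepancy must be 'mean_sq' or 'mmd'")


@dataclass
class VaeLossWeights:
    w_rec_s: float = 1.0
    w_rec_t: float = 1.0
    w_kl: float = 0.01
    w_disc: float = 0.1
    w_seg_source: float = 1.0
    w_seg_target: float = 1.0

    def __post_init__(self):
        if min(self.w_rec_s, self.w_rec_t, self.w_kl, self.w_disc,
               self.w_seg_source, self.w_seg_target) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class LatentCode:
    """Per-sample Gaussian posterior: spatial mu/sigma maps and a sample z."""

    mu: Tensor
    sigma: Tensor
    z: Tensor | None = None

    def __post_init__(self):
        if np.any(self.sigma.data <= 0):
            raise ValueError("sigma must be strictly positive")


class _Encoder(nn.Module):
    def __init__(self, w: int, zc: int, rng):
        self.trunk = nn.Sequential(
            nn.Conv2d(1, w, 3, act="relu", rng=rng),
            nn.Conv2d(w, 2 * w, 3, stride=2, act="relu", rng=rng),
            nn.Conv2d(2 * w, 2 * w, 3, act="relu", rng=rng),
        )
        self.mu_head = nn.Conv2d(2 * w, zc, 3, act="none", rng=rng)
        self.logsigma_head = nn.Conv2d(2 * w, zc, 3, act="none", rng=rng)

    def forward(self, x):
        feats = self.trunk(x)
        logsigma = self.logsigma_head(feats)
        return feats, self.mu_head(feats), logsigma.exp()


class _Decoder(nn.Module):
    """Reconstructs a slice from (z, label condition) — condition has n_classes channels."""

    def __init__(self, w: int, zc: int, n_classes: int, rng):
        self.net = nn.Sequential(
            nn.Conv2d(zc + n_classes, 2 * w, 3, act="relu", rng=rng),
            nn.Upsample2(),
            nn.Conv2d(2 * w, w, 3, act="relu", rng=rng),
            nn.Conv2d(w, 1, 3, act="none", rng=rng),
        )

    def forward(self, x):
        return self.net(x)


class _Classifier(nn.Module):
    def __init__(self, w: int, n_classes: int, rng):
        self.net = nn.Sequential(
            nn.Conv2d(2 * w, 2 * w, 3, act="relu", rng=rng),
            nn.Upsample2(),
            nn.Conv2d(2 * w, w, 3, act="relu", rng=rng),
            nn.Conv2d(w, n_classes, 3, act="none", rng=rng),
        )

    def forward(self, feats):
        return self.net(feats)


@dataclass
class VaeComponents:
    encoder_s: _Encoder
    encoder_t: _Encoder
    decoder_s: _Decoder
    decoder_t: _Decoder
    classifier: _Classifier  # shared across domains
    spec: VaeModelSpec

    def parameters(self):
        params = []
        for m in (self.encoder_s, self.encoder_t, self.decoder_s,
                  self.decoder_t, self.classifier):
            params.extend(m.parameters())
        return params

    def encoder(self, domain: str) -> _Encoder:
        return {"source": self.encoder_s, "target": self.encoder_t}[domain]

    def decoder(self, domain: str) -> _Decoder:
        return {"source": self.decoder_s, "target": self.decoder_t}[domain]


def build_components(spec: VaeModelSpec, seed: int = 0) -> VaeComponents:
    rng = np.random.default_rng(seed)
    w, zc = spec.width, spec.latent_channels
    return VaeComponents(
        encoder_s=_Encoder(w, zc, rng), encoder_t=_Encoder(w, zc, rng),
        decoder_s=_Decoder(w, zc, spec.n_classes, rng),
        decoder_t=_Decoder(w, zc, spec.n_classes, rng),
        classifier=_Classifier(w, spec.n_classes, rng), spec=spec,
    )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _check_size(x: np.ndarray, spec: VaeModelSpec):
    if x.shape[-2:] != (spec.input_size, spec.input_size):
        raise ValueError(
            f"expected {spec.input_size}x{spec.input_size} slices, got {x.shape[-2:]}")


def encode(components: VaeComponents, x, domain: str,
           rng: np.random.Generator | None = None) -> tuple[Tensor, LatentCode]:
    """Encode slices into (features, LatentCode); sigma = exp(log-sigma) > 0."""
    x = nn.as_tensor(x)
    _check_size(x.data, components.spec)
    feats, mu, sigma = components.encoder(domain)(x)
    code = LatentCode(mu, sigma)
    if rng is not None:
        eps = rng.standard_normal(mu.shape).astype(np.float32)
        code.z = reparameterize(code, eps)
    return feats, code


def reparameterize(code: LatentCode, eps) -> Tensor:
    """z = mu + sigma ⊙ eps (the reparameterization trick)."""
    eps = np.asarray(eps, dtype=np.float32)
    if eps.shape != code.mu.shape:
        raise ValueError(f"eps shape {eps.shape} != mu shape {code.mu.shape}")
    return code.mu + code.sigma * nn.Tensor(eps)


def kl_divergence(code: LatentCode, reduction: str = "batch_mean") -> Tensor:
    """Closed-form KL(N(mu, diag sigma^2) || N(0, I)).

    Per element: (mu^2 + sigma^2 - 1 - log sigma^2) / 2. ``batch_mean``
    sums over feature dimensions and averages over the batch; ``mean``
    averages over everything; ``sum`` sums everything.
    """
    if np.any(code.sigma.data <= 0):
        raise ValueError("sigma must be strictly positive")
    mu, sigma = code.mu, code.sigma
    per_elem = (mu * mu + sigma * sigma - 1.0 - (sigma * sigma).log()) * 0.5
    if reduction == "sum":
        return per_elem.sum()
    if reduction == "mean":
        return per_elem.mean()
    if reduction == "batch_mean":
        if per_elem.ndim == 0:
            return per_elem
        n = per_elem.shape[0]
        return per_elem.sum() * (1.0 / n)
    raise ValueError(f"unknown reduction {reduction!r}")


def latent_discrepancy(code_source: LatentCode, code_target: LatentCode,
                       kind: str = "mean_sq") -> Tensor:
    """Explicit cross-domain latent alignment penalty.

    ``mean_sq`` (default): squared distance between the domains'
    batch-mean latent maps, averaged over features — a pseudo-metric that
    is non-negative, symmetric, and zero for identical batches. ``mmd``:
    a Gaussian-kernel maximum mean discrepancy over flattened mu maps.
    """
    mu_s, mu_t = code_source.mu, code_target.mu
    if mu_s.size == 0 or mu_t.size == 0:
        raise ValueError("latent codes must be non-empty")
    if kind == "mean_sq":
        mean_s = mu_s.mean(axis=0) if mu_s.ndim > 1 else mu_s
        mean_t = mu_t.mean(axis=0) if mu_t.ndim > 1 else mu_t
        d = mean_s - mean_t
        return (d * d).mean()
    if kind == "mmd":
        return _mmd(mu_s, mu_t)
    raise ValueError(f"unknown discrepancy kind {kind!r}")


def _mmd(a: Tensor, b: Tensor) -> Tensor:
    """Gaussian-kernel MMD^2 with median-heuristic bandwidth (no gradient
    through the bandwidth)."""
    fa = a.reshape(a.shape[0], -1) if a.ndim > 1 else a.reshape(1, -1)
    fb = b.reshape(b.shape[0], -1) if b.ndim > 1 else b.reshape(1, -1)
    alld = np.concatenate([fa.data, fb.data], axis=0)
    sq = ((alld[:, None] - alld[None]) ** 2).sum(-1)
    med = np.median(sq[sq > 0]) if (sq > 0).any() else 1.0
    gamma = 1.0 / max(med, 1e-12)

    def k(x: Tensor, y: Tensor) -> Tensor:
        d2 = ((x.reshape(x.shape[0], 1, -1) - y.reshape(1, y.shape[0], -1)) ** 2).sum(axis=2)
        return (d2 * (-gamma)).exp().mean()

    return k(fa, fa) + k(fb, fb) - 2.0 * k(fa, fb)


def reconstruct(components: VaeComponents, z: Tensor, domain: str,
                label_condition: Tensor) -> Tensor:
    """Decode z conditioned on a label map (n_classes channels: soft
    predictions for unsupervised slices, one-hot ground truth for
    supervised ones)."""
    n_classes = components.spec.n_classes
    if label_condition.shape[1] != n_classes:
        raise ValueError(
            f"label condition must have {n_classes} channels, got {label_condition.shape[1]}")
    if label_condition.shape[-2:] != z.shape[-2:]:
        raise ValueError("label condition spatial size must match z")
    return components.decoder(domain)(nn.concat([z, label_condition], axis=1))


def _downsample_probs(probs: Tensor) -> Tensor:
    """Average-pool class maps 2x to the latent resolution."""
    n, c, h, w = probs.shape
    return probs.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=5).mean(axis=3)


def total_loss(batch: TrainBatch, components: VaeComponents, weights: VaeLossWeights,
               rng: np.random.Generator | None = None) -> LossBreakdown:
    """Full objective: rec_s, rec_t, kl, disc, seg_src, seg_tgt.

    ``seg_tgt`` is exactly zero with an all-false supervised mask, and
    target reconstruction is conditioned on ground-truth one-hot maps on
    supervised slices and on predicted soft maps elsewhere.
    """
    rng = rng or np.random.default_rng(0)
    spec = components.spec
    x_s = nn.as_tensor(batch.source)
    x_t = nn.as_tensor(batch.target)

    feats_s, code_s = encode(components, x_s, "source", rng)
    feats_t, code_t = encode(components, x_t, "target", rng)

    logits_s = components.classifier(feats_s)
    logits_t = components.classifier(feats_t)

    seg_src = nn.dice_ce_loss(logits_s, batch.source_labels)
    if batch.supervised_mask.any():
        idx = np.flatnonzero(batch.supervised_mask)
        seg_tgt = nn.dice_ce_loss(logits_t[idx], batch.target_labels[idx])
    else:
        seg_tgt = nn.Tensor(np.float32(0.0))

    # source reconstruction conditioned on ground-truth source labels
    cond_s = Tensor(_onehot_at_latent(batch.source_labels, spec))
    rec_s = nn.l1_loss(reconstruct(components, code_s.z, "source", cond_s), x_s)

    # target: GT condition where supervised, predicted soft maps elsewhere
    cond_t = _downsample_probs(logits_t.softmax(axis=1))
    if batch.supervised_mask.any():
        gt_cond = _onehot_at_latent(batch.target_labels, spec)
        mask = batch.supervised_mask[:, None, None, None].astype(np.float32)
        cond_t = cond_t * Tensor(1.0 - mask) + Tensor(gt_cond * mask)
    rec_t = nn.l1_loss(reconstruct(components, code_t.z, "target", cond_t), x_t)

    kl = (kl_divergence(code_s, "mean") + kl_divergence(code_t, "mean")) * 0.5
    disc = latent_discrepancy(code_s, code_t, spec.discrepancy)

    terms = {"rec_s": rec_s, "rec_t": rec_t, "kl": kl, "disc": disc,
             "seg_src": seg_src, "seg_tgt": seg_tgt}
    wmap = {"rec_s": weights.w_rec_s, "rec_t": weights.w_rec_t, "kl": weights.w_kl,
            "disc": weights.w_disc, "seg_src": weights.w_seg_source,
            "seg_tgt": weights.w_seg_target}
    total = None
    for k, t in terms.items():
        contrib = t * wmap[k]
        total = contrib if total is None else total + contrib
    bd = LossBreakdown({k: float(t.data) for k, t in terms.items()}, wmap,
                       float(total.data), tensor=total)
    for name, val in bd.terms.items():
        if not np.isfinite(val):
            raise RuntimeError(f"non-finite loss term {name!r}: {val}")
    return bd


def _onehot_at_latent(labels: np.ndarray, spec: VaeModelSpec) -> np.ndarray:
    """One-hot labels average-pooled to the latent (half) resolution."""
    oh = nn.one_hot(np.asarray(labels), spec.n_classes)
    n, c, h, w = oh.shape
    return oh.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


class VaeTrainer:
    """Joint optimisation of both VAEs and the shared classifier."""

    def __init__(self, spec: VaeModelSpec, weights: VaeLossWeights | None = None,
                 lr: float = 2e-3, seed: int = 0):
        self.spec = spec
        self.weights = weights or VaeLossWeights()
        self.components = build_components(spec, seed)
        self.opt = nn.Adam(self.components.parameters(), lr=lr)
        self.rng = np.random.default_rng(seed + 1)
        self.history: list[dict] = []

    def train_step(self, batch: TrainBatch) -> LossBreakdown:
        for p in self.components.parameters():
            p.grad = None
        bd = total_loss(batch, self.components, self.weights, self.rng)
        bd.tensor.backward()
        self.opt.step()
        self.history.append({"step": len(self.history), **bd.terms, "total": bd.total})
        return bd

    def predict_slices(self, slices: np.ndarray) -> np.ndarray:
        """Argmax segmentation of target-domain slices, (Z,H,W) -> (Z,H,W) int."""
        with nn.no_grad():
            feats, _, _ = self.components.encoder("target")(nn.as_tensor(slices[:, None]))
            probs = self.components.classifier(feats).softmax(axis=1).data
        return probs.argmax(axis=1).astype(np.int16)
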