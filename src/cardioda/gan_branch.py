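"""Adversarial translation-plus-segmentation branch.

A CycleGAN-style source-to-target generator feeds a shared encoder whose
features drive both a decoder (reconstructing source-like images, closing
the cycle) and a pixel-wise classifier producing the segmentation. Patch
discriminators judge generated target and source images; an optional
feature-level discriminator aligns classifier outputs across domains.
The objective combines least-squares adversarial losses, L1
cycle-consistency, a hybrid Dice+CE segmentation loss on translated source
slices, and — the semi-supervised extension — the same segmentation loss
on the subset of real target slices that carry ground-truth labels. With
no supervised target slices the objective reduces exactly to the
unsupervised formulation.

Inputs are axial slices rescaled per slice to [-1, 1]; all generator
outputs pass through tanh and therefore stay in that range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .core import N_CLASSES
from .nn import Tensor

__all__ = [
    "GanModelSpec", "GanLossWeights", "GanComponents", "TrainBatch",
    "LossBreakdown", "build_components", "translate", "reconstruct", "segment",
    "adversarial_loss", "segmentation_loss", "total_loss", "GanTrainer",
]


@dataclass
class GanModelSpec:
    input_size: int = 256
    n_classes: int = N_CLASSES
    width: int = 16
    disc_depth: int = 3
    feature_discriminator: bool = True
    feature_disc_weight: float = 0.1

    def __post_init__(self):
        if self.input_size % 4 != 0:
            raise ValueError("input_size must be divisible by 4")


@dataclass
class GanLossWeights:
    w_adv: float = 1.0
    w_cyc: float = 10.0
    w_seg_source: float = 1.0
    w_seg_target: float = 1.0

    def __post_init__(self):
        if min(self.w_adv, self.w_cyc, self.w_seg_source, self.w_seg_target) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class TrainBatch:
    """One optimisation batch of unpaired source and target axial slices.

    ``supervised_mask`` flags the target slices whose ground-truth labels
    enter the target segmentation loss; it may only be true where labels
    are provided.
    """

    source: np.ndarray          # (Ns, 1, H, W)
    source_labels: np.ndarray   # (Ns, H, W) int
    target: np.ndarray          # (Nt, 1, H, W)
    target_labels: np.ndarray | None = None  # (Nt, H, W) int
    supervised_mask: np.ndarray | None = None  # (Nt,) bool

    def __post_init__(self):
        nt = self.target.shape[0]
        if self.supervised_mask is None:
            self.supervised_mask = np.zeros(nt, dtype=bool)
        self.supervised_mask = np.asarray(self.supervised_mask, dtype=bool)
        if self.supervised_mask.shape != (nt,):
            raise ValueError("supervised_mask must have one flag per target slice")
        if self.supervised_mask.any() and self.target_labels is None:
            raise ValueError("supervised_mask set but no target labels provided")


@dataclass
class LossBreakdown:
    """Named scalar loss terms plus the exact weighted total that was differentiated."""

    terms: dict[str, float]
    weights: dict[str, float]
    total: float
    tensor: Tensor | None = field(default=None, repr=False, compare=False)

    def weighted_sum(self) -> float:
        return float(sum(self.weights[k] * v for k, v in self.terms.items()))


class _Generator(nn.Module):
    def __init__(self, w: int, rng):
        self.net = nn.Sequential(
            nn.Conv2d(1, w, 3, act="relu", rng=rng),
            nn.Conv2d(w, 2 * w, 3, stride=2, act="relu", rng=rng),
            nn.Conv2d(2 * w, 2 * w, 3, act="relu", rng=rng),
            nn.Upsample2(),
            nn.Conv2d(2 * w, w, 3, act="relu", rng=rng),
            nn.Conv2d(w, 1, 3, act="tanh", rng=rng),
        )

    def forward(self, x):
        return self.net(x)


class _Encoder(nn.Module):
    def __init__(self, w: int, rng):
        self.net = nn.Sequential(
            nn.Conv2d(1, w, 3, act="relu", rng=rng),
            nn.Conv2d(w, 2 * w, 3, stride=2, act="relu", rng=rng),
            nn.Conv2d(2 * w, 2 * w, 3, act="relu", rng=rng),
        )

    def forward(self, x):
        return self.net(x)


class _Decoder(nn.Module):
    """Target-feature to source-image reconstructor (the reverse generator)."""

    def __init__(self, w: int, rng):
        self.net = nn.Sequential(
            nn.Conv2d(2 * w, w, 3, act="relu", rng=rng),
            nn.Upsample2(),
            nn.Conv2d(w, w, 3, act="relu", rng=rng),
            nn.Conv2d(w, 1, 3, act="tanh", rng=rng),
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


class _PatchDiscriminator(nn.Module):
    def __init__(self, cin: int, w: int, depth: int, rng):
        mods = [nn.Conv2d(cin, w, 3, stride=2, act="lrelu", rng=rng)]
        c = w
        for _ in range(depth - 2):
            mods.append(nn.Conv2d(c, 2 * c, 3, stride=2, act="lrelu", rng=rng))
            c *= 2
        mods.append(nn.Conv2d(c, 1, 3, act="sigmoid", rng=rng))
        self.net = nn.Sequential(*mods)

    def forward(self, x):
        return self.net(x)


@dataclass
class GanComponents:
    g_st: _Generator       # source -> target image translation
    encoder: _Encoder      # shared encoder for real/generated target images
    decoder: _Decoder      # reconstructs source-like images (cycle)
    classifier: _Classifier
    d_t: _PatchDiscriminator
    d_s: _PatchDiscriminator
    d_feat: _PatchDiscriminator | None
    spec: GanModelSpec

    def generator_params(self):
        params = []
        for m in (self.g_st, self.encoder, self.decoder, self.classifier):
            params.extend(m.parameters())
        return params

    def discriminator_params(self):
        params = self.d_t.parameters() + self.d_s.parameters()
        if self.d_feat is not None:
            params.extend(self.d_feat.parameters())
        return params


def build_components(spec: GanModelSpec, seed: int = 0) -> GanComponents:
    rng = np.random.default_rng(seed)
    w = spec.width
    d_feat = (_PatchDiscriminator(spec.n_classes, w, spec.disc_depth, rng)
              if spec.feature_discriminator else None)
    return GanComponents(
        g_st=_Generator(w, rng), encoder=_Encoder(w, rng), decoder=_Decoder(w, rng),
        classifier=_Classifier(w, spec.n_classes, rng),
        d_t=_PatchDiscriminator(1, w, spec.disc_depth, rng),
        d_s=_PatchDiscriminator(1, w, spec.disc_depth, rng),
        d_feat=d_feat, spec=spec,
    )


# ---------------------------------------------------------------------------
# Forward operations
# ---------------------------------------------------------------------------

def _check_size(x: np.ndarray, spec: GanModelSpec):
    if x.shape[-2:] != (spec.input_size, spec.input_size):
        raise ValueError(
            f"expected {spec.input_size}x{spec.input_size} slices, got {x.shape[-2:]}")


def translate(components: GanComponents, x_source) -> Tensor:
    """Source-to-target image translation; output in [-1, 1] (tanh)."""
    x = nn.as_tensor(x_source)
    _check_size(x.data, components.spec)
    return components.g_st(x)


def reconstruct(components: GanComponents, x) -> Tensor:
    """Map a (real or generated) target image back to a source-like image."""
    x = nn.as_tensor(x)
    _check_size(x.data, components.spec)
    return components.decoder(components.encoder(x))


def segment(components: GanComponents, x) -> Tensor:
    """Per-pixel class probabilities (n_classes channels summing to 1)."""
    return segment_logits(components, x).softmax(axis=1)


def segment_logits(components: GanComponents, x) -> Tensor:
    x = nn.as_tensor(x)
    _check_size(x.data, components.spec)
    return components.classifier(components.encoder(x))


adversarial_loss = nn.lsgan_loss
segmentation_loss = nn.dice_ce_loss


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

def total_loss(batch: TrainBatch, components: GanComponents,
               weights: GanLossWeights) -> LossBreakdown:
    """Generator-side objective with exact weighted decomposition.

    ``seg_src`` is evaluated on translated source slices against source
    labels; ``seg_tgt`` only on target slices flagged supervised — with an
    all-false mask it is exactly zero and the objective is the
    unsupervised one.
    """
    spec = components.spec
    x_s = nn.as_tensor(batch.source)
    x_t = nn.as_tensor(batch.target)
    _check_size(x_s.data, spec)

    fake_t = translate(components, x_s)
    feats_fake = components.encoder(fake_t)
    feats_real = components.encoder(x_t)

    seg_src = segmentation_loss(components.classifier(feats_fake), batch.source_labels)

    if batch.supervised_mask.any():
        idx = np.flatnonzero(batch.supervised_mask)
        sup_logits = components.classifier(components.encoder(x_t[idx]))
        seg_tgt = segmentation_loss(sup_logits, batch.target_labels[idx])
    else:
        seg_tgt = nn.Tensor(np.float32(0.0))

    adv_t = adversarial_loss(components.d_t(fake_t), is_real=True)
    fake_s = components.decoder(feats_real)
    adv_s = adversarial_loss(components.d_s(fake_s), is_real=True)
    cyc = nn.l1_loss(components.decoder(feats_fake), x_s)

    terms = {"adv_t": adv_t, "adv_s": adv_s, "cyc": cyc,
             "seg_src": seg_src, "seg_tgt": seg_tgt}
    wmap = {"adv_t": weights.w_adv, "adv_s": weights.w_adv, "cyc": weights.w_cyc,
            "seg_src": weights.w_seg_source, "seg_tgt": weights.w_seg_target}

    if components.d_feat is not None:
        probs_t = components.classifier(feats_real).softmax(axis=1)
        terms["adv_feat"] = adversarial_loss(components.d_feat(probs_t), is_real=True)
        wmap["adv_feat"] = spec.feature_disc_weight

    total = None
    for k, t in terms.items():
        contrib = t * wmap[k]
        total = contrib if total is None else total + contrib
    bd = LossBreakdown({k: float(t.data) for k, t in terms.items()}, wmap,
                       float(total.data), tensor=total)
    _check_finite(bd)
    return bd


def _check_finite(bd: LossBreakdown):
    for name, val in bd.terms.items():
        if not np.isfinite(val):
            raise RuntimeError(f"non-finite loss term {name!r}: {val}")


def _discriminator_loss(components: GanComponents, batch: TrainBatch) -> Tensor:
    x_s = nn.as_tensor(batch.source)
    x_t = nn.as_tensor(batch.target)
    with nn.no_grad():
        fake_t = translate(components, x_s)
        feats_real = components.encoder(x_t)
        fake_s = components.decoder(feats_real)
        probs_t = components.classifier(feats_real).softmax(axis=1)
        probs_fake = segment(components, fake_t)
    loss = (adversarial_loss(components.d_t(x_t), True)
            + adversarial_loss(components.d_t(fake_t), False)
            + adversarial_loss(components.d_s(x_s), True)
            + adversarial_loss(components.d_s(fake_s), False))
    if components.d_feat is not None:
        loss = loss + (adversarial_loss(components.d_feat(probs_fake), True)
                       + adversarial_loss(components.d_feat(probs_t), False))
    return loss * 0.5


class GanTrainer:
    """Alternating generator/discriminator optimisation with a loss log."""

    def __init__(self, spec: GanModelSpec, weights: GanLossWeights | None = None,
                 lr: float = 2e-3, seed: int = 0):
        self.spec = spec
        self.weights = weights or GanLossWeights()
        self.components = build_components(spec, seed)
        self.opt_g = nn.Adam(self.components.generator_params(), lr=lr)
        self.opt_d = nn.Adam(self.components.discriminator_params(), lr=lr)
        self.history: list[dict] = []

    def train_step(self, batch: TrainBatch) -> LossBreakdown:
        # generator phase
        for p in self.components.generator_params() + self.components.discriminator_params():
            p.grad = None
        bd = total_loss(batch, self.components, self.weights)
        bd.tensor.backward()
        self.opt_g.step()
        # discriminator phase
        for p in self.components.discriminator_params():
            p.grad = None
        d_loss = _discriminator_loss(self.components, batch)
        if not np.isfinite(float(d_loss.data)):
            raise RuntimeError("non-finite loss term 'disc'")
        d_loss.backward()
        self.opt_d.step()
        record = {"step": len(self.history), **bd.terms,
                  "disc": float(d_loss.data), "total": bd.total}
        self.history.append(record)
        return bd

    def predict_slices(self, slices: np.ndarray) -> np.ndarray:
        """Argmax segmentation of target-domain slices, (Z,H,W) -> (Z,H,W) int."""
        with nn.no_grad():
            probs = segment(self.components, slices[:, None]).data
        return probs.argmax(axis=1).astype(np.int16)
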