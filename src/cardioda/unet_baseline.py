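"""Fully supervised 2D UNet baseline.

Trains only on target-domain cases that carry ground-truth labels — the
benchmark against which the semi-supervised generative branches are
compared. The augmentation policy mirrors a standard nnU-Net-style recipe:
affine (rotation + isotropic scaling), additive Gaussian noise, Gaussian
blur, intensity scaling and mirroring, each applied with a configurable
probability. Spatial transforms hit image and labels identically (linear
vs nearest interpolation); intensity transforms hit the image only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import affine_transform, gaussian_filter

from . import nn
from .core import N_CLASSES
from .gan_branch import TrainBatch

__all__ = [
    "UnetSpec", "AugmentationPolicy", "augment", "Unet",
    "UnetTrainer", "train_supervised", "predict",
]


@dataclass
class UnetSpec:
    depth: int = 3
    base_width: int = 8
    n_classes: int = N_CLASSES
    input_size: int = 192

    def __post_init__(self):
        if self.depth < 3:
            raise ValueError("UNet depth must be >= 3")
        if self.input_size % (2 ** (self.depth - 1)) != 0:
            raise ValueError("input_size must be divisible by 2^(depth-1)")


@dataclass
class AugmentationPolicy:
    """Which transforms run, with what probability and magnitude."""

    transforms: tuple[str, ...] = (
        "affine", "gaussian_noise", "gaussian_blur", "scale_intensity", "mirror")
    probabilities: dict[str, float] = field(default_factory=lambda: {
        "affine": 0.3, "gaussian_noise": 0.2, "gaussian_blur": 0.2,
        "scale_intensity": 0.2, "mirror": 0.5})
    rotation_deg: float = 15.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    noise_sd_max: float = 0.1   # fraction of the slice intensity range
    blur_sigma: tuple[float, float] = (0.5, 1.0)
    intensity_scale: tuple[float, float] = (0.9, 1.1)

    def __post_init__(self):
        known = {"affine", "gaussian_noise", "gaussian_blur", "scale_intensity", "mirror"}
        bad = set(self.transforms) - known
        if bad:
            raise ValueError(f"unknown transforms: {sorted(bad)}")
        for t, p in self.probabilities.items():
            if not 0 <= p <= 1:
                raise ValueError(f"probability for {t!r} out of [0,1]: {p}")


def augment(slice2d: np.ndarray, labels: np.ndarray, policy: AugmentationPolicy,
            seed_or_rng) -> tuple[np.ndarray, np.ndarray]:
    """Apply the policy to one aligned image/label slice, reproducibly."""
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    img = np.asarray(slice2d, dtype=np.float32).copy()
    lab = np.asarray(labels).copy()

    def on(name: str) -> bool:
        return (name in policy.transforms
                and rng.uniform() < policy.probabilities.get(name, 0.0))

    if on("affine"):
        theta = np.deg2rad(rng.uniform(-policy.rotation_deg, policy.rotation_deg))
        s = rng.uniform(*policy.scale_range)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]) / s
        center = (np.asarray(img.shape) - 1) / 2.0
        offset = center - rot @ center
        img = affine_transform(img, rot, offset=offset, order=1, mode="constant", cval=0.0)
        lab = affine_transform(lab, rot, offset=offset, order=0, mode="constant",
                               cval=0).astype(lab.dtype)
    if on("mirror"):
        axis = int(rng.integers(0, 2))
        img = np.flip(img, axis=axis).copy()
        lab = np.flip(lab, axis=axis).copy()
    if on("gaussian_noise"):
        rng_range = float(img.max() - img.min())
        sd = rng.uniform(0, policy.noise_sd_max) * (rng_range if rng_range > 0 else 1.0)
        img = img + rng.normal(0, sd, size=img.shape).astype(np.float32)
    if on("gaussian_blur"):
        img = gaussian_filter(img, sigma=rng.uniform(*policy.blur_sigma))
    if on("scale_intensity"):
        img = img * rng.uniform(*policy.intensity_scale)
    return img.astype(np.float32), lab


class Unet(nn.Module):
    """Plain 2D UNet: strided-conv downsampling, nearest-upsample + skip concat."""

    def __init__(self, spec: UnetSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        w = spec.base_width
        widths = [w * 2**i for i in range(spec.depth)]
        self.in_conv = nn.Conv2d(1, widths[0], 3, act="relu", rng=rng)
        self.down = [nn.Conv2d(widths[i], widths[i + 1], 3, stride=2, act="relu", rng=rng)
                     for i in range(spec.depth - 1)]
        self.mid = [nn.Conv2d(c, c, 3, act="relu", rng=rng) for c in widths]
        self.up = [nn.Conv2d(widths[i + 1] + widths[i], widths[i], 3, act="relu", rng=rng)
                   for i in reversed(range(spec.depth - 1))]
        self.out_conv = nn.Conv2d(widths[0], spec.n_classes, 3, act="none", rng=rng)

    def forward(self, x):
        skips = []
        h = self.in_conv(x)
        for i, down in enumerate(self.down):
            h = self.mid[i](h)
            skips.append(h)
            h = down(h)
        h = self.mid[-1](h)
        for up, skip in zip(self.up, reversed(skips)):
            h = up(nn.concat([h.upsample2(), skip], axis=1))
        return self.out_conv(h)


class UnetTrainer:
    def __init__(self, spec: UnetSpec, policy: AugmentationPolicy | None = None,
                 lr: float = 2e-3, seed: int = 0):
        self.spec = spec
        self.policy = policy or AugmentationPolicy()
        self.model = Unet(spec, seed)
        self.opt = nn.Adam(self.model.parameters(), lr=lr)
        self.rng = np.random.default_rng(seed + 1)
        self.history: list[dict] = []

    def train_step(self, batch: TrainBatch) -> float:
        """Supervised Dice+CE step on target slices; ignores source slices."""
        if batch.target_labels is None or not batch.supervised_mask.any():
            raise ValueError("UNet is fully supervised: batch has no labelled target slices")
        idx = np.flatnonzero(batch.supervised_mask)
        imgs, labs = [], []
        for i in idx:
            im, la = augment(batch.target[i, 0], batch.target_labels[i],
                             self.policy, self.rng)
            imgs.append(im)
            labs.append(la)
        x = np.stack(imgs)[:, None]
        y = np.stack(labs)
        self.model.zero_grad()
        loss = nn.dice_ce_loss(self.model(nn.Tensor(x)), y)
        if not np.isfinite(float(loss.data)):
            raise RuntimeError("non-finite loss term 'seg'")
        loss.backward()
        self.opt.step()
        val = float(loss.data)
        self.history.append({"step": len(self.history), "seg": val, "total": val})
        return val

    def predict_slices(self, slices: np.ndarray) -> np.ndarray:
        with nn.no_grad():
            probs = self.model(nn.as_tensor(slices[:, None])).softmax(axis=1).data
        return probs.argmax(axis=1).astype(np.int16)


def train_supervised(slices: np.ndarray, labels: np.ndarray, spec: UnetSpec,
                     policy: AugmentationPolicy | None = None, steps: int = 300,
                     batch_size: int = 4, lr: float = 2e-3, seed: int = 0) -> UnetTrainer:
    """Train on labelled target slices only; fails loudly with zero labelled data."""
    if slices.shape[0] == 0:
        raise ValueError("UNet requires at least one labelled case: "
                         "full supervision, no unsupervised mode (p=0 is invalid)")
    trainer = UnetTrainer(spec, policy, lr=lr, seed=seed)
    rng = np.random.default_rng(seed + 2)
    n = slices.shape[0]
    for _ in range(steps):
        idx = rng.integers(0, n, size=min(batch_size, n))
        batch = TrainBatch(
            source=np.zeros((0, 1, spec.input_size, spec.input_size), np.float32),
            source_labels=np.zeros((0, spec.input_size, spec.input_size), np.int16),
            target=slices[idx][:, None], target_labels=labels[idx],
            supervised_mask=np.ones(len(idx), dtype=bool))
        trainer.train_step(batch)
    return trainer


def predict(trainer: UnetTrainer, slices: np.ndarray) -> np.ndarray:
    """Per-slice class probabilities (N, C, H, W), normalised per pixel."""
    with nn.no_grad():
        return trainer.model(nn.as_tensor(slices[:, None])).softmax(axis=1).data
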