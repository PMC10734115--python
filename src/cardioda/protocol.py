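"""Experiment orchestration.

Patient-wise k-fold cross-validation over the target cohort, selection of
supervised target cases at fraction p in {0, 0.1, 0.2, 0.3}, unpaired
random-slice batch sampling, and the full method x supervision experiment
grid. For every experiment cell the models are trained per fold on the
fold's training cases only, validation cases are predicted slice by slice,
reassembled into original-space 3D label maps, and scored per label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Cohort
from .evaluation import case_metrics
from .gan_branch import GanLossWeights, GanModelSpec, GanTrainer, TrainBatch
from .imaging_io import SliceStack, preprocess_case, reassemble
from .unet_baseline import AugmentationPolicy, UnetSpec, UnetTrainer
from .vae_branch import VaeLossWeights, VaeModelSpec, VaeTrainer

__all__ = [
    "FoldSplit", "SupervisionPlan", "RunConfig", "make_folds", "count_rule",
    "select_supervised", "sample_batch", "run_experiment", "experiment_grid",
]

SUPERVISION_LEVELS = (0.0, 0.1, 0.2, 0.3)


@dataclass
class FoldSplit:
    """k folds of target case ids; validation sets partition the cohort."""

    folds: list[tuple[list[str], list[str]]]  # (train_ids, validation_ids)

    def __post_init__(self):
        all_val = [cid for _, val in self.folds for cid in val]
        if len(all_val) != len(set(all_val)):
            raise ValueError("validation sets must be disjoint")
        for train, val in self.folds:
            if set(train) & set(val):
                raise ValueError("a case appears in both train and validation")

    def __len__(self):
        return len(self.folds)


@dataclass
class SupervisionPlan:
    """Which target training cases contribute labels, per fold."""

    fraction: float
    selected: list[list[str]]  # per fold
    seed: int


def make_folds(case_ids: list[str], k: int, seed: int) -> FoldSplit:
    """Shuffle by seed and split into k near-equal validation sets by patient."""
    case_ids = list(case_ids)
    if k > len(case_ids):
        raise ValueError(f"k={k} exceeds the {len(case_ids)} available cases")
    rng = np.random.default_rng(seed)
    order = [str(c) for c in rng.permutation(case_ids)]
    val_sets = [list(chunk) for chunk in np.array_split(order, k)]
    folds = []
    for val in val_sets:
        train = [cid for cid in order if cid not in val]
        folds.append((train, [str(v) for v in val]))
    return FoldSplit(folds)


def count_rule(p: float, n_total: int, override: int | None = None) -> int:
    """Supervised-case count: floor(p * n_total), unless explicitly overridden."""
    if not 0 <= p <= 1:
        raise ValueError(f"supervision fraction must be in [0, 1], got {p}")
    if override is not None:
        return int(override)
    return math.floor(p * n_total)


def select_supervised(fold_split: FoldSplit, p: float, n_total: int, seed: int,
                      override: int | None = None) -> SupervisionPlan:
    """Uniform random supervised-case pick per fold, excluding validation cases."""
    n_sup = count_rule(p, n_total, override)
    rng = np.random.default_rng(seed)
    selected = []
    for train, _val in fold_split.folds:
        if n_sup > len(train):
            raise ValueError(
                f"requested {n_sup} supervised cases but the fold trains on {len(train)}")
        pick = sorted(rng.choice(train, size=n_sup, replace=False).tolist())
        selected.append(pick)
    return SupervisionPlan(p, selected, seed)


def sample_batch(source_stacks: dict[str, SliceStack], target_stacks: dict[str, SliceStack],
                 supervised_ids: set[str] | list[str], batch_size: int,
                 rng: np.random.Generator) -> TrainBatch:
    """Draw unpaired source/target slices uniformly at random across volumes.

    Source and target indices are drawn independently (no anatomical
    correspondence); the supervised mask marks target slices whose case is
    in the supervision plan.
    """
    if not source_stacks or not target_stacks:
        raise ValueError("source and target pools must be non-empty")
    supervised_ids = set(supervised_ids)

    def draw(stacks: dict[str, SliceStack]):
        ids = sorted(stacks)
        imgs, labs, sup = [], [], []
        for _ in range(batch_size):
            cid = ids[rng.integers(0, len(ids))]
            stack = stacks[cid]
            k = int(rng.integers(0, len(stack)))
            imgs.append(stack.slices[k])
            labs.append(stack.label_slices[k])
            sup.append(cid in supervised_ids)
        return np.stack(imgs)[:, None], np.stack(labs), np.array(sup)

    xs, ys, _ = draw(source_stacks)
    xt, yt, sup_t = draw(target_stacks)
    return TrainBatch(xs, ys, xt, yt, sup_t)


@dataclass
class RunConfig:
    """Desk-scale defaults for one experiment cell; sizes are configurable."""

    out_xy: int = 32
    margin: int | None = 2
    k_folds: int = 2
    steps: int = 200
    batch_size: int = 4
    lr: float = 2e-3
    width: int = 8
    latent_channels: int = 4
    seed: int = 0
    count_override: int | None = None
    gan_weights: GanLossWeights = field(default_factory=GanLossWeights)
    vae_weights: VaeLossWeights = field(default_factory=VaeLossWeights)
    augmentation: AugmentationPolicy = field(default_factory=AugmentationPolicy)


def _build_trainer(method: str, config: RunConfig, seed: int):
    if method == "gan":
        return GanTrainer(GanModelSpec(input_size=config.out_xy, width=config.width),
                          config.gan_weights, lr=config.lr, seed=seed)
    if method == "vae":
        return VaeTrainer(VaeModelSpec(input_size=config.out_xy, width=config.width,
                                       latent_channels=config.latent_channels),
                          config.vae_weights, lr=config.lr, seed=seed)
    if method == "unet":
        return UnetTrainer(UnetSpec(depth=3, base_width=config.width,
                                    input_size=config.out_xy),
                           config.augmentation, lr=config.lr, seed=seed)
    raise ValueError(f"unknown method {method!r}")


def run_experiment(method: str, p: float, cohort: Cohort, config: RunConfig,
                   fold_split: FoldSplit | None = None,
                   predictions_dir=None) -> pd.DataFrame:
    """Train and evaluate one (method, supervision) cell across folds.

    Returns a MetricsTable with one row per (fold, validation case, label).
    The UNet baseline has no unsupervised mode and rejects p = 0.
    """
    if method not in ("gan", "vae", "unet"):
        raise ValueError(f"unknown method {method!r}")
    if method == "unet" and p == 0:
        raise ValueError("the UNet baseline is fully supervised and cannot run at "
                         "p=0 (no labelled target cases)")
    branch = "gan" if method == "gan" else ("vae" if method == "vae" else "unet")
    target_cases = {c.case_id: c for c in cohort.by_domain("target")}
    source_cases = {c.case_id: c for c in cohort.by_domain("source")}

    src_stacks = {cid: preprocess_case(c.volume, c.labels, branch, config.out_xy,
                                       config.margin)
                  for cid, c in source_cases.items()}
    tgt_stacks = {cid: preprocess_case(c.volume, c.labels, branch, config.out_xy,
                                       config.margin)
                  for cid, c in target_cases.items()}

    target_ids = sorted(target_cases)
    if fold_split is None:
        fold_split = make_folds(target_ids, config.k_folds, config.seed)
    plan = select_supervised(fold_split, p, len(target_ids), config.seed + 1,
                             config.count_override)

    tables = []
    for fold_idx, (train_ids, val_ids) in enumerate(fold_split.folds):
        rng = np.random.default_rng(config.seed + 100 + fold_idx)
        trainer = _build_trainer(method, config, config.seed + 10 + fold_idx)
        train_stacks = {cid: tgt_stacks[cid] for cid in train_ids}
        supervised = set(plan.selected[fold_idx])
        for _ in range(config.steps):
            if method == "unet":
                sup_stacks = {cid: train_stacks[cid] for cid in supervised}
                batch = sample_batch(src_stacks, sup_stacks, supervised,
                                     config.batch_size, rng)
            else:
                batch = sample_batch(src_stacks, train_stacks, supervised,
                                     config.batch_size, rng)
            trainer.train_step(batch)
        for cid in val_ids:
            stack = tgt_stacks[cid]
            preds = trainer.predict_slices(stack.slices)
            pred_map = reassemble(stack, preds)
            if predictions_dir is not None:
                from .imaging_io import write_labels
                write_labels(pred_map, Path(predictions_dir) /
                             f"{method}_p{int(round(p * 100))}_{cid}_pred.nii.gz")
            tables.append(case_metrics(pred_map, target_cases[cid].labels,
                                       cid, method, p, fold_idx))
    return pd.concat(tables, ignore_index=True)


def experiment_grid(cohort: Cohort, config: RunConfig,
                    methods: tuple[str, ...] = ("gan", "vae", "unet"),
                    levels: tuple[float, ...] = SUPERVISION_LEVELS) -> pd.DataFrame:
    """The full method x supervision grid (UNet skips p=0): 11 cells by default."""
    tables = []
    for method in methods:
        for p in levels:
            if method == "unet" and p == 0:
                continue
            tables.append(run_experiment(method, p, cohort, config))
    return pd.concat(tables, ignore_index=True)
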