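"""3D segmentation metrics, volume agreement, and paired statistics.

Metrics are always computed in original-image space on reassembled label
maps, with distances in physical millimetres derived from the voxel
spacing. Conventions for degenerate inputs are centralised here: Dice is
1 when both masks are empty and 0 when exactly one is; ASD is undefined
(NaN, with a warning) when either surface is empty; Wilcoxon tests drop
zero differences and are reported as missing when fewer than two non-zero
differences remain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion, generate_binary_structure
from scipy.spatial import cKDTree
from scipy.stats import wilcoxon

from .core import CLASS_INDEX, FOREGROUND_LABELS, LabelMap

__all__ = [
    "dice3d", "asd", "volume_ml", "volume_agreement", "VolumeAgreement",
    "paired_wilcoxon", "WilcoxonResult", "case_metrics", "aggregate",
    "pairwise_comparisons", "significance_tier",
]


def _check_grids(pred: LabelMap, gt: LabelMap):
    if pred.shape != gt.shape:
        raise ValueError(f"grid mismatch: {pred.shape} vs {gt.shape}")
    if not np.allclose(pred.spacing, gt.spacing):
        raise ValueError(f"spacing mismatch: {pred.spacing} vs {gt.spacing}")


def dice3d(pred: LabelMap, gt: LabelMap, label: int) -> float:
    """Volumetric Dice 2|P∩G| / (|P|+|G|) for one label."""
    _check_grids(pred, gt)
    p = pred.values == label
    g = gt.values == label
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & g).sum()) / denom


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Border voxels under 6-connectivity: mask minus its erosion."""
    struct = generate_binary_structure(3, 1)
    interior = binary_erosion(mask, structure=struct, border_value=0)
    return np.argwhere(mask & ~interior)


def asd(pred: LabelMap, gt: LabelMap, label: int,
        spacing: tuple[float, float, float] | None = None) -> float:
    """Symmetric average surface distance in mm between two label masks.

    Surfaces are 6-connectivity border voxels; distances are Euclidean
    between voxel centres in physical coordinates, pooled over both
    surfaces. Returns NaN (with a warning) if either mask is empty.
    """
    _check_grids(pred, gt)
    spacing = np.asarray(spacing if spacing is not None else pred.spacing, dtype=float)
    p = pred.values == label
    g = gt.values == label
    if not p.any() or not g.any():
        warnings.warn(f"ASD undefined for label {label}: empty mask", stacklevel=2)
        return float("nan")
    sp = _surface_voxels(p) * spacing
    sg = _surface_voxels(g) * spacing
    d_pg, _ = cKDTree(sg).query(sp, k=1)
    d_gp, _ = cKDTree(sp).query(sg, k=1)
    return float((d_pg.sum() + d_gp.sum()) / (len(sp) + len(sg)))


def volume_ml(labels: LabelMap, label: int) -> float:
    """Structure volume in millilitres: voxel count x voxel volume (mm^3) / 1000."""
    voxel_mm3 = float(np.prod(labels.spacing))
    return int((labels.values == label).sum()) * voxel_mm3 / 1000.0


@dataclass
class VolumeAgreement:
    """Signed-difference statistics (gt - pred) in mL, as printed in agreement tables."""

    mean_signed_diff: float
    std_signed_diff: float
    rmse: float


def volume_agreement(pairs: list[tuple[float, float]]) -> VolumeAgreement:
    """Agreement between predicted and ground-truth volumes over cases.

    ``pairs`` is a list of (pred_vol, gt_vol); the signed difference is
    gt - pred per case; std is the sample standard deviation.
    """
    if len(pairs) == 0:
        raise ValueError("volume_agreement needs at least one (pred, gt) pair")
    pred = np.asarray([p for p, _ in pairs], dtype=float)
    gt = np.asarray([g for _, g in pairs], dtype=float)
    diff = gt - pred
    std = float(diff.std(ddof=1)) if len(diff) > 1 else 0.0
    return VolumeAgreement(float(diff.mean()), std, float(np.sqrt((diff**2).mean())))


# ---------------------------------------------------------------------------
# Paired statistics
# ---------------------------------------------------------------------------

@dataclass
class WilcoxonResult:
    p_value: float  # NaN when undefined
    n_used: int
    n_zeros_dropped: int
    tier: str  # "p<=1e-3", "p<=5e-2" or "ns"
    note: str = ""


def significance_tier(p: float) -> str:
    if np.isnan(p):
        return "ns"
    if p <= 1e-3:
        return "p<=1e-3"
    if p <= 5e-2:
        return "p<=5e-2"
    return "ns"


def paired_wilcoxon(scores_a, scores_b) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired per-case scores.

    Exact null distribution for n <= 25 non-zero differences, normal
    approximation above; zero differences are dropped and reported.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diff = a - b
    nz = diff[diff != 0]
    n_zeros = len(diff) - len(nz)
    if len(nz) < 2:
        return WilcoxonResult(float("nan"), len(nz), n_zeros, "ns",
                              "fewer than 2 non-zero differences; test undefined")
    method = "exact" if len(nz) <= 25 else "approx"
    res = wilcoxon(nz, zero_method="wilcox", alternative="two-sided", method=method)
    p = float(res.pvalue)
    note = f"{n_zeros} zero difference(s) dropped" if n_zeros else ""
    return WilcoxonResult(p, len(nz), n_zeros, significance_tier(p), note)


# ---------------------------------------------------------------------------
# Per-case metrics and aggregation
# ---------------------------------------------------------------------------

def case_metrics(pred: LabelMap, gt: LabelMap, case_id: str, method: str,
                 supervision: float, fold: int) -> pd.DataFrame:
    """One MetricsTable row per foreground label for a single case."""
    rows = []
    for label in FOREGROUND_LABELS:
        rows.append({
            "case_id": case_id, "method": method, "supervision": supervision,
            "fold": fold, "label": CLASS_INDEX[label],
            "dice": dice3d(pred, gt, label),
            "asd_mm": asd(pred, gt, label),
            "pred_vol_ml": volume_ml(pred, label),
            "gt_vol_ml": volume_ml(gt, label),
        })
    return pd.DataFrame(rows)


def aggregate(tables: list[pd.DataFrame] | pd.DataFrame) -> pd.DataFrame:
    """Mean +/- std Dice and ASD per (method, supervision, label), pooled over folds."""
    table = pd.concat(tables, ignore_index=True) if isinstance(tables, list) else tables
    required = {"method", "supervision", "label", "dice", "asd_mm"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"metrics table missing columns: {sorted(missing)}")
    out = (table.groupby(["method", "supervision", "label"], sort=True)
           .agg(dice_mean=("dice", "mean"), dice_std=("dice", "std"),
                asd_mean=("asd_mm", "mean"), asd_std=("asd_mm", "std"),
                n_cases=("dice", "size"))
           .reset_index())
    return out.fillna({"dice_std": 0.0, "asd_std": 0.0})


def pairwise_comparisons(table: pd.DataFrame, by: str = "supervision",
                         metric: str = "dice") -> pd.DataFrame:
    """Per-label paired Wilcoxon tests between all level pairs of ``by``.

    Cases are paired by case_id (each case scored once, in its validation
    fold). ``by`` is 'supervision' (within a method) or 'method' (within a
    supervision level); remaining grouping columns are iterated over.
    """
    if by not in ("supervision", "method"):
        raise ValueError("by must be 'supervision' or 'method'")
    other = "method" if by == "supervision" else "supervision"
    rows = []
    for (other_val, label), sub in table.groupby([other, "label"]):
        levels = sorted(sub[by].unique())
        for i, la in enumerate(levels):
            for lb in levels[i + 1:]:
                wide = sub.pivot_table(index="case_id", columns=by, values=metric)
                if la not in wide.columns or lb not in wide.columns:
                    continue
                pair = wide[[la, lb]].dropna()
                res = paired_wilcoxon(pair[la].to_numpy(), pair[lb].to_numpy())
                rows.append({other: other_val, "label": label,
                             f"{by}_a": la, f"{by}_b": lb,
                             "p_value": res.p_value, "tier": res.tier,
                             "n_pairs": res.n_used, "note": res.note})
    return pd.DataFrame(rows)
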