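"""Metric correctness against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardioda.core import LabelMap
from cardioda.evaluation import (
    aggregate,
    asd,
    dice3d,
    paired_wilcoxon,
    pairwise_comparisons,
    significance_tier,
    volume_agreement,
    volume_ml,
)


def _lm(arr, spacing=(1.0, 1.0, 1.0)):
    return LabelMap(np.asarray(arr, dtype=np.int16), spacing)


# -- brute-force oracles --------------------------------------------------------

def brute_dice(p: np.ndarray, g: np.ndarray) -> float:
    inter = sum(1 for idx in np.ndindex(p.shape) if p[idx] and g[idx])
    tot = int(p.sum()) + int(g.sum())
    return 1.0 if tot == 0 else 2.0 * inter / tot


def brute_surface(mask: np.ndarray) -> list:
    """6-connectivity border voxels by explicit neighbour checks."""
    out = []
    for idx in np.argwhere(mask):
        x, y, z = idx
        for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            nx, ny, nz = x + dx, y + dy, z + dz
            if (not (0 <= nx < mask.shape[0] and 0 <= ny < mask.shape[1]
                     and 0 <= nz < mask.shape[2])) or not mask[nx, ny, nz]:
                out.append((x, y, z))
                break
    return out


def brute_asd(p: np.ndarray, g: np.ndarray, spacing) -> float:
    sp = np.asarray(brute_surface(p), dtype=float) * spacing
    sg = np.asarray(brute_surface(g), dtype=float) * spacing
    d1 = [min(np.sqrt(((a - b) ** 2).sum()) for b in sg) for a in sp]
    d2 = [min(np.sqrt(((a - b) ** 2).sum()) for b in sp) for a in sg]
    return (sum(d1) + sum(d2)) / (len(d1) + len(d2))


# -- Dice ------------------------------------------------------------------------

def test_dice_identical_and_disjoint():
    a = np.zeros((4, 4, 4), dtype=np.int16)
    a[:2] = 1
    b = np.zeros((4, 4, 4), dtype=np.int16)
    b[2:] = 1
    assert dice3d(_lm(a), _lm(a), 1) == 1.0
    assert dice3d(_lm(a), _lm(b), 1) == 0.0


def test_dice_half_overlap():
    p = np.zeros((4, 4, 4), dtype=np.int16)
    g = np.zeros((4, 4, 4), dtype=np.int16)
    p[0, 0, :4] = 1          # |P| = 4
    g[0, 0, 2:4] = 1         # overlap 2
    g[0, 1, :2] = 1          # |G| = 4
    assert dice3d(_lm(p), _lm(g), 1) == 0.5


def test_dice_empty_mask_conventions():
    z = np.zeros((3, 3, 3), dtype=np.int16)
    o = z.copy()
    o[1, 1, 1] = 1
    assert dice3d(_lm(z), _lm(z), 1) == 1.0
    assert dice3d(_lm(o), _lm(z), 1) == 0.0


def test_dice_grid_mismatch_rejected():
    with pytest.raises(ValueError, match="mismatch"):
        dice3d(_lm(np.zeros((3, 3, 3), dtype=int)), _lm(np.zeros((4, 4, 4), dtype=int)), 1)


# -- ASD -------------------------------------------------------------------------

def test_asd_identical_masks_zero():
    a = np.zeros((5, 5, 5), dtype=np.int16)
    a[1:4, 1:4, 1:4] = 1
    assert asd(_lm(a), _lm(a), 1) == 0.0


def test_asd_single_voxels_respect_spacing():
    p = np.zeros((3, 3, 5), dtype=np.int16)
    g = np.zeros((3, 3, 5), dtype=np.int16)
    p[1, 1, 1] = 1
    g[1, 1, 2] = 1
    spacing = (1.0, 1.0, 3.0)
    assert asd(_lm(p, spacing), _lm(g, spacing), 1) == pytest.approx(3.0)


def test_asd_empty_mask_is_missing():
    a = np.zeros((3, 3, 3), dtype=np.int16)
    b = a.copy()
    b[0, 0, 0] = 1
    with pytest.warns(UserWarning, match="empty"):
        assert np.isnan(asd(_lm(a), _lm(b), 1))


@pytest.mark.parametrize("seed", range(6))
def test_metrics_match_bruteforce_oracles(seed):
    rng = np.random.default_rng(seed)
    spacing = tuple(rng.uniform(0.5, 3.0, 3))
    p = (rng.random((10, 10, 10)) < 0.15).astype(np.int16)
    g = (rng.random((10, 10, 10)) < 0.15).astype(np.int16)
    lp, lg = _lm(p, spacing), _lm(g, spacing)
    assert dice3d(lp, lg, 1) == pytest.approx(brute_dice(p > 0, g > 0), abs=1e-12)
    assert asd(lp, lg, 1) == pytest.approx(brute_asd(p > 0, g > 0, spacing), abs=1e-9)


# -- volumes ---------------------------------------------------------------------

def test_volume_ml_unit_conversion():
    arr = np.zeros((10, 10, 10), dtype=np.int16)
    arr[:, :, :] = 1
    assert volume_ml(_lm(arr), 1) == pytest.approx(1.0)  # 1000 voxels at 1 mm^3
    assert volume_ml(_lm(arr), 2) == 0.0
    assert volume_ml(_lm(arr, (1, 1, 2)), 1) == pytest.approx(2.0)


def test_volume_agreement_hand_values():
    # gt - pred differences {3, -1, 2}
    pairs = [(0.0, 3.0), (1.0, 0.0), (0.0, 2.0)]
    va = volume_agreement(pairs)
    assert va.mean_signed_diff == pytest.approx(4 / 3)
    assert va.rmse == pytest.approx(np.sqrt(14 / 3))
    assert va.std_signed_diff == pytest.approx(np.std([3, -1, 2], ddof=1))


def test_volume_agreement_all_zero():
    va = volume_agreement([(1.0, 1.0), (2.0, 2.0)])
    assert va.mean_signed_diff == 0.0 and va.std_signed_diff == 0.0 and va.rmse == 0.0


@settings(deadline=None, max_examples=100)
@given(st.lists(st.tuples(st.floats(0, 300), st.floats(0, 300)), min_size=1, max_size=20))
def test_rmse_dominates_mean(pairs):
    va = volume_agreement(pairs)
    assert va.rmse >= abs(va.mean_signed_diff) - 1e-9


# -- Wilcoxon --------------------------------------------------------------------

def test_wilcoxon_identical_samples_missing():
    res = paired_wilcoxon([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert np.isnan(res.p_value)
    assert "non-zero" in res.note


def test_wilcoxon_three_negative_diffs_exact_quarter():
    """All three differences are -1; enumerating the 2^3 sign assignments
    gives two-sided p = 2/8 = 0.25."""
    res = paired_wilcoxon([1, 2, 3], [2, 3, 4])
    assert res.p_value == pytest.approx(0.25)
    assert res.n_used == 3


def test_wilcoxon_symmetry():
    a = [0.5, 0.7, 0.9, 0.4, 0.8]
    b = [0.6, 0.6, 0.95, 0.5, 0.7]
    assert paired_wilcoxon(a, b).p_value == pytest.approx(paired_wilcoxon(b, a).p_value)


def test_significance_tiers():
    assert significance_tier(0.0005) == "p<=1e-3"
    assert significance_tier(0.01) == "p<=5e-2"
    assert significance_tier(0.2) == "ns"


# -- aggregation -----------------------------------------------------------------

def _toy_table():
    import pandas as pd
    rows = []
    for cid, d in [("a", 0.8), ("b", 0.9)]:
        rows.append({"case_id": cid, "method": "gan", "supervision": 0.3, "fold": 0,
                     "label": "LV", "dice": d, "asd_mm": 1.0,
                     "pred_vol_ml": 10.0, "gt_vol_ml": 11.0})
    return pd.DataFrame(rows)


def test_aggregate_mean_and_row_order_invariance():
    t = _toy_table()
    s1 = aggregate(t)
    s2 = aggregate(t.iloc[::-1].reset_index(drop=True))
    assert s1["dice_mean"].iloc[0] == pytest.approx(0.85)
    num = s1.select_dtypes("number")
    assert np.allclose(num.to_numpy(), s2[num.columns].to_numpy())
    assert (s1[["method", "label"]].to_numpy() == s2[["method", "label"]].to_numpy()).all()


def test_aggregate_single_case_std_zero():
    t = _toy_table().iloc[:1]
    s = aggregate(t)
    assert s["dice_std"].iloc[0] == 0.0
    assert s["n_cases"].iloc[0] == 1


def test_pairwise_comparisons_structure():
    import pandas as pd
    rows = []
    rng = np.random.default_rng(1)
    for p_level, shift in [(0.0, 0.0), (0.3, 0.2)]:
        for i in range(8):
            rows.append({"case_id": f"c{i}", "method": "gan", "supervision": p_level,
                         "fold": 0, "label": "LV",
                         "dice": float(np.clip(0.5 + shift + rng.normal(0, 0.02), 0, 1)),
                         "asd_mm": 1.0, "pred_vol_ml": 1, "gt_vol_ml": 1})
    table = pd.DataFrame(rows)
    out = pairwise_comparisons(table, by="supervision")
    assert len(out) == 1
    assert out["p_value"].iloc[0] <= 0.05
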