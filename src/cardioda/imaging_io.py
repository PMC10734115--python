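"""Volume I/O and preprocessing.

Implements the preprocessing pipeline the segmentation branches expect:
a heart-centred in-plane crop (from the foreground-label centroid), per-slice
resizing to the branch's input size, branch-specific intensity normalisation
([-1, 1] per axial slice for the adversarial branch, per-volume
standardisation for the variational branch and the UNet), extraction of
axial 2D slice stacks, and exact reassembly of per-slice predictions back
into the original 3D grid so that all metrics are computed with true
physical spacing.

Coordinate conventions: voxel indices are 0-based; arrays are (x, y, z)
with axial slices taken along the last axis; crop boxes are half-open
[lo, hi).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from skimage.transform import resize as _sk_resize

from .core import CLASS_INDEX, LabelMap, Volume3D

__all__ = [
    "read_volume", "read_labels", "write_volume", "write_labels",
    "crop_to_heart", "resize_slice", "scale_minus1_1", "standardize",
    "extract_axial", "reassemble", "CropGeometry", "SliceStack",
    "preprocess_case",
]

IDENTITY_REMAP = {k: k for k in CLASS_INDEX}


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _spacing_from_header(img) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)


def read_volume(path: str | Path, domain: str = "source") -> Volume3D:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got ndim={data.ndim}")
    return Volume3D(data.astype(np.float32), _spacing_from_header(img), domain)


def read_labels(path: str | Path, value_remap: dict[int, int] | None = None) -> LabelMap:
    """Read an integer label image, remapping on-disk codes to class indices 0-6."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D label image, got ndim={data.ndim}")
    data = np.rint(data).astype(np.int32)
    remap = IDENTITY_REMAP if value_remap is None else value_remap
    present = set(np.unique(data).tolist())
    unknown = present - set(remap)
    if unknown:
        raise ValueError(f"{path}: on-disk label code(s) {sorted(unknown)} absent from value_remap")
    lut = np.zeros(max(remap) + 1, dtype=np.int16)
    for code, cls in remap.items():
        lut[code] = cls
    return LabelMap(lut[data], _spacing_from_header(img))


def _affine(spacing) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def write_volume(vol: Volume3D, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(vol.values.astype(np.float32), _affine(vol.spacing)), str(path))
    return path


def write_labels(labels: LabelMap, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(labels.values.astype(np.int16), _affine(labels.spacing)), str(path))
    return path


# ---------------------------------------------------------------------------
# Geometry: crop, resize, normalise
# ---------------------------------------------------------------------------

@dataclass
class CropGeometry:
    """Everything needed to map cropped/resized slices back to the original grid."""

    orig_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    box: tuple[int, int, int, int]  # (x0, x1, y0, y1), half-open
    out_xy: int

    @property
    def crop_shape(self) -> tuple[int, int]:
        x0, x1, y0, y1 = self.box
        return (x1 - x0, y1 - y0)

    @property
    def resize_factor(self) -> float:
        return self.out_xy / self.crop_shape[0]

    def to_dict(self) -> dict:
        return {
            "orig_shape": list(self.orig_shape),
            "spacing": list(self.spacing),
            "box": list(self.box),
            "out_xy": self.out_xy,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CropGeometry":
        return cls(tuple(d["orig_shape"]), tuple(d["spacing"]), tuple(d["box"]), d["out_xy"])


def _axis_box(center: int, extent: int, size: int) -> tuple[int, int]:
    """Half-open interval of length <= extent centred on `center`, clamped to [0, size)."""
    lo = center - extent // 2
    lo = max(0, min(lo, size - extent))
    lo = max(0, lo)
    hi = min(size, lo + extent)
    return lo, hi


def crop_to_heart(vol: Volume3D, labels: LabelMap, out_xy: int,
                  margin: int | None = None) -> tuple[Volume3D, LabelMap, CropGeometry]:
    """In-plane crop centred on the foreground-label centroid.

    With ``margin=None`` the crop extent equals ``out_xy`` (no resizing
    needed downstream); otherwise the extent covers the foreground
    bounding box plus ``margin`` voxels on each side and the slices are
    later resized to ``out_xy``.
    """
    fg = labels.values > 0
    if not fg.any():
        raise ValueError("cannot crop: label map has no foreground voxels")
    coords = np.argwhere(fg)
    cx, cy = (int(round(c)) for c in coords[:, :2].mean(axis=0))
    if margin is None:
        extent = out_xy
    else:
        bbox_x = coords[:, 0].max() - coords[:, 0].min() + 1
        bbox_y = coords[:, 1].max() - coords[:, 1].min() + 1
        extent = int(max(bbox_x, bbox_y)) + 2 * int(margin)
    nx, ny, _ = vol.shape
    x0, x1 = _axis_box(cx, extent, nx)
    y0, y1 = _axis_box(cy, extent, ny)
    geom = CropGeometry(vol.shape, vol.spacing, (x0, x1, y0, y1), out_xy)
    cvol = Volume3D(vol.values[x0:x1, y0:y1, :], vol.spacing, vol.domain)
    clab = LabelMap(labels.values[x0:x1, y0:y1, :], labels.spacing)
    return cvol, clab, geom


def resize_slice(slice2d: np.ndarray, out_size: int, kind: str = "intensity") -> np.ndarray:
    """Resize a 2D slice: linear interpolation for intensities, nearest for labels."""
    slice2d = np.asarray(slice2d)
    if slice2d.shape == (out_size, out_size):
        return slice2d.copy()
    if kind == "label":
        out = _sk_resize(slice2d.astype(np.float32), (out_size, out_size), order=0,
                         anti_aliasing=False, preserve_range=True)
        return np.rint(out).astype(slice2d.dtype)
    if kind != "intensity":
        raise ValueError(f"kind must be 'intensity' or 'label', got {kind!r}")
    out = _sk_resize(slice2d.astype(np.float32), (out_size, out_size), order=1,
                     anti_aliasing=False, preserve_range=True)
    return out.astype(np.float32)


def scale_minus1_1(slice2d: np.ndarray) -> np.ndarray:
    """Affine per-slice rescale to [-1, 1]; a constant slice maps to all zeros."""
    slice2d = np.asarray(slice2d, dtype=np.float32)
    lo, hi = float(slice2d.min()), float(slice2d.max())
    if hi == lo:
        return np.zeros_like(slice2d)
    return (2.0 * (slice2d - lo) / (hi - lo) - 1.0).astype(np.float32)


def standardize(vol: Volume3D) -> Volume3D:
    """Whole-volume zero-mean / unit-std normalisation."""
    mean = float(vol.values.mean())
    std = float(vol.values.std())
    if std == 0:
        raise ValueError("cannot standardize a constant volume (zero std)")
    out = (vol.values.astype(np.float64) - mean) / std
    return Volume3D(out.astype(np.float32), vol.spacing, vol.domain)


# ---------------------------------------------------------------------------
# Axial slice stacks
# ---------------------------------------------------------------------------

@dataclass
class SliceStack:
    """Ordered axial 2D slices plus the geometry to invert the preprocessing."""

    slices: np.ndarray  # (Z, H, W) float32
    geometry: CropGeometry
    label_slices: np.ndarray | None = None  # (Z, H, W) int16
    normalization: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.slices.ndim != 3:
            raise ValueError("slices must be a (Z, H, W) array")
        if self.label_slices is not None and self.label_slices.shape != self.slices.shape:
            raise ValueError("label slices must align with intensity slices")

    def __len__(self) -> int:
        return self.slices.shape[0]


def extract_axial(vol: Volume3D, labels: LabelMap | None, geometry: CropGeometry,
                  out_size: int | None = None) -> SliceStack:
    """Slice a (cropped) volume along z, resizing in-plane to ``out_size``."""
    out_size = out_size or geometry.out_xy
    z = vol.shape[2]
    imgs = np.stack([resize_slice(vol.values[:, :, k], out_size, "intensity")
                     for k in range(z)])
    labs = None
    if labels is not None:
        labs = np.stack([resize_slice(labels.values[:, :, k], out_size, "label")
                         for k in range(z)]).astype(np.int16)
    return SliceStack(imgs.astype(np.float32), geometry, labs)


def reassemble(stack: SliceStack, per_slice_predictions: list[np.ndarray] | np.ndarray) -> LabelMap:
    """Map per-slice label predictions back into the original 3D grid.

    Inverts the in-plane resize with nearest-neighbour interpolation and
    pastes each slice into its crop box; voxels outside the box are
    background.
    """
    preds = np.asarray(per_slice_predictions)
    if preds.shape[0] != len(stack):
        raise ValueError(
            f"prediction count {preds.shape[0]} does not match slice count {len(stack)}")
    geom = stack.geometry
    x0, x1, y0, y1 = geom.box
    cw = x1 - x0
    out = np.zeros(geom.orig_shape, dtype=np.int16)
    for k in range(preds.shape[0]):
        sl = preds[k].astype(np.int16)
        if sl.shape != (cw, y1 - y0):
            sl = np.rint(
                _sk_resize(sl.astype(np.float32), (cw, y1 - y0), order=0,
                           anti_aliasing=False, preserve_range=True)
            ).astype(np.int16)
        out[x0:x1, y0:y1, k] = sl
    return LabelMap(out, geom.spacing)


# ---------------------------------------------------------------------------
# Per-branch preprocessing pipeline
# ---------------------------------------------------------------------------

def preprocess_case(vol: Volume3D, labels: LabelMap, branch: str, out_xy: int,
                    margin: int | None = None) -> SliceStack:
    """Crop around the heart, slice axially and normalise for one branch.

    ``branch='gan'`` rescales each axial slice to [-1, 1]; ``'vae'`` and
    ``'unet'`` standardise the whole volume before slicing.
    """
    if branch not in ("gan", "vae", "unet"):
        raise ValueError(f"unknown branch {branch!r}")
    cvol, clab, geom = crop_to_heart(vol, labels, out_xy, margin)
    if branch in ("vae", "unet"):
        cvol = standardize(cvol)
    stack = extract_axial(cvol, clab, geom, out_xy)
    if branch == "gan":
        stack.slices = np.stack([scale_minus1_1(s) for s in stack.slices])
        stack.normalization = {"kind": "minmax_slice", "range": [-1.0, 1.0]}
    else:
        stack.normalization = {"kind": "standardize_volume"}
    return stack
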