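"""Synthetic two-domain cardiac phantom cohorts.

Generates desk-scale stand-ins for a cross-modality whole-heart study:
one shared anatomy model (nested ellipsoids for the ventricles and atria,
a myocardial shell, and a tube for the ascending aorta, warped by a smooth
random displacement field) rendered under two appearance models. The
``source`` domain mimics CT angiography (high-contrast intensity plateaus,
low noise, no shading); the ``target`` domain mimics b-SSFP MR angiography
(compressed contrast, higher noise, smooth multiplicative bias field).
This is qualitative appearance modelling only — no imaging physics.

All data are synthetic; every generated label map contains the six
foreground structures (LV, MYO, RV, LA, RA, AA).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates

from .core import FOREGROUND_LABELS, Case, Cohort, LabelMap, Volume3D
from .imaging_io import write_labels, write_volume

__all__ = [
    "DomainAppearance", "PhantomSpec", "generate_phantom", "generate_cohort",
    "write_cohort", "default_phantom_spec",
]


@dataclass
class DomainAppearance:
    """Per-label intensity plateaus plus noise and bias-field settings."""

    plateaus: dict[int, float]
    noise_sd: float = 0.0
    bias_amplitude: float = 0.0

    def __post_init__(self):
        if self.noise_sd < 0 or self.bias_amplitude < 0:
            raise ValueError("noise_sd and bias_amplitude must be non-negative")
        missing = set(range(7)) - set(self.plateaus)
        if missing:
            raise ValueError(f"plateaus missing for labels {sorted(missing)}")
        vals = list(self.plateaus.values())
        if len(set(vals)) != len(vals):
            raise ValueError("plateau values must be distinct within a domain")


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (64, 64, 16)
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.0)
    anatomy_seed: int = 0
    deformation_amplitude: float = 1.5  # voxels
    appearance: dict[str, DomainAppearance] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(int(s) < 16 for s in self.grid_shape):
            raise ValueError(f"grid_shape entries must be >= 16, got {self.grid_shape}")
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacings must be positive")
        if self.deformation_amplitude < 0:
            raise ValueError("deformation_amplitude must be non-negative")
        if not self.appearance:
            self.appearance = _default_appearances()


def _default_appearances() -> dict[str, DomainAppearance]:
    # CT-like: wide plateau spread, near-noiseless, uniform illumination.
    ct = DomainAppearance(
        plateaus={0: 0.00, 1: 0.90, 2: 0.35, 3: 0.80, 4: 0.70, 5: 0.60, 6: 1.00},
        noise_sd=0.01, bias_amplitude=0.0,
    )
    # MR-like: compressed contrast, brighter background, noise + shading.
    mr = DomainAppearance(
        plateaus={0: 0.10, 1: 0.55, 2: 0.72, 3: 0.30, 4: 0.62, 5: 0.22, 6: 0.46},
        noise_sd=0.04, bias_amplitude=0.20,
    )
    return {"source": ct, "target": mr}


def default_phantom_spec(**overrides) -> PhantomSpec:
    """A PhantomSpec with the package's CT-like / MR-like appearance defaults."""
    return PhantomSpec(**overrides)


# ---------------------------------------------------------------------------
# Anatomy
# ---------------------------------------------------------------------------

# (label, centre, radii) in normalised [-1, 1] coordinates. MYO is painted as
# an outer ellipsoid first, then the LV pool overwrites its interior, leaving
# a shell. The aorta is a tube along z painted last.
_ELLIPSOIDS = [
    (2, (-0.35, -0.30, 0.0), (0.40, 0.40, 0.75)),  # MYO outer envelope
    (1, (-0.35, -0.30, 0.0), (0.25, 0.25, 0.55)),  # LV blood pool
    (3, (0.38, -0.32, 0.0), (0.24, 0.24, 0.55)),   # RV
    (4, (-0.38, 0.42, 0.0), (0.22, 0.20, 0.48)),   # LA
    (5, (0.40, 0.42, 0.0), (0.22, 0.20, 0.48)),    # RA
]
_AA_CENTER, _AA_RADIUS, _AA_ZEXTENT = (0.02, 0.12), 0.13, 0.85


def _base_labels(shape: tuple[int, int, int]) -> np.ndarray:
    nx, ny, nz = shape
    x = np.linspace(-1, 1, nx)[:, None, None]
    y = np.linspace(-1, 1, ny)[None, :, None]
    z = np.linspace(-1, 1, nz)[None, None, :]
    lab = np.zeros(shape, dtype=np.int16)
    for label, (cx, cy, cz), (rx, ry, rz) in _ELLIPSOIDS:
        mask = ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0
        lab[mask] = label
    tube = (((x - _AA_CENTER[0]) / _AA_RADIUS) ** 2
            + ((y - _AA_CENTER[1]) / _AA_RADIUS) ** 2 <= 1.0) & (np.abs(z) <= _AA_ZEXTENT)
    lab[np.broadcast_to(tube, shape)] = 6
    return lab


def _deform_labels(lab: np.ndarray, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    if amplitude == 0:
        return lab
    shape = lab.shape
    disp = []
    for _ in range(3):
        f = gaussian_filter(rng.standard_normal(shape), sigma=4.0)
        peak = np.abs(f).max()
        disp.append(f / peak * amplitude if peak > 0 else f)
    grid = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    coords = [g + d for g, d in zip(grid, disp)]
    return map_coordinates(lab, coords, order=0, mode="nearest").astype(np.int16)


def _bias_field(shape: tuple[int, int, int], amplitude: float,
                rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative shading: 1 + amplitude * sum of low-order cosines."""
    if amplitude == 0:
        return np.ones(shape, dtype=np.float32)
    nx, ny, nz = shape
    x = np.linspace(0, np.pi, nx)[:, None, None]
    y = np.linspace(0, np.pi, ny)[None, :, None]
    z = np.linspace(0, np.pi, nz)[None, None, :]
    phases = rng.uniform(0, 2 * np.pi, size=3)
    b = (np.cos(x + phases[0]) + np.cos(y + phases[1]) + np.cos(z + phases[2])) / 3.0
    return (1.0 + amplitude * b).astype(np.float32)


def _noise_seed(anatomy_seed: int, domain: str) -> int:
    h = hashlib.sha256(f"{anatomy_seed}:{domain}".encode()).digest()
    return int.from_bytes(h[:4], "little")


def generate_phantom(spec: PhantomSpec, domain: str) -> tuple[Volume3D, LabelMap]:
    """Render one phantom case for the given domain.

    The label geometry depends only on ``spec.anatomy_seed`` (identical
    across domains); plateaus, bias and noise come from the domain's
    appearance model.
    """
    if domain not in spec.appearance:
        raise ValueError(f"no appearance defined for domain {domain!r}")
    anat_rng = np.random.default_rng(spec.anatomy_seed)
    lab = _deform_labels(_base_labels(spec.grid_shape), spec.deformation_amplitude, anat_rng)
    present = set(np.unique(lab).tolist())
    missing = [l for l in FOREGROUND_LABELS if l not in present]
    if missing:
        raise ValueError(
            f"grid {spec.grid_shape} too small/deformed to contain structures {missing}")

    app = spec.appearance[domain]
    lut = np.zeros(7, dtype=np.float32)
    for label, plateau in app.plateaus.items():
        lut[label] = plateau
    img = lut[lab]
    noise_rng = np.random.default_rng(_noise_seed(spec.anatomy_seed, domain))
    img = img * _bias_field(spec.grid_shape, app.bias_amplitude, noise_rng)
    if app.noise_sd > 0:
        img = img + noise_rng.normal(0, app.noise_sd, size=img.shape).astype(np.float32)
    return (Volume3D(img.astype(np.float32), spec.spacing, domain),
            LabelMap(lab, spec.spacing))


def generate_cohort(spec: PhantomSpec, n_source: int, n_target: int,
                    paired: bool = False, seed: int = 0) -> Cohort:
    """Draw a two-domain cohort; paired mode reuses anatomy seeds across domains."""
    if n_source < 1 or n_target < 1:
        raise ValueError("need at least one case per domain")
    rng = np.random.default_rng(seed)
    src_seeds = rng.integers(0, 2**31 - 1, size=n_source)
    tgt_seeds = src_seeds[:n_target].copy() if paired else rng.integers(
        0, 2**31 - 1, size=n_target)
    if paired and n_target > n_source:
        extra = rng.integers(0, 2**31 - 1, size=n_target - n_source)
        tgt_seeds = np.concatenate([tgt_seeds, extra])
    cases: list[Case] = []
    for i, s in enumerate(src_seeds):
        vol, lab = generate_phantom(replace(spec, anatomy_seed=int(s)), "source")
        cases.append(Case(f"src_{i:03d}", "source", vol, lab))
    for i, s in enumerate(tgt_seeds):
        vol, lab = generate_phantom(replace(spec, anatomy_seed=int(s)), "target")
        cases.append(Case(f"tgt_{i:03d}", "target", vol, lab))
    return Cohort(cases, paired=paired)


def write_cohort(cohort: Cohort, out_dir) -> pd.DataFrame:
    """Write volumes/labels as NIfTI and return (and save) the manifest."""
    from pathlib import Path

    out_dir = Path(out_dir)
    rows = []
    for case in cohort.cases:
        img_path = out_dir / f"{case.case_id}_image.nii.gz"
        lab_path = out_dir / f"{case.case_id}_labels.nii.gz"
        write_volume(case.volume, img_path)
        write_labels(case.labels, lab_path)
        rows.append({"case_id": case.case_id, "domain": case.domain,
                     "image": img_path.name, "labels": lab_path.name})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
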