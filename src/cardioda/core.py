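"""Core domain containers shared across the package.

A whole-heart scene is a 3D intensity volume plus an aligned integer label
map over seven classes: background and six cardiac structures — left
ventricle blood pool (LV), left-ventricular myocardium (MYO), right
ventricle (RV), left atrium (LA), right atrium (RA) and ascending aorta
(AA). Volumes carry per-axis voxel spacing in millimetres and a domain tag
(``source`` for the CT-like modality, ``target`` for the MR-like one).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CLASS_INDEX: dict[int, str] = {
    0: "BG", 1: "LV", 2: "MYO", 3: "RV", 4: "LA", 5: "RA", 6: "AA",
}
FOREGROUND_LABELS: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
N_CLASSES = 7
DOMAINS = ("source", "target")


@dataclass
class Volume3D:
    """Anisotropic 3D intensity grid with physical spacing and a domain tag."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    domain: str = "source"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")
        if self.domain not in DOMAINS:
            raise ValueError(f"domain must be one of {DOMAINS}, got {self.domain!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class LabelMap:
    """Integer label grid aligned 1:1 with a Volume3D, values in 0..6."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    class_index: dict[int, str] = field(default_factory=lambda: dict(CLASS_INDEX))

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("label map must hold integers")
        self.values = self.values.astype(np.int16)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.values.ndim}")
        bad = set(np.unique(self.values)) - set(self.class_index)
        if bad:
            raise ValueError(f"label values outside the class index: {sorted(bad)}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.values, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


@dataclass
class Case:
    """One patient scan: id, imaging domain, volume and aligned labels."""

    case_id: str
    domain: str
    volume: Volume3D
    labels: LabelMap

    def __post_init__(self):
        if self.volume.shape != self.labels.shape:
            raise ValueError("volume and labels must share a grid")


@dataclass
class Cohort:
    """A two-domain study population, optionally anatomy-paired across domains."""

    cases: list[Case]
    paired: bool = False

    def __post_init__(self):
        for domain in DOMAINS:
            ids = [c.case_id for c in self.cases if c.domain == domain]
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicate case_ids in domain {domain!r}")

    def by_domain(self, domain: str) -> list[Case]:
        return [c for c in self.cases if c.domain == domain]

    def case_ids(self, domain: str) -> list[str]:
        return [c.case_id for c in self.by_domain(domain)]
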