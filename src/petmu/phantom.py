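"""Synthetic phantoms: tissue tables, geometric specs, and ground-truth volumes.

A phantom stands in for a patient: a body-like outline of water-based soft
tissue containing lung, fat, bone (with marrow) compartments and hot lesions.
Each tissue carries a linear attenuation coefficient (LAC, cm^-1) at the four
energies relevant to LSO-background transmission imaging (88, 202, 307 keV,
the Lu-176 gamma lines) and PET (511 keV), plus an activity concentration.

LAC defaults are derived from published photon mass-attenuation coefficients
(log-log interpolation of standard tables for water, adipose tissue and
cortical bone, times an assumed density); ``scripts/derive_tissue_lacs.py``
regenerates them. At 511 keV the defaults fall inside the segmentation ranges
used by the evaluation module: fat 0.080-0.090, water-based soft tissue
0.090-0.105, bone > 0.105 cm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import yaml

from .core import ConfigurationError, ValidationError, VoxelVolume, substream

ENERGIES_KEV = (88.0, 202.0, 307.0, 511.0)


@dataclass(frozen=True)
class Tissue:
    """LAC (cm^-1) per energy and activity concentration (Bq/mL)."""

    lac: Dict[float, float]
    activity_bq_ml: float = 0.0


@dataclass
class TissueTable:
    tissues: Dict[str, Tissue]

    def __post_init__(self):
        for name, t in self.tissues.items():
            energies = sorted(t.lac)
            vals = [t.lac[e] for e in energies]
            if any(v < 0 for v in vals):
                raise ValidationError(f"negative LAC for tissue {name!r}")
            # attenuation decreases with energy over 88-511 keV
            if any(a < b - 1e-12 for a, b in zip(vals, vals[1:])):
                raise ValidationError(
                    f"LAC of {name!r} must be non-increasing with energy")
        air = self.tissues.get("air")
        if air is not None and any(v != 0 for v in air.lac.values()):
            raise ValidationError("air LAC must be zero at all energies")

    def lac(self, tissue: str, energy_kev: float) -> float:
        if tissue not in self.tissues:
            raise ConfigurationError(f"unknown tissue {tissue!r}")
        t = self.tissues[tissue]
        if energy_kev not in t.lac:
            raise ConfigurationError(f"no LAC for {tissue!r} at {energy_kev} keV")
        return t.lac[energy_kev]

    def activity(self, tissue: str) -> float:
        if tissue not in self.tissues:
            raise ConfigurationError(f"unknown tissue {tissue!r}")
        return self.tissues[tissue].activity_bq_ml

    @property
    def names(self) -> List[str]:
        return list(self.tissues)

    def to_dict(self) -> dict:
        return {
            name: {"lac": {str(e): float(v) for e, v in t.lac.items()},
                   "activity_bq_ml": float(t.activity_bq_ml)}
            for name, t in self.tissues.items()
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TissueTable":
        return cls({
            name: Tissue({float(e): float(v) for e, v in spec["lac"].items()},
                         float(spec.get("activity_bq_ml", 0.0)))
            for name, spec in d.items()
        })


# LACs in cm^-1 at (88, 202, 307, 511) keV. Values derived from standard
# photon cross-section tables; see scripts/derive_tissue_lacs.py.
_DEFAULT_TISSUES = {
    #                88       202      307      511      Bq/mL
    "air":          ((0.0,     0.0,     0.0,     0.0),    0.0),
    "lung":         ((0.0534,  0.0410,  0.0353,  0.0288), 1200.0),
    "fat":          ((0.1594,  0.1223,  0.1053,  0.0860), 2500.0),
    "soft_tissue":  ((0.1780,  0.1365,  0.1175,  0.0960), 5000.0),
    "bone_marrow":  ((0.1817,  0.1394,  0.1200,  0.0980), 3000.0),
    "bone":         ((0.3298,  0.2086,  0.1764,  0.1430), 2000.0),
}


def default_tissue_table() -> TissueTable:
    """Default five-compartment tissue table (plus marrow).

    At 511 keV: fat falls in [0.080, 0.090), water-based soft tissue in
    [0.090, 0.105], bone above 0.105 cm^-1 — consistent with the LAC
    thresholds the evaluation module segments on.
    """
    return TissueTable({
        name: Tissue(dict(zip(ENERGIES_KEV, lacs)), act)
        for name, (lacs, act) in _DEFAULT_TISSUES.items()
    })


@dataclass
class Shape:
    """Ellipse/ellipsoid or axis-aligned box primitive, in voxel units."""

    kind: str  # "ellipse" or "box"
    center: Tuple[float, ...]
    radii: Tuple[float, ...]  # semi-axes (ellipse) or half-sizes (box)
    tissue: str = "soft_tissue"

    def mask(self, shape: Tuple[int, ...]) -> np.ndarray:
        grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape],
                            indexing="ij", sparse=True)
        if len(self.center) != len(shape):
            raise ValidationError("shape primitive dimensionality mismatch")
        if any(r <= 0 for r in self.radii):
            raise ValidationError("primitive radii must be positive")
        if self.kind == "ellipse":
            acc = sum(((g - c) / r) ** 2
                      for g, c, r in zip(grids, self.center, self.radii))
            return acc <= 1.0
        if self.kind == "box":
            out = np.ones(shape, dtype=bool)
            for g, c, r in zip(grids, self.center, self.radii):
                out &= np.abs(g - c) <= r
            return out
        raise ValidationError(f"unknown primitive kind {self.kind!r}")


@dataclass
class Lesion:
    center: Tuple[float, ...]
    radius: float
    activity_multiplier: float = 5.0

    def __post_init__(self):
        if self.radius <= 0:
            raise ValidationError("lesion radius must be positive")


@dataclass
class PhantomSpec:
    """Declarative phantom description: painter's-order compartment list."""

    shape: Tuple[int, ...]
    compartments: List[Shape] = field(default_factory=list)
    lesions: List[Lesion] = field(default_factory=list)
    voxel_size_mm: float = 1.65
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "shape": list(self.shape),
            "voxel_size_mm": self.voxel_size_mm,
            "seed": self.seed,
            "compartments": [
                {"kind": c.kind, "center": [float(v) for v in c.center],
                 "radii": [float(v) for v in c.radii], "tissue": c.tissue}
                for c in self.compartments],
            "lesions": [
                {"center": [float(v) for v in l.center],
                 "radius": float(l.radius),
                 "activity_multiplier": float(l.activity_multiplier)}
                for l in self.lesions],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        return cls(
            shape=tuple(d["shape"]),
            compartments=[Shape(c["kind"], tuple(c["center"]), tuple(c["radii"]),
                                c.get("tissue", "soft_tissue"))
                          for c in d.get("compartments", [])],
            lesions=[Lesion(tuple(l["center"]), float(l["radius"]),
                            float(l.get("activity_multiplier", 5.0)))
                     for l in d.get("lesions", [])],
            voxel_size_mm=float(d.get("voxel_size_mm", 1.65)),
            seed=int(d.get("seed", 0)),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class Phantom:
    """Ground truth bundle: labels, activity, and mu-maps per energy."""

    labels: VoxelVolume
    label_names: List[str]
    activity: VoxelVolume
    mu_maps: Dict[float, VoxelVolume]

    def mu(self, energy_kev: float) -> VoxelVolume:
        return self.mu_maps[float(energy_kev)]


def build_phantom(spec: PhantomSpec, table: TissueTable,
                  energies_kev: Sequence[float] = ENERGIES_KEV) -> Phantom:
    """Rasterise a phantom spec into label, activity and mu-map volumes.

    Compartments are painted in list order (later primitives overwrite
    earlier ones); lesions multiply the underlying tissue's activity. The
    result is a pure function of (spec, table).
    """
    for comp in spec.compartments:
        if comp.tissue not in table.tissues:
            raise ConfigurationError(f"unknown tissue {comp.tissue!r} in spec")
    names = ["air"] + [n for n in table.names if n != "air"]
    index = {n: i for i, n in enumerate(names)}

    labels = np.zeros(spec.shape, dtype=np.int16)
    for comp in spec.compartments:
        labels[comp.mask(spec.shape)] = index[comp.tissue]

    lac_lut = {e: np.array([table.lac(n, e) for n in names]) for e in energies_kev}
    act_lut = np.array([table.activity(n) for n in names])

    activity = act_lut[labels]
    for les in spec.lesions:
        m = Shape("ellipse", les.center, (les.radius,) * len(spec.shape)).mask(spec.shape)
        if not m.any():
            raise ConfigurationError("lesion lies outside the grid")
        activity = np.where(m, activity * les.activity_multiplier, activity)

    vx = spec.voxel_size_mm
    mk = lambda arr, role, e=None: VoxelVolume(arr, vx, role, e)
    return Phantom(
        labels=mk(labels, "label"),
        label_names=names,
        activity=mk(activity.astype(float), "activity"),
        mu_maps={float(e): mk(lac_lut[e][labels], "mu_map", float(e))
                 for e in energies_kev},
    )


def body_phantom_spec(shape: Tuple[int, int] = (64, 64), seed: int = 0,
                      n_lesions: int = 1, voxel_size_mm: float = 1.65) -> PhantomSpec:
    """Randomised 2-D body-like phantom: fat layer, soft tissue, lungs,
    spine (cortical bone around marrow), and hot lesions.

    The randomisation jitters compartment positions and semi-axes so a cohort
    of phantoms has anatomical variability; geometry is deterministic in
    ``seed``.
    """
    if len(shape) != 2:
        raise ConfigurationError("body_phantom_spec builds 2-D phantoms")
    rng = substream(seed, "phantom-geometry")
    ny, nx = shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    # body outline (fat) and inner soft tissue
    by = ny * (0.40 + 0.04 * rng.uniform(-1, 1))
    bx = nx * (0.44 + 0.04 * rng.uniform(-1, 1))
    fat_thickness = 0.06 * min(ny, nx) * (1 + 0.3 * rng.uniform(-1, 1))
    comps = [
        Shape("ellipse", (cy, cx), (by, bx), "fat"),
        Shape("ellipse", (cy, cx), (by - fat_thickness, bx - fat_thickness),
              "soft_tissue"),
    ]
    # lungs
    ly = by * (0.38 + 0.05 * rng.uniform(-1, 1))
    lx = bx * (0.30 + 0.05 * rng.uniform(-1, 1))
    off = bx * (0.42 + 0.05 * rng.uniform(-1, 1))
    lcy = cy - 0.15 * by
    comps += [
        Shape("ellipse", (lcy, cx - off), (ly, lx), "lung"),
        Shape("ellipse", (lcy, cx + off), (ly, lx), "lung"),
    ]
    # spine: cortical bone shell around marrow
    sy = cy + by * (0.55 + 0.06 * rng.uniform(-1, 1))
    srad = 0.085 * min(ny, nx) * (1 + 0.2 * rng.uniform(-1, 1))
    comps += [
        Shape("ellipse", (sy, cx), (srad, srad), "bone"),
        Shape("ellipse", (sy, cx), (srad * 0.5, srad * 0.5), "bone_marrow"),
    ]
    lesions = []
    for _ in range(n_lesions):
        ang = rng.uniform(0, 2 * np.pi)
        r = rng.uniform(0.25, 0.6)
        lcy2 = cy + r * (by - 2 * fat_thickness - 4) * np.sin(ang) * 0.5
        lcx2 = cx + r * (bx - 2 * fat_thickness - 4) * np.cos(ang)
        lesions.append(Lesion((lcy2, lcx2), rng.uniform(1.8, 3.2),
                              rng.uniform(4.0, 8.0)))
    return PhantomSpec(shape=shape, compartments=comps, lesions=lesions,
                       voxel_size_mm=voxel_size_mm, seed=seed)
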