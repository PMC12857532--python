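"""Synthetic pelvic phantoms and expert demonstration apertures.

Every downstream stage (dose, objectives, RL training) is exercised on seeded
phantoms generated here: a central ellipsoidal PTV (prostate-like target), an
anterior-superior bladder, a posterior rectum elongated along the
superior-inferior axis, and two lateral femoral heads, all as labeled binary
masks on a regular grid.  The expert demonstrator used for behavioral-cloning
initialization is a beam's-eye-view conformal projection of the PTV with a
configurable margin.

Grid axes are (x, y, z) = (patient left-right, posterior->anterior,
inferior->superior); voxel centers sit at ``index * spacing`` mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml
from scipy import ndimage

from vmatrl.machine import ArcTemplate, MachineModel

__all__ = ["Phantom", "ExpertDemo", "generate_phantom", "generate_expert_demos",
           "STRUCTURES", "OAR_NAMES"]

STRUCTURES = ("PTV", "bladder", "rectum", "femoral_head_L", "femoral_head_R")
OAR_NAMES = ("bladder", "rectum", "femoral_head_L", "femoral_head_R")

# nominal anatomy: per-structure ellipsoid semi-axes (mm) and centroid offsets
# from the grid center (mm, in (x, y, z)); sizes jitter +/-20 %, centroids
# jitter up to +/-10 mm (seeded)
_NOMINAL = {
    "PTV": ((24.0, 22.0, 24.0), (0.0, 0.0, 0.0)),
    "bladder": ((26.0, 22.0, 20.0), (0.0, 34.0, 18.0)),
    "rectum": ((13.0, 13.0, 36.0), (0.0, -31.0, -2.0)),
    "femoral_head_L": ((15.0, 15.0, 15.0), (44.0, -4.0, -6.0)),
    "femoral_head_R": ((15.0, 15.0, 15.0), (-44.0, -4.0, -6.0)),
}
_SIZE_JITTER = 0.20  # fractional
_CENTER_JITTER_MM = 10.0

_SIZE_CLASSES = {
    "toy": {"shape": (16, 16, 16), "spacing": (8.0, 8.0, 8.0)},
    "standard": {"shape": (48, 48, 32), "spacing": (5.0, 5.0, 5.0)},
}


@dataclass
class Phantom:
    """Labeled voxel anatomy on a regular grid with a prescription."""

    grid_shape: tuple
    spacing: tuple  # mm
    masks: dict  # name -> bool array of grid_shape
    prescription_dose: float = 36.25  # Gy
    isocenter: tuple = (0.0, 0.0, 0.0)  # mm, grid frame
    patient_id: str = "phantom"

    def voxel_centers(self) -> tuple:
        """Per-axis voxel-center coordinate vectors in mm."""
        return tuple(np.arange(n) * s for n, s in zip(self.grid_shape, self.spacing))

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def oar_union(self) -> np.ndarray:
        out = np.zeros(self.grid_shape, dtype=bool)
        for name in OAR_NAMES:
            if name in self.masks:
                out |= self.masks[name]
        return out

    def validate(self) -> None:
        for name, mask in self.masks.items():
            if mask.shape != tuple(self.grid_shape):
                raise ValueError(f"mask {name} does not match grid shape")
            if not mask.any():
                raise ValueError(f"mask {name} is empty")
        if "PTV" not in self.masks:
            raise ValueError("phantom needs a PTV mask")
        _, n_comp = ndimage.label(self.masks["PTV"])
        if n_comp != 1:
            raise ValueError("PTV mask must be connected")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")

    def save(self, prefix) -> None:
        """Write masks to ``<prefix>.h5`` and geometry to ``<prefix>.yaml``."""
        prefix = Path(prefix)
        with h5py.File(prefix.with_suffix(".h5"), "w") as fh:
            for name, mask in self.masks.items():
                fh.create_dataset(f"masks/{name}", data=mask.astype(np.uint8))
        sidecar = {
            "format": "vmatrl-phantom-v1",
            "patient_id": self.patient_id,
            "grid_shape": [int(v) for v in self.grid_shape],
            "spacing_mm": [float(v) for v in self.spacing],
            "prescription_dose_gy": float(self.prescription_dose),
            "isocenter_mm": [float(v) for v in self.isocenter],
            "structures": sorted(self.masks),
        }
        with open(prefix.with_suffix(".yaml"), "w") as fh:
            yaml.safe_dump(sidecar, fh, sort_keys=False)

    @classmethod
    def load(cls, prefix) -> "Phantom":
        prefix = Path(prefix)
        with open(prefix.with_suffix(".yaml")) as fh:
            meta = yaml.safe_load(fh)
        masks = {}
        with h5py.File(prefix.with_suffix(".h5"), "r") as fh:
            for name in meta["structures"]:
                masks[name] = fh[f"masks/{name}"][...].astype(bool)
        return cls(grid_shape=tuple(meta["grid_shape"]),
                   spacing=tuple(meta["spacing_mm"]), masks=masks,
                   prescription_dose=meta["prescription_dose_gy"],
                   isocenter=tuple(meta["isocenter_mm"]),
                   patient_id=meta.get("patient_id", "phantom"))


@dataclass
class ExpertDemo:
    """Per-control-point conformal apertures used as the imitation target."""

    patient_id: str
    apertures: np.ndarray  # (n_cp, 52): 26 X1 then 26 X2, cm


def _ellipsoid_mask(centers, semiaxes, center_mm) -> np.ndarray:
    xs, ys, zs = centers
    dx = (xs - center_mm[0]) / semiaxes[0]
    dy = (ys - center_mm[1]) / semiaxes[1]
    dz = (zs - center_mm[2]) / semiaxes[2]
    return (dx[:, None, None] ** 2 + dy[None, :, None] ** 2
            + dz[None, None, :] ** 2) <= 1.0


def generate_phantom(seed: int, size_class: str = "toy",
                     prescription_dose: float = 36.25,
                     patient_id: str | None = None) -> Phantom:
    """Generate a seeded synthetic pelvic phantom.

    Deterministic for a fixed ``(seed, size_class)``.  Organ semi-axes jitter
    by +/-20 % and centroids by up to +/-10 mm; overlap with the PTV is removed
    from every OAR mask so per-structure ideal doses stay consistent.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    if size_class not in _SIZE_CLASSES:
        raise ValueError(f"unknown size_class {size_class!r}; "
                         f"choose from {sorted(_SIZE_CLASSES)}")
    geom = _SIZE_CLASSES[size_class]
    shape, spacing = geom["shape"], geom["spacing"]
    rng = np.random.default_rng(seed)

    centers = tuple(np.arange(n) * s for n, s in zip(shape, spacing))
    grid_center = np.array([(n - 1) * s / 2.0 for n, s in zip(shape, spacing)])
    # keep jitter inside the grid on the coarse toy class
    jitter_cap = _CENTER_JITTER_MM if size_class == "standard" else 6.0

    masks = {}
    for name in STRUCTURES:
        semi, offset = _NOMINAL[name]
        scale = 1.0 + _SIZE_JITTER * rng.uniform(-1.0, 1.0)
        shift = rng.uniform(-jitter_cap, jitter_cap, size=3)
        center = grid_center + np.asarray(offset) + shift
        mask = _ellipsoid_mask(centers, np.asarray(semi) * scale, center)
        if not mask.any():  # guard tiny structures on coarse grids
            idx = np.round(center / np.asarray(spacing)).astype(int)
            idx = np.clip(idx, 0, np.asarray(shape) - 1)
            mask = np.zeros(shape, dtype=bool)
            mask[tuple(idx)] = True
        masks[name] = mask

    for name in OAR_NAMES:
        masks[name] &= ~masks["PTV"]
        if not masks[name].any():
            raise RuntimeError(f"OAR {name} vanished after PTV overlap removal")

    ptv_idx = np.argwhere(masks["PTV"])
    iso = ptv_idx.mean(axis=0) * np.asarray(spacing)
    phantom = Phantom(grid_shape=tuple(shape), spacing=tuple(float(s) for s in spacing),
                      masks=masks, prescription_dose=prescription_dose,
                      isocenter=tuple(float(v) for v in iso),
                      patient_id=patient_id or f"{size_class}-{seed:04d}")
    phantom.validate()
    return phantom


def bev_coordinates(phantom: Phantom, angle_deg: float) -> tuple:
    """Project voxel centers into the isocenter plane at a gantry angle.

    Returns ``(u, z)`` in cm for every voxel: ``u`` along the leaf-travel
    direction, ``z`` along the leaf-pair stacking (superior positive), both
    relative to the isocenter.  The projection is parallel (divergence-free),
    matching the dose engine's beamlet geometry.
    """
    theta = np.deg2rad(angle_deg)
    xs, ys, zs = phantom.voxel_centers()
    dx = (xs - phantom.isocenter[0]) / 10.0  # cm
    dy = (ys - phantom.isocenter[1]) / 10.0
    dz = (zs - phantom.isocenter[2]) / 10.0
    # leaf-travel unit vector u(theta) = (cos t, -sin t, 0)
    u = (np.cos(theta) * dx[:, None, None] - np.sin(theta) * dy[None, :, None]
         + 0.0 * dz[None, None, :])
    z = np.broadcast_to(dz[None, None, :], phantom.grid_shape)
    return u, z


def generate_expert_demos(phantom: Phantom, arc: ArcTemplate,
                          machine: MachineModel | None = None,
                          margin_cm: float = 0.3) -> ExpertDemo:
    """Conformal-aperture expert: leaves open to the PTV silhouette per CP.

    At each gantry angle the PTV voxel centers are projected into the
    isocenter plane; every leaf pair whose band intersects the (margin-grown)
    silhouette opens from the silhouette's lower to upper edge along the
    travel direction, again grown by the margin.  Pairs with no projected PTV
    stay closed at the field center.
    """
    machine = machine or MachineModel()
    if "PTV" not in phantom.masks or not phantom.masks["PTV"].any():
        raise ValueError("phantom has an empty PTV; cannot build expert apertures")
    ptv = phantom.masks["PTV"]
    edges = machine.pair_edges()  # superior -> inferior
    n_pairs = machine.leaf_pairs
    apertures = np.zeros((arc.n_cp, 2 * n_pairs), dtype=float)
    for ci, angle in enumerate(arc.angles()):
        u, z = bev_coordinates(phantom, angle)
        uv, zv = u[ptv], z[ptv]
        x1 = np.zeros(n_pairs)
        x2 = np.zeros(n_pairs)
        for p in range(n_pairs):
            z_hi, z_lo = edges[p], edges[p + 1]
            sel = (zv + margin_cm >= z_lo) & (zv - margin_cm <= z_hi)
            if sel.any():
                lo = max(uv[sel].min() - margin_cm, -machine.field_half_width)
                hi = min(uv[sel].max() + margin_cm, machine.field_half_width)
                x1[p], x2[p] = lo, hi
        apertures[ci, :n_pairs] = x1
        apertures[ci, n_pairs:] = x2
    return ExpertDemo(patient_id=phantom.patient_id, apertures=apertures)
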