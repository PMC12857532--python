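"""Analytic beamlet dose engine, plan dose composition, D95 normalization, gamma.

The engine models each control-point angle as a parallel (divergence-free)
beam decomposed into beamlets on a (leaf pair) x (along-travel bin) grid in
the isocenter plane.  A beamlet deposits

    dose(v) = C * exp(-mu * depth(v)) * P_u(u_v - u_b) * P_z(z_v - z_p)

with ``depth`` the distance from the voxel to the phantom surface toward the
source, and ``P_u``/``P_z`` rectangular profiles convolved with a Gaussian
penumbra (error-function edges).  Because the three factors depend only on
(voxel), (beamlet travel-bin, voxel) and (leaf pair, voxel z) respectively,
the bank stores them factorized; composing an aperture is two small einsums.

Dose is strictly linear in MU and in the per-beamlet open fraction, which is
what the RL reward structure relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.special import erf

from vmatrl.machine import ArcTemplate, ControlPoint, MachineModel, Plan
from vmatrl.phantoms import Phantom

__all__ = [
    "KernelParams",
    "BeamletBank",
    "DoseGrid",
    "NormalizationError",
    "precompute_beamlets",
    "aperture_fractions",
    "cp_dose",
    "plan_dose",
    "normalize_d95",
    "d95_dose",
    "gamma_pass_rate",
]


class NormalizationError(RuntimeError):
    """Target coverage cannot be anchored (e.g. the PTV receives no dose)."""


@dataclass(frozen=True)
class KernelParams:
    """Analytic beamlet kernel parameters.

    ``mu_mm`` is the linear attenuation coefficient (1/mm); ``sigma_mm`` the
    Gaussian penumbra width; ``calibration`` is fixed so a broad open field
    delivers ``dose_per_mu_ref`` Gy/MU at ``ref_depth_mm`` depth.
    """

    mu_mm: float = 0.005
    sigma_mm: float = 3.0
    dose_per_mu_ref: float = 0.02  # Gy/MU (~2 Gy per 100 MU)
    ref_depth_mm: float = 100.0
    n_travel_bins: int = 0  # 0 -> one bin per projected leaf width

    def __post_init__(self) -> None:
        if self.mu_mm <= 0 or self.sigma_mm <= 0 or self.dose_per_mu_ref <= 0:
            raise ValueError("kernel parameters must be strictly positive")

    @property
    def calibration(self) -> float:
        """Central-axis Gy/MU before attenuation."""
        return self.dose_per_mu_ref * np.exp(self.mu_mm * self.ref_depth_mm)


@dataclass
class DoseGrid:
    """3D dose on a phantom grid, raw (Gy) or anchored to 95 % target coverage."""

    values: np.ndarray
    spacing: tuple
    normalization: str = "raw"  # 'raw' | 'd95_anchored'

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.normalization not in ("raw", "d95_anchored"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    def copy(self) -> "DoseGrid":
        return DoseGrid(self.values.copy(), tuple(self.spacing), self.normalization)


@dataclass
class BeamletBank:
    """Factorized per-angle beamlet dose tensors (Gy/MU) on a phantom grid.

    Per precomputed angle ``a``:
      * ``attenuation[a]`` — grid-shaped central-axis dose factor C*exp(-mu*depth)
      * ``profile_u[a]``   — (n_bins, nx, ny) travel-direction beamlet profiles
    ``profile_z`` — (n_pairs, nz) leaf-pair profiles, shared across angles.
    The dense tensor of one beamlet is the outer product of the three factors.
    """

    angles: np.ndarray
    attenuation: dict
    profile_u: dict
    profile_z: np.ndarray
    u_edges: np.ndarray  # (n_bins + 1,) cm
    grid_shape: tuple
    spacing: tuple
    kernel: KernelParams = field(default_factory=KernelParams)

    @property
    def n_bins(self) -> int:
        return len(self.u_edges) - 1

    @property
    def n_pairs(self) -> int:
        return self.profile_z.shape[0]

    def has_angle(self, angle: float) -> bool:
        return any(abs(a - angle) < 1e-9 for a in self.angles)

    def beamlet_dose(self, angle: float, pair: int, travel_bin: int) -> np.ndarray:
        """Materialize one beamlet's dense dose tensor (Gy/MU)."""
        a = self._key(angle)
        return (self.attenuation[a]
                * self.profile_u[a][travel_bin][:, :, None]
                * self.profile_z[pair][None, None, :])

    def _key(self, angle: float) -> float:
        for a in self.angles:
            if abs(a - angle) < 1e-9:
                return float(a)
        raise KeyError(f"angle {angle} not precomputed in bank")

    def bracketing(self, angle: float) -> tuple:
        """Two nearest precomputed angles (circular) and linear weights."""
        diffs = np.abs((self.angles - angle + 180.0) % 360.0 - 180.0)
        order = np.argsort(diffs)
        a0, a1 = float(self.angles[order[0]]), float(self.angles[order[1 % len(order)]])
        d0, d1 = diffs[order[0]], diffs[order[1 % len(order)]]
        if d0 + d1 < 1e-12:
            return a0, a1, 1.0, 0.0
        w0 = d1 / (d0 + d1)
        return a0, a1, float(w0), float(1.0 - w0)

    def save(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.attrs["format"] = "vmatrl-bank-v1"
            fh.attrs["grid_shape"] = self.grid_shape
            fh.attrs["spacing_mm"] = self.spacing
            fh.attrs["mu_mm"] = self.kernel.mu_mm
            fh.attrs["sigma_mm"] = self.kernel.sigma_mm
            fh.attrs["dose_per_mu_ref"] = self.kernel.dose_per_mu_ref
            fh.attrs["ref_depth_mm"] = self.kernel.ref_depth_mm
            fh.create_dataset("angles", data=self.angles)
            fh.create_dataset("u_edges", data=self.u_edges)
            fh.create_dataset("profile_z", data=self.profile_z)
            for a in self.angles:
                g = fh.create_group(f"angle_{a:.4f}")
                g.create_dataset("attenuation", data=self.attenuation[float(a)])
                g.create_dataset("profile_u", data=self.profile_u[float(a)])

    @classmethod
    def load(cls, path) -> "BeamletBank":
        with h5py.File(path, "r") as fh:
            kernel = KernelParams(mu_mm=float(fh.attrs["mu_mm"]),
                                  sigma_mm=float(fh.attrs["sigma_mm"]),
                                  dose_per_mu_ref=float(fh.attrs["dose_per_mu_ref"]),
                                  ref_depth_mm=float(fh.attrs["ref_depth_mm"]))
            angles = fh["angles"][...]
            atten, prof_u = {}, {}
            for a in angles:
                g = fh[f"angle_{a:.4f}"]
                atten[float(a)] = g["attenuation"][...]
                prof_u[float(a)] = g["profile_u"][...]
            return cls(angles=angles, attenuation=atten, profile_u=prof_u,
                       profile_z=fh["profile_z"][...], u_edges=fh["u_edges"][...],
                       grid_shape=tuple(int(v) for v in fh.attrs["grid_shape"]),
                       spacing=tuple(float(v) for v in fh.attrs["spacing_mm"]),
                       kernel=kernel)


def _rect_gauss_profile(x: np.ndarray, lo: float, hi: float, sigma: float) -> np.ndarray:
    """Rectangular profile on [lo, hi] convolved with a Gaussian of width sigma."""
    s = sigma * np.sqrt(2.0)
    return 0.5 * (erf((hi - x) / s) - erf((lo - x) / s))


def _depth_to_surface(phantom: Phantom, angle_deg: float) -> np.ndarray:
    """Per-voxel distance (mm) from voxel center to the grid boundary toward
    the source at the given gantry angle (parallel geometry)."""
    theta = np.deg2rad(angle_deg)
    s = np.array([np.sin(theta), np.cos(theta), 0.0])  # toward the source
    xs, ys, zs = phantom.voxel_centers()
    coords = [xs, ys, zs]
    t_min = np.full(phantom.grid_shape, np.inf)
    for ax in range(3):
        if abs(s[ax]) < 1e-12:
            continue
        n, sp = phantom.grid_shape[ax], phantom.spacing[ax]
        lo, hi = -sp / 2.0, (n - 1) * sp + sp / 2.0  # voxel-edge bounds
        bound = hi if s[ax] > 0 else lo
        t_ax = (bound - coords[ax]) / s[ax]
        shape = [1, 1, 1]
        shape[ax] = n
        t_min = np.minimum(t_min, t_ax.reshape(shape))
    return t_min


def precompute_beamlets(phantom: Phantom, arc: ArcTemplate,
                        machine: MachineModel | None = None,
                        kernel: KernelParams | None = None,
                        angles: np.ndarray | None = None) -> BeamletBank:
    """Precompute the factorized beamlet bank for every arc angle.

    Deterministic.  ``angles`` overrides the arc's CP angles (e.g. a coarser
    set for angular-blending studies).
    """
    machine = machine or MachineModel()
    kernel = kernel or KernelParams()
    angle_list = np.asarray(angles if angles is not None else arc.angles(), dtype=float)

    n_bins = kernel.n_travel_bins
    if n_bins <= 0:
        n_bins = int(np.ceil(2.0 * machine.field_half_width / machine.leaf_width_iso))
    u_edges = np.linspace(-machine.field_half_width, machine.field_half_width, n_bins + 1)

    xs, ys, zs = phantom.voxel_centers()
    z_cm = (zs - phantom.isocenter[2]) / 10.0
    sigma_cm = kernel.sigma_mm / 10.0
    pair_edges = machine.pair_edges()  # superior -> inferior, cm
    profile_z = np.stack([
        _rect_gauss_profile(z_cm, pair_edges[p + 1], pair_edges[p], sigma_cm)
        for p in range(machine.leaf_pairs)
    ])

    atten, prof_u = {}, {}
    theta_all = np.deg2rad(angle_list)
    for angle, theta in zip(angle_list, theta_all):
        depth = _depth_to_surface(phantom, angle)
        atten[float(angle)] = kernel.calibration * np.exp(-kernel.mu_mm * depth)
        dx = (xs - phantom.isocenter[0]) / 10.0
        dy = (ys - phantom.isocenter[1]) / 10.0
        u = np.cos(theta) * dx[:, None] - np.sin(theta) * dy[None, :]  # (nx, ny) cm
        prof_u[float(angle)] = np.stack([
            _rect_gauss_profile(u, u_edges[b], u_edges[b + 1], sigma_cm)
            for b in range(n_bins)
        ])
    return BeamletBank(angles=angle_list, attenuation=atten, profile_u=prof_u,
                       profile_z=profile_z, u_edges=u_edges,
                       grid_shape=tuple(phantom.grid_shape),
                       spacing=tuple(phantom.spacing), kernel=kernel)


def aperture_fractions(cp: ControlPoint, bank: BeamletBank) -> np.ndarray:
    """Open fraction in [0, 1] of each (pair, travel-bin) beamlet under a CP
    aperture; a leaf bisecting a bin credits the bin linearly."""
    lo = np.maximum(cp.leaf_x1[:, None], bank.u_edges[None, :-1])
    hi = np.minimum(cp.leaf_x2[:, None], bank.u_edges[None, 1:])
    width = bank.u_edges[1:] - bank.u_edges[:-1]
    return np.clip((hi - lo) / width[None, :], 0.0, 1.0)


def _aperture_dose(fractions: np.ndarray, angle: float, bank: BeamletBank) -> np.ndarray:
    """Dose tensor (Gy/MU) of an aperture at one precomputed angle."""
    a = bank._key(angle)
    # (pairs,bins),(pairs,nz) -> (bins,nz); (bins,nx,ny),(bins,nz) -> (nx,ny,nz)
    m = np.einsum("pb,pz->bz", fractions, bank.profile_z)
    open_field = np.einsum("bxy,bz->xyz", bank.profile_u[a], m)
    return bank.attenuation[a] * open_field


def cp_dose(cp: ControlPoint, bank: BeamletBank,
            machine: MachineModel | None = None) -> DoseGrid:
    """Raw dose (Gy) of a single control point: MU x aperture-weighted beamlets."""
    frac = aperture_fractions(cp, bank)
    return DoseGrid(cp.mu * _aperture_dose(frac, cp.angle, bank),
                    spacing=bank.spacing, normalization="raw")


def plan_dose(plan: Plan, bank: BeamletBank, blend: bool = False) -> DoseGrid:
    """Raw cumulative dose of a plan.

    With ``blend=False`` (default) each CP deposits at its own precomputed
    angle.  With ``blend=True`` each CP's fluence is split across the two
    nearest precomputed angles with weights linear in angular distance
    (summing to 1) — the VMAT adaptation for banks coarser than the CP
    spacing.  When bank angles coincide with CP angles the two modes agree.
    """
    total = np.zeros(bank.grid_shape, dtype=float)
    for cp in plan.control_points:
        if cp.mu == 0.0:
            continue
        frac = aperture_fractions(cp, bank)
        if blend:
            a0, a1, w0, w1 = bank.bracketing(cp.angle)
            total += cp.mu * w0 * _aperture_dose(frac, a0, bank)
            if w1 > 0.0:
                total += cp.mu * w1 * _aperture_dose(frac, a1, bank)
        else:
            total += cp.mu * _aperture_dose(frac, cp.angle, bank)
    return DoseGrid(total, spacing=bank.spacing, normalization="raw")


def d95_dose(dose_values: np.ndarray, ptv_mask: np.ndarray) -> float:
    """D95: the largest dose d such that >= 95 % of PTV voxels receive >= d.

    Computed from the sorted PTV voxel doses without interpolation.
    """
    vals = np.sort(np.asarray(dose_values)[ptv_mask])[::-1]
    if vals.size == 0:
        raise ValueError("empty PTV mask")
    k = int(np.ceil(0.95 * vals.size)) - 1
    return float(vals[k])


def normalize_d95(dose: DoseGrid, ptv_mask: np.ndarray) -> tuple:
    """Scale dose so PTV D95 equals 1.0 (prescription-relative).

    Returns ``(anchored DoseGrid, scale factor)``.  Raises
    :class:`NormalizationError` when the PTV receives no anchorable dose.
    """
    d95 = d95_dose(dose.values, ptv_mask)
    if d95 <= 0.0:
        raise NormalizationError("PTV D95 is zero; cannot anchor target coverage")
    s = 1.0 / d95
    return DoseGrid(dose.values * s, spacing=tuple(dose.spacing),
                    normalization="d95_anchored"), s


def gamma_pass_rate(eval_dose: DoseGrid, ref_dose: DoseGrid,
                    dose_crit_pct: float = 3.0, dist_crit_mm: float = 2.0,
                    threshold_pct: float = 10.0,
                    search_radius_factor: float = 3.0) -> float:
    """Global 3D gamma pass rate (percent of evaluated voxels with gamma <= 1).

    The dose criterion is a percentage of the reference maximum (global
    normalization); reference voxels below ``threshold_pct`` % of that maximum
    are excluded.  For each evaluated reference voxel the evaluated
    distribution is searched exhaustively over all voxel offsets within
    ``search_radius_factor * dist_crit_mm``.
    """
    ref = np.asarray(ref_dose.values, dtype=float)
    ev = np.asarray(eval_dose.values, dtype=float)
    if ref.shape != ev.shape or tuple(ref_dose.spacing) != tuple(eval_dose.spacing):
        raise ValueError("gamma comparison requires identical grid geometry")
    ref_max = ref.max()
    if ref_max <= 0:
        raise ValueError("reference dose is identically zero")
    dd = dose_crit_pct / 100.0 * ref_max
    spacing = np.asarray(ref_dose.spacing, dtype=float)
    radius = search_radius_factor * dist_crit_mm

    max_off = np.floor(radius / spacing).astype(int)
    offsets = []
    for ox in range(-max_off[0], max_off[0] + 1):
        for oy in range(-max_off[1], max_off[1] + 1):
            for oz in range(-max_off[2], max_off[2] + 1):
                r = np.linalg.norm(np.array([ox, oy, oz]) * spacing)
                if r <= radius + 1e-9:
                    offsets.append(((ox, oy, oz), r))

    evaluated = ref >= threshold_pct / 100.0 * ref_max
    gamma_sq = np.full(ref.shape, np.inf)
    for (ox, oy, oz), r in offsets:
        shifted = _shift_with_nan(ev, (ox, oy, oz))
        cand = ((shifted - ref) / dd) ** 2 + (r / dist_crit_mm) ** 2
        cand = np.where(np.isnan(shifted), np.inf, cand)
        gamma_sq = np.minimum(gamma_sq, cand)
    n_eval = int(evaluated.sum())
    if n_eval == 0:
        raise ValueError("no voxels above the evaluation threshold")
    n_pass = int((gamma_sq[evaluated] <= 1.0 + 1e-12).sum())
    return 100.0 * n_pass / n_eval


def _shift_with_nan(arr: np.ndarray, offset: tuple) -> np.ndarray:
    """arr sampled at index+offset; out-of-bounds positions become NaN."""
    out = np.full(arr.shape, np.nan)
    src, dst = [], []
    for n, o in zip(arr.shape, offset):
        src.append(slice(max(o, 0), min(n, n + o)))
        dst.append(slice(max(-o, 0), min(n, n - o)))
    out[tuple(dst)] = arr[tuple(src)]
    return out
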