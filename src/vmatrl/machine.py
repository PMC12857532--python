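"""Machine model, arc geometry, plan containers, deliverability, and plan I/O.

Conventions
-----------
* Leaf positions are signed centimetres in the isocenter plane along the leaf
  travel direction.  Each of the 26 leaf pairs holds a lower edge ``x1`` and an
  upper edge ``x2``; ``x1 <= x2`` defines an open gap, ``x1 == x2`` a closed pair.
* Pair index increases superior -> inferior; pair boundaries are multiples of
  the projected leaf width, with the bank centred on the isocenter.
* Gantry angles are degrees in [0, 360), increasing clockwise viewed from the
  superior direction; the arc is a single rotation with evenly spaced control
  points and an optional excluded interval (the MR-linac cryostat gap).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "MachineModel",
    "ArcTemplate",
    "ControlPoint",
    "Plan",
    "DeliverabilityViolation",
    "DeliverabilityReport",
    "PlanValidationError",
    "build_arc_template",
    "check_deliverability",
    "project_action_to_bounds",
    "make_deliverable",
    "read_plan",
    "write_plan",
]

# numerical slack for inclusive boundary comparisons (ties are deliverable)
_BOUND_EPS = 1e-9


class PlanValidationError(ValueError):
    """A plan or plan file violates a structural invariant."""


@dataclass(frozen=True)
class MachineModel:
    """Delivery machine description (MR-linac-like defaults).

    ``cp_delivery_time`` is the time budget to move between adjacent control
    points; leaf-travel and per-CP monitor-unit limits derive from it.
    """

    leaf_pairs: int = 26
    leaf_width_iso: float = 0.71  # cm, projected at isocenter
    field_half_width: float = 10.0  # cm, maximum |leaf position|
    max_leaf_speed: float = 6.0  # cm/s
    max_dose_rate: float = 425.0  # MU/min
    cp_delivery_time: float = 0.5  # s

    def __post_init__(self) -> None:
        for name in ("leaf_pairs", "leaf_width_iso", "field_half_width",
                     "max_leaf_speed", "max_dose_rate", "cp_delivery_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"MachineModel.{name} must be strictly positive")

    @property
    def n_leaves(self) -> int:
        return 2 * self.leaf_pairs

    @property
    def max_travel_per_cp(self) -> float:
        """Maximum leaf travel between adjacent CPs, cm."""
        return self.max_leaf_speed * self.cp_delivery_time

    @property
    def max_mu_per_cp(self) -> float:
        """Maximum MU deliverable in one CP interval."""
        return self.max_dose_rate * self.cp_delivery_time / 60.0

    def pair_edges(self) -> np.ndarray:
        """Superior->inferior pair boundary coordinates (cm), length pairs+1."""
        w = self.leaf_width_iso
        top = 0.5 * self.leaf_pairs * w
        return top - w * np.arange(self.leaf_pairs + 1)


@dataclass(frozen=True)
class ArcTemplate:
    """Ordered control-point angles of a single arc."""

    cp_angles: tuple
    spacing_deg: float = 2.0
    gap: tuple | None = (4.0, 23.0)

    def __post_init__(self) -> None:
        angles = np.asarray(self.cp_angles, dtype=float)
        if angles.ndim != 1 or angles.size == 0:
            raise ValueError("ArcTemplate needs at least one CP angle")
        if np.any(np.diff(angles) <= 0):
            raise ValueError("CP angles must be strictly increasing")

    @property
    def n_cp(self) -> int:
        return len(self.cp_angles)

    def angles(self) -> np.ndarray:
        return np.asarray(self.cp_angles, dtype=float)


def build_arc_template(spacing_deg: float = 2.0,
                       gap: tuple | None = (4.0, 23.0)) -> ArcTemplate:
    """Build a single-arc CP angle list with an optional excluded interval.

    Angles are the multiples of ``spacing_deg`` in [0, 360).  An angle ``a`` is
    excluded when ``gap[0] + spacing <= a <= gap[1] - spacing``, i.e. the gap's
    conservative interior: delivery is retained at the grid angles adjacent to
    the gap edges.  With the 2 degree spacing and the 4-23 degree cryostat gap
    this removes the eight angles 6..20 and yields 172 CPs.
    """
    if spacing_deg <= 0 or 360.0 % spacing_deg != 0:
        raise ValueError("spacing_deg must be positive and divide 360")
    angles = np.arange(0.0, 360.0, spacing_deg)
    if gap is not None:
        lo, hi = float(gap[0]), float(gap[1])
        if hi - lo >= 360.0:
            raise ValueError("gap cannot cover the full circle")
        keep = ~((angles >= lo + spacing_deg - _BOUND_EPS)
                 & (angles <= hi - spacing_deg + _BOUND_EPS))
        angles = angles[keep]
    return ArcTemplate(cp_angles=tuple(angles.tolist()), spacing_deg=spacing_deg,
                       gap=tuple(gap) if gap is not None else None)


@dataclass
class ControlPoint:
    """One control point: gantry angle, 52 leaf positions, and an MU value.

    ``leaf_x1``/``leaf_x2`` are the 26 lower/upper leaf-pair edges (cm).
    """

    angle: float
    leaf_x1: np.ndarray
    leaf_x2: np.ndarray
    mu: float

    def __post_init__(self) -> None:
        self.leaf_x1 = np.asarray(self.leaf_x1, dtype=float)
        self.leaf_x2 = np.asarray(self.leaf_x2, dtype=float)
        if self.leaf_x1.shape != self.leaf_x2.shape or self.leaf_x1.ndim != 1:
            raise PlanValidationError("leaf arrays must be 1-D and equal length")

    @property
    def leaf_positions(self) -> np.ndarray:
        """52-vector: 26 X1 ('top') then 26 X2 ('bottom') values."""
        return np.concatenate([self.leaf_x1, self.leaf_x2])

    @classmethod
    def from_leaf_vector(cls, angle: float, leaves: np.ndarray, mu: float) -> "ControlPoint":
        leaves = np.asarray(leaves, dtype=float)
        n = leaves.size // 2
        return cls(angle=angle, leaf_x1=leaves[:n].copy(), leaf_x2=leaves[n:].copy(), mu=mu)

    def validate(self, machine: MachineModel) -> None:
        if self.leaf_x1.size != machine.leaf_pairs:
            raise PlanValidationError(
                f"expected {machine.leaf_pairs} leaf pairs, got {self.leaf_x1.size}")
        if self.mu < 0:
            raise PlanValidationError("MU must be non-negative")
        if np.any(self.leaf_x2 < self.leaf_x1 - _BOUND_EPS):
            raise PlanValidationError("crossed leaf pair (X2 < X1)")
        fhw = machine.field_half_width
        if np.any(np.abs(self.leaf_x1) > fhw + _BOUND_EPS) or np.any(
                np.abs(self.leaf_x2) > fhw + _BOUND_EPS):
            raise PlanValidationError("leaf position outside field half-width")

    def copy(self) -> "ControlPoint":
        return ControlPoint(self.angle, self.leaf_x1.copy(), self.leaf_x2.copy(), float(self.mu))


@dataclass
class Plan:
    """An ordered set of control points forming one VMAT arc."""

    control_points: list
    patient_id: str = "anon"

    @property
    def n_cp(self) -> int:
        return len(self.control_points)

    def angles(self) -> np.ndarray:
        return np.array([cp.angle for cp in self.control_points], dtype=float)

    def mus(self) -> np.ndarray:
        return np.array([cp.mu for cp in self.control_points], dtype=float)

    def total_mu(self) -> float:
        return float(self.mus().sum())

    def validate(self, machine: MachineModel, template: ArcTemplate | None = None) -> None:
        if template is not None:
            if self.n_cp != template.n_cp:
                raise PlanValidationError(
                    f"plan has {self.n_cp} CPs, arc template expects {template.n_cp}")
            if not np.allclose(self.angles(), template.angles()):
                raise PlanValidationError("plan CP angles do not match arc template")
        for i, cp in enumerate(self.control_points):
            try:
                cp.validate(machine)
            except PlanValidationError as exc:
                raise PlanValidationError(f"control point {i}: {exc}") from exc

    def copy(self) -> "Plan":
        return Plan([cp.copy() for cp in self.control_points], self.patient_id)


@dataclass(frozen=True)
class DeliverabilityViolation:
    cp_index: int
    kind: str  # 'leaf_bound' | 'leaf_crossing' | 'leaf_travel' | 'mu_limit'
    detail: str
    magnitude: float


@dataclass
class DeliverabilityReport:
    violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return len(self.violations) == 0

    def __len__(self) -> int:
        return len(self.violations)

    def summary(self) -> str:
        if self.ok:
            return "deliverable (no violations)"
        kinds: dict = {}
        for v in self.violations:
            kinds[v.kind] = kinds.get(v.kind, 0) + 1
        parts = ", ".join(f"{k}: {n}" for k, n in sorted(kinds.items()))
        return f"{len(self.violations)} violations ({parts})"


def check_deliverability(plan: Plan, machine: MachineModel) -> DeliverabilityReport:
    """Report every physical-constraint violation of a plan.

    Checks, per CP: leaf positions within the field half-width, non-crossing
    pairs, per-CP MU within the dose-rate limit; and between adjacent CPs,
    leaf travel within ``max_leaf_speed * cp_delivery_time``.  All boundary
    comparisons are inclusive: a quantity exactly at its limit is deliverable.
    """
    rep = DeliverabilityReport()
    fhw = machine.field_half_width
    mu_max = machine.max_mu_per_cp
    travel_max = machine.max_travel_per_cp
    prev_leaves = None
    for i, cp in enumerate(plan.control_points):
        leaves = cp.leaf_positions
        over = np.abs(leaves) - fhw
        for j in np.flatnonzero(over > _BOUND_EPS):
            rep.violations.append(DeliverabilityViolation(
                i, "leaf_bound", f"leaf {j} at {leaves[j]:.3f} cm exceeds +/-{fhw} cm",
                float(over[j])))
        cross = cp.leaf_x1 - cp.leaf_x2
        for p in np.flatnonzero(cross > _BOUND_EPS):
            rep.violations.append(DeliverabilityViolation(
                i, "leaf_crossing", f"pair {p}: X1 {cp.leaf_x1[p]:.3f} > X2 {cp.leaf_x2[p]:.3f}",
                float(cross[p])))
        if cp.mu - mu_max > _BOUND_EPS:
            rep.violations.append(DeliverabilityViolation(
                i, "mu_limit", f"MU {cp.mu:.4f} exceeds {mu_max:.4f} per CP",
                float(cp.mu - mu_max)))
        if prev_leaves is not None:
            travel = np.abs(leaves - prev_leaves) - travel_max
            for j in np.flatnonzero(travel > _BOUND_EPS):
                rep.violations.append(DeliverabilityViolation(
                    i, "leaf_travel",
                    f"leaf {j} travels {np.abs(leaves - prev_leaves)[j]:.3f} cm "
                    f"> {travel_max:.3f} cm from CP {i - 1}",
                    float(travel[j])))
        prev_leaves = leaves
    return rep


def project_action_to_bounds(raw_leaves: np.ndarray, machine: MachineModel) -> np.ndarray:
    """Repair a raw 52-vector of leaf positions to per-CP validity.

    Values are clipped to the field half-width; any crossed pair (X1 > X2) is
    closed at the midpoint of its two clipped edges.  The map is idempotent
    and never increases any |position|.
    """
    raw = np.asarray(raw_leaves, dtype=float)
    n = raw.size // 2
    x1 = np.clip(raw[:n], -machine.field_half_width, machine.field_half_width)
    x2 = np.clip(raw[n:], -machine.field_half_width, machine.field_half_width)
    crossed = x1 > x2
    mid = 0.5 * (x1 + x2)
    x1 = np.where(crossed, mid, x1)
    x2 = np.where(crossed, mid, x2)
    return np.concatenate([x1, x2])


def make_deliverable(plan: Plan, machine: MachineModel, max_sweeps: int = 25) -> Plan:
    """Project a plan onto the deliverable set.

    Monitor units are clipped to non-negative and rescaled globally so the
    largest per-CP MU sits at the dose-rate cap (global rescale preserves the
    relative modulation; target-coverage renormalization removes the overall
    scale anyway).  Leaf positions are repaired per CP and then smoothed by
    alternating forward/backward sweeps that clip inter-CP travel to the leaf
    speed limit, re-closing any pair the sweep crosses.
    """
    out = plan.copy()
    mus = np.clip(out.mus(), 0.0, None)
    peak = mus.max() if mus.size else 0.0
    if peak > machine.max_mu_per_cp:
        mus = mus * (machine.max_mu_per_cp / peak)
    for cp, mu in zip(out.control_points, mus):
        cp.mu = float(mu)
        repaired = project_action_to_bounds(cp.leaf_positions, machine)
        n = machine.leaf_pairs
        cp.leaf_x1, cp.leaf_x2 = repaired[:n], repaired[n:]

    travel = machine.max_travel_per_cp
    n = machine.leaf_pairs
    for sweep in range(max_sweeps):
        changed = False
        order = range(1, out.n_cp) if sweep % 2 == 0 else range(out.n_cp - 2, -1, -1)
        step = -1 if sweep % 2 == 0 else 1
        for i in order:
            ref = out.control_points[i + step].leaf_positions
            cur = out.control_points[i].leaf_positions
            clipped = np.clip(cur, ref - travel, ref + travel)
            clipped = project_action_to_bounds(clipped, machine)
            if not np.array_equal(clipped, cur):
                changed = True
                out.control_points[i].leaf_x1 = clipped[:n]
                out.control_points[i].leaf_x2 = clipped[n:]
        if not changed and check_deliverability(out, machine).ok:
            break
    return out


# ---------------------------------------------------------------------------
# Plan file I/O (YAML; schema documented in the README)
# ---------------------------------------------------------------------------

def write_plan(plan: Plan, path, machine: MachineModel | None = None) -> None:
    """Write a plan to a YAML file (full float precision; round-trip exact)."""
    doc = {
        "format": "vmatrl-plan-v1",
        "patient_id": plan.patient_id,
        "n_cp": plan.n_cp,
        "control_points": [
            {
                "angle": float(cp.angle),
                "mu": float(cp.mu),
                "x1": [float(v) for v in cp.leaf_x1],
                "x2": [float(v) for v in cp.leaf_x2],
            }
            for cp in plan.control_points
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_plan(path, machine: MachineModel | None = None,
              template: ArcTemplate | None = None) -> Plan:
    """Read a plan file, validating structure (and machine/arc if provided)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or doc.get("format") != "vmatrl-plan-v1":
        raise PlanValidationError(f"{path}: not a vmatrl plan file")
    cps = []
    for i, item in enumerate(doc.get("control_points", [])):
        try:
            cp = ControlPoint(angle=float(item["angle"]),
                              leaf_x1=np.array(item["x1"], dtype=float),
                              leaf_x2=np.array(item["x2"], dtype=float),
                              mu=float(item["mu"]))
        except (KeyError, TypeError, ValueError) as exc:
            raise PlanValidationError(f"{path}: malformed control point {i}: {exc}") from exc
        if cp.mu < 0:
            raise PlanValidationError(f"{path}: control point {i}: negative MU")
        cps.append(cp)
    plan = Plan(control_points=cps, patient_id=str(doc.get("patient_id", "anon")))
    if machine is not None:
        plan.validate(machine, template)
    elif template is not None:
        if plan.n_cp != template.n_cp:
            raise PlanValidationError(
                f"{path}: plan has {plan.n_cp} CPs, template expects {template.n_cp}")
    return plan
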