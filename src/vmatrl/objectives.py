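"""DVH metrics, the constraint-scaled dose objective, and step rewards.

The plan objective is

    v = sum_i  w_i * MSE_i * f_i ** n_i

over structures i, where ``MSE_i`` is the mean squared per-voxel deviation of
the (D95-anchored, prescription-relative) dose from the structure's ideal
(1.0 for the PTV, 0.0 for OARs), ``n_i`` counts the structure's satisfied
dose-volume constraints (strict inequality), and ``f_i < 1`` rewards each
satisfied constraint with a multiplicative reduction of that structure's
term.  Defaults: PTV w=50, D2.0cm3 < 135 %, f=0.75; bladder w=20,
V50% < 40 %, f=0.5; rectum w=20, V50% < 50 % and V80% < 20 %, f=0.7.
The step reward is the decrease in v, so improvements are positive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import yaml

from vmatrl.dose import DoseGrid
from vmatrl.phantoms import Phantom

__all__ = [
    "Constraint",
    "StructureObjective",
    "ObjectiveSpec",
    "ObjectiveValue",
    "dvh_metric",
    "conformity_index",
    "objective_value",
    "step_reward",
]


@dataclass(frozen=True)
class Constraint:
    """A dose-volume constraint, satisfied by strict inequality.

    ``metric`` uses the DVH metric grammar of :func:`dvh_metric`
    (e.g. ``"D2.0cc"``, ``"V50%"``); ``limit`` is on the metric's own scale:
    prescription-relative dose for D-metrics, percent volume for V-metrics.
    """

    metric: str
    limit: float

    def satisfied(self, metric_value: float) -> bool:
        return metric_value < self.limit

    def label(self) -> str:
        if self.metric.startswith("V"):
            return f"{self.metric} < {self.limit:g}%"
        return f"{self.metric} < {self.limit * 100:g}%"


@dataclass(frozen=True)
class StructureObjective:
    name: str
    weight: float
    ideal_dose: float  # prescription-relative
    scaling_factor: float
    constraints: tuple = ()

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if not (0.0 < self.scaling_factor < 1.0):
            raise ValueError("scaling factor must lie in (0, 1)")


@dataclass(frozen=True)
class ObjectiveSpec:
    """Per-structure weights, ideal doses, constraints, and scaling factors."""

    structures: tuple

    @classmethod
    def default(cls) -> "ObjectiveSpec":
        return cls(structures=(
            StructureObjective("PTV", 50.0, 1.0, 0.75, (Constraint("D2.0cc", 1.35),)),
            StructureObjective("bladder", 20.0, 0.0, 0.5, (Constraint("V50%", 40.0),)),
            StructureObjective("rectum", 20.0, 0.0, 0.7,
                               (Constraint("V50%", 50.0), Constraint("V80%", 20.0))),
        ))

    def names(self) -> list:
        return [s.name for s in self.structures]

    def to_yaml(self, path) -> None:
        doc = {"structures": [
            {"name": s.name, "weight": s.weight, "ideal_dose": s.ideal_dose,
             "scaling_factor": s.scaling_factor,
             "constraints": [{"metric": c.metric, "limit": c.limit}
                             for c in s.constraints]}
            for s in self.structures]}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ObjectiveSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(structures=tuple(
            StructureObjective(
                s["name"], float(s["weight"]), float(s["ideal_dose"]),
                float(s["scaling_factor"]),
                tuple(Constraint(c["metric"], float(c["limit"]))
                      for c in s.get("constraints", ())))
            for s in doc["structures"]))


@dataclass
class ObjectiveValue:
    """Total objective with its per-structure decomposition."""

    total: float
    terms: dict  # name -> w_i * MSE_i * f_i^{n_i}
    mse: dict  # name -> MSE_i
    n_satisfied: dict  # name -> n_i


_METRIC_RE = re.compile(
    r"^(?:(Dmean)|(Dmax)|(Dmin)|D(?P<dpct>[0-9.]+)%|D(?P<dcc>[0-9.]+)cc|V(?P<vpct>[0-9.]+)%)$")


def dvh_metric(dose: DoseGrid, mask: np.ndarray, metric: str,
               voxel_volume_mm3: float | None = None) -> float:
    """Evaluate a DVH metric over a structure on prescription-relative dose.

    Grammar: ``Dmean`` / ``Dmax`` / ``Dmin``; ``Dx%`` — the minimum dose
    received by the hottest x % of voxels; ``Dx.xcc`` — the minimum dose of
    the hottest x.x cm^3 (voxel volume from grid spacing unless overridden);
    ``VX%`` — the percent of structure volume receiving at least X % of the
    prescription.  D-metrics return prescription-relative dose, V-metrics
    percent volume.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty structure mask")
    d = np.asarray(dose.values)[mask]
    m = _METRIC_RE.match(metric)
    if m is None:
        raise ValueError(f"unknown DVH metric {metric!r}")
    if m.group(1):
        return float(d.mean())
    if m.group(2):
        return float(d.max())
    if m.group(3):
        return float(d.min())
    if m.group("dpct") is not None:
        x = float(m.group("dpct"))
        srt = np.sort(d)[::-1]
        k = max(int(np.ceil(x / 100.0 * d.size)), 1) - 1
        return float(srt[k])
    if m.group("dcc") is not None:
        cc = float(m.group("dcc"))
        if voxel_volume_mm3 is None:
            voxel_volume_mm3 = float(np.prod(dose.spacing))
        n_hot = max(int(np.ceil(cc * 1000.0 / voxel_volume_mm3)), 1)
        n_hot = min(n_hot, d.size)
        return float(np.sort(d)[::-1][n_hot - 1])
    x = float(m.group("vpct"))
    return float(100.0 * (d >= x / 100.0).mean())


def conformity_index(dose: DoseGrid, ptv_mask: np.ndarray) -> float:
    """CI: voxels anywhere receiving >= 95 % of prescription / PTV voxels."""
    ptv_mask = np.asarray(ptv_mask, dtype=bool)
    if not ptv_mask.any():
        raise ValueError("empty PTV mask")
    n_95 = int((np.asarray(dose.values) >= 0.95).sum())
    return n_95 / int(ptv_mask.sum())


def objective_value(dose: DoseGrid, phantom: Phantom,
                    spec: ObjectiveSpec | None = None) -> ObjectiveValue:
    """Constraint-scaled dose objective on a D95-anchored dose.

    Raises on un-anchored dose: normalization to 95 % target coverage is part
    of the objective's definition, not an optional preprocessing step.
    """
    if dose.normalization != "d95_anchored":
        raise ValueError("objective_value requires a d95_anchored DoseGrid; "
                         "apply normalize_d95 first")
    spec = spec or ObjectiveSpec.default()
    vox_vol = phantom.voxel_volume_mm3()
    terms, mses, ns = {}, {}, {}
    total = 0.0
    for s in spec.structures:
        mask = phantom.masks[s.name]
        d = np.asarray(dose.values)[mask]
        mse = float(np.mean((d - s.ideal_dose) ** 2))
        n_i = sum(c.satisfied(dvh_metric(dose, mask, c.metric, vox_vol))
                  for c in s.constraints)
        term = s.weight * mse * s.scaling_factor ** n_i
        terms[s.name], mses[s.name], ns[s.name] = term, mse, n_i
        total += term
    return ObjectiveValue(total=total, terms=terms, mse=mses, n_satisfied=ns)


def step_reward(v_old: ObjectiveValue, v_new: ObjectiveValue) -> float:
    """Reward of a transition: the decrease in objective value (old - new)."""
    return v_old.total - v_new.total
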