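"""Cohort plan evaluation and statistical comparison.

``evaluate_plan`` computes the clinically reported DVH metrics (Dmean, D2%,
D98%, D95%, Dmax in Gy; V40/50/80 % as percent of structure volume; PTV
conformity index) on the D95-anchored dose, converted to Gy with the
prescription.  ``compare_cohorts`` reports per-metric mean +/- SD for two
cohorts with a two-sided Wilcoxon rank-sum p-value — exact enumeration with
midrank ties for combined n <= 10, tie-corrected normal approximation
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from vmatrl.dose import BeamletBank, normalize_d95, plan_dose
from vmatrl.machine import MachineModel, Plan, check_deliverability
from vmatrl.objectives import ObjectiveSpec, conformity_index, dvh_metric, objective_value
from vmatrl.phantoms import Phantom

__all__ = ["PlanReport", "evaluate_plan", "compare_cohorts", "rank_sum_test",
           "reports_to_frame"]

# metric layout of the cohort table: structure -> metrics
_REPORT_METRICS = {
    "PTV": ("Dmean", "D2%", "D95%", "D98%", "Dmax"),
    "bladder": ("Dmean", "Dmax", "V50%"),
    "rectum": ("Dmean", "Dmax", "V50%", "V80%"),
    "femoral_head_L": ("Dmean", "V40%"),
    "femoral_head_R": ("Dmean", "V40%"),
}


@dataclass
class PlanReport:
    """Per-structure dose metrics of one evaluated plan."""

    patient_id: str
    metrics: dict  # (structure, metric) -> value; doses Gy, volumes %
    conformity: float
    constraint_flags: dict  # (structure, constraint label) -> bool
    n_satisfied: dict  # structure -> satisfied-constraint count
    objective: float
    deliverability: str

    def as_series(self) -> pd.Series:
        data = {f"{s} {m}": v for (s, m), v in self.metrics.items()}
        data["PTV CI"] = self.conformity
        data["objective"] = self.objective
        return pd.Series(data, name=self.patient_id)


def evaluate_plan(plan: Plan, phantom: Phantom, bank: BeamletBank,
                  spec: ObjectiveSpec | None = None,
                  machine: MachineModel | None = None) -> PlanReport:
    """Dose -> D95 anchor -> Gy conversion -> full metric table.

    A plan whose target cannot be anchored (e.g. all MUs zero) raises rather
    than returning silently-zero metrics.
    """
    spec = spec or ObjectiveSpec.default()
    machine = machine or MachineModel()
    raw = plan_dose(plan, bank)
    anchored, _ = normalize_d95(raw, phantom.masks["PTV"])
    rx = phantom.prescription_dose
    vox = phantom.voxel_volume_mm3()

    metrics = {}
    for struct, names in _REPORT_METRICS.items():
        if struct not in phantom.masks:
            continue
        mask = phantom.masks[struct]
        for m in names:
            val = dvh_metric(anchored, mask, m, vox)
            if not m.startswith("V"):
                val *= rx  # prescription-relative -> Gy
            metrics[(struct, m)] = float(val)

    obj = objective_value(anchored, phantom, spec)
    flags = {}
    for s in spec.structures:
        for c in s.constraints:
            val = dvh_metric(anchored, phantom.masks[s.name], c.metric, vox)
            flags[(s.name, c.label())] = bool(c.satisfied(val))
    report = check_deliverability(plan, machine)
    return PlanReport(patient_id=plan.patient_id, metrics=metrics,
                      conformity=conformity_index(anchored, phantom.masks["PTV"]),
                      constraint_flags=flags, n_satisfied=dict(obj.n_satisfied),
                      objective=obj.total, deliverability=report.summary())


def reports_to_frame(reports: list) -> pd.DataFrame:
    return pd.DataFrame([r.as_series() for r in reports])


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value with midrank ties.

    Combined n <= 10: exact enumeration of all assignments of the pooled
    midranks (p doubled from the smaller tail, capped at 1).  Larger samples:
    normal approximation with tie-corrected variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 1 or ny < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    w_obs = ranks[:nx].sum()
    n = nx + ny
    if n <= 10:
        total = 0
        le = 0
        ge = 0
        for idx in combinations(range(n), nx):
            w = ranks[list(idx)].sum()
            total += 1
            le += w <= w_obs + 1e-9
            ge += w >= w_obs - 1e-9
        p = 2.0 * min(le / total, ge / total)
        return float(min(p, 1.0))
    mu = nx * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / ((n) * (n - 1))
    var = nx * ny / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return 1.0
    z = (w_obs - mu) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def compare_cohorts(reports_a: list, reports_b: list) -> pd.DataFrame:
    """Per-metric cohort means +/- SD and rank-sum p-values.

    Requires >= 2 plans per cohort and identical metric sets.
    """
    if len(reports_a) < 2 or len(reports_b) < 2:
        raise ValueError("each cohort needs at least 2 plans")
    fa = reports_to_frame(reports_a)
    fb = reports_to_frame(reports_b)
    if set(fa.columns) != set(fb.columns):
        raise ValueError("cohorts report different metric sets")
    rows = []
    for col in fa.columns:
        a, b = fa[col].to_numpy(), fb[col].to_numpy()
        rows.append({
            "metric": col,
            "mean_a": a.mean(), "sd_a": a.std(ddof=1),
            "mean_b": b.mean(), "sd_b": b.std(ddof=1),
            "p_value": rank_sum_test(a, b),
        })
    return pd.DataFrame(rows).set_index("metric")
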