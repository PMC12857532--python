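"""The VMAT planning environment: states, incremental dose, episode rollouts.

The environment wraps one phantom + beamlet bank + working plan.  The MLC
agent edits one control point's apertures per step (sequential over the arc);
the MU agent rewrites all monitor units at once for a fixed number of global
refinement steps.  Rewards are decreases of the constraint-scaled dose
objective evaluated on the D95-anchored cumulative dose, so episode rewards
telescope to v(initial plan) - v(final plan).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from vmatrl.dose import (BeamletBank, DoseGrid, NormalizationError,
                         aperture_fractions, _aperture_dose, normalize_d95)
from vmatrl.machine import (ArcTemplate, MachineModel, Plan,
                            project_action_to_bounds)
from vmatrl.objectives import ObjectiveSpec, ObjectiveValue, objective_value
from vmatrl.phantoms import Phantom
from vmatrl.policies import TandemPolicy, sample_action

__all__ = ["Trajectory", "PlanningEnv", "run_mlc_episode", "run_mu_episode"]


@dataclass
class Trajectory:
    """Per-step records consumed by GAE / PPO."""

    vol_states: list = field(default_factory=list)
    vec_states: list = field(default_factory=list)
    actions: list = field(default_factory=list)
    log_probs: list = field(default_factory=list)
    values: list = field(default_factory=list)
    rewards: list = field(default_factory=list)
    dones: list = field(default_factory=list)

    def append(self, vol, vec, action, log_prob, value, reward, done) -> None:
        self.vol_states.append(vol)
        self.vec_states.append(vec)
        self.actions.append(np.asarray(action, dtype=float))
        self.log_probs.append(float(log_prob))
        self.values.append(float(value))
        self.rewards.append(reward)
        self.dones.append(1.0 if done else 0.0)

    def __len__(self) -> int:
        return len(self.rewards)

    def total_reward(self) -> float:
        return float(np.sum(self.rewards))

    def validate(self) -> None:
        n = len(self.rewards)
        if n == 0:
            raise ValueError("empty trajectory")
        fields = (self.vol_states, self.vec_states, self.actions, self.log_probs,
                  self.values, self.dones)
        if any(len(f) != n for f in fields):
            raise ValueError("trajectory field lengths differ")
        if self.dones[-1] != 1.0 or any(d != 0.0 for d in self.dones[:-1]):
            raise ValueError("trajectory must end with exactly one terminal step")


class PlanningEnv:
    """Dose bookkeeping and state construction for one phantom."""

    def __init__(self, phantom: Phantom, bank: BeamletBank, machine: MachineModel,
                 arc: ArcTemplate, spec: ObjectiveSpec | None = None):
        self.phantom = phantom
        self.bank = bank
        self.machine = machine
        self.arc = arc
        self.spec = spec or ObjectiveSpec.default()
        self.ptv_mask = phantom.masks["PTV"]
        self._ptv_ch = self.ptv_mask.astype(float)
        self._oar_ch = phantom.oar_union().astype(float)
        self.plan: Plan | None = None
        self._unit: np.ndarray | None = None  # (n_cp, *grid) Gy/MU per CP
        self._cum: np.ndarray | None = None

    # -- plan state ----------------------------------------------------------
    def reset(self, plan: Plan) -> None:
        self.plan = plan.copy()
        units = []
        for cp in self.plan.control_points:
            frac = aperture_fractions(cp, self.bank)
            units.append(_aperture_dose(frac, cp.angle, self.bank))
        self._unit = np.stack(units)
        self._cum = np.einsum("c,c...->...", self.plan.mus(), self._unit)

    def set_cp_leaves(self, index: int, leaves: np.ndarray) -> None:
        """Replace one CP's apertures, updating cumulative dose incrementally."""
        cp = self.plan.control_points[index]
        n = self.machine.leaf_pairs
        cp.leaf_x1, cp.leaf_x2 = leaves[:n].copy(), leaves[n:].copy()
        new_unit = _aperture_dose(aperture_fractions(cp, self.bank), cp.angle, self.bank)
        self._cum += cp.mu * (new_unit - self._unit[index])
        self._unit[index] = new_unit

    def set_all_mus(self, mus: np.ndarray) -> None:
        delta = np.asarray(mus, dtype=float) - self.plan.mus()
        self._cum += np.einsum("c,c...->...", delta, self._unit)
        for cp, mu in zip(self.plan.control_points, mus):
            cp.mu = float(mu)

    def raw_dose(self) -> DoseGrid:
        return DoseGrid(self._cum.copy(), spacing=tuple(self.phantom.spacing),
                        normalization="raw")

    def anchored_dose(self) -> DoseGrid:
        dose, _ = normalize_d95(self.raw_dose(), self.ptv_mask)
        return dose

    def objective(self) -> ObjectiveValue:
        """Objective of the current working plan (D95-anchored). May raise
        :class:`NormalizationError` for degenerate plans."""
        return objective_value(self.anchored_dose(), self.phantom, self.spec)

    # -- states --------------------------------------------------------------
    def _bev_align(self, values: np.ndarray, angle: float) -> np.ndarray:
        """Rotate a volume about the superior-inferior axis into the BEV frame."""
        if angle % 360.0 == 0.0:
            return values
        return ndimage.rotate(values, angle, axes=(0, 1), reshape=False,
                              order=1, mode="constant", cval=0.0)

    def _cp_vector(self, index: int) -> np.ndarray:
        cp = self.plan.control_points[index]
        leaves = cp.leaf_positions / self.machine.field_half_width
        return np.concatenate([leaves, [cp.mu / self.machine.max_mu_per_cp]])

    def mlc_state(self, index: int) -> tuple:
        """(3, *grid) volumetric + (53,) vector state for the MLC agent."""
        try:
            dose = self.anchored_dose().values
        except NormalizationError:
            dose = np.zeros(self.phantom.grid_shape)
        angle = self.plan.control_points[index].angle
        vol = np.stack([self._bev_align(dose, angle),
                        self._bev_align(self._ptv_ch, angle),
                        self._bev_align(self._oar_ch, angle)])
        return vol, self._cp_vector(index)

    def mu_state(self) -> tuple:
        """(3, *grid) volumetric + (53 * n_cp,) vector state for the MU agent."""
        try:
            dose = self.anchored_dose().values
        except NormalizationError:
            dose = np.zeros(self.phantom.grid_shape)
        vol = np.stack([dose, self._ptv_ch, self._oar_ch])
        vec = np.concatenate([self._cp_vector(i) for i in range(self.plan.n_cp)])
        return vol, vec


def _fill_degenerate(rewards: list) -> list:
    """Assign the episode's worst reward to steps whose proposal was rejected."""
    valid = [r for r in rewards if r is not None]
    worst = min(valid) if valid else 0.0
    return [worst if r is None else r for r in rewards]


def run_mlc_episode(plan: Plan, policy: TandemPolicy, env: PlanningEnv,
                    rng: np.random.Generator | None = None,
                    sample: bool = True) -> tuple:
    """Sequentially re-aperture every control point with the MLC policy.

    Actions live in the network's tanh space (-1, 1) and map linearly to
    +/- field half-width; samples are repaired to per-CP validity before dose
    computation while the stored action (and its log-probability) stays
    unprojected.  Returns ``(Trajectory, updated plan)``.
    """
    env.reset(plan)
    machine = env.machine
    v_prev = env.objective()
    traj = Trajectory()
    mode = "train" if sample else "infer"
    n_cp = env.plan.n_cp
    for t in range(n_cp):
        vol, vec = env.mlc_state(t)
        out = policy(vol[None], vec[None])
        action, log_prob = sample_action(out, mode, rng)
        value = float(np.ravel(out.value.data)[0])
        leaves = project_action_to_bounds(action * machine.field_half_width, machine)
        old = env.plan.control_points[t].leaf_positions
        env.set_cp_leaves(t, leaves)
        try:
            v_new = env.objective()
            reward = v_prev.total - v_new.total
            v_prev = v_new
        except NormalizationError:
            env.set_cp_leaves(t, old)  # discard the degenerate proposal
            reward = None
        traj.append(vol, vec, action, log_prob, value, reward, done=(t == n_cp - 1))
    traj.rewards = _fill_degenerate(traj.rewards)
    traj.validate()
    return traj, env.plan.copy()


def run_mu_episode(plan: Plan, policy: TandemPolicy, env: PlanningEnv,
                   rng: np.random.Generator | None = None, steps: int = 8,
                   sample: bool = True) -> tuple:
    """Globally refine all monitor units for ``steps`` iterations (default 8).

    The policy acts as a segment-weight optimizer: each step samples the full
    MU vector, recomputes cumulative dose, and is rewarded by the objective
    decrease.  Proposals that leave the target without anchorable dose are
    discarded and assigned the episode's worst reward.
    """
    env.reset(plan)
    v_prev = env.objective()
    traj = Trajectory()
    mode = "train" if sample else "infer"
    for t in range(steps):
        vol, vec = env.mu_state()
        out = policy(vol[None], vec[None])
        action, log_prob = sample_action(out, mode, rng)
        value = float(np.ravel(out.value.data)[0])
        # actions are MU fractions of the per-CP cap (the softplus head keeps
        # the mean positive); negative noise excursions are floored at zero
        mus = np.clip(action, 0.0, None) * env.machine.max_mu_per_cp
        old = env.plan.mus()
        env.set_all_mus(mus)
        try:
            v_new = env.objective()
            reward = v_prev.total - v_new.total
            v_prev = v_new
        except NormalizationError:
            env.set_all_mus(old)
            reward = None
        traj.append(vol, vec, action, log_prob, value, reward, done=(t == steps - 1))
    traj.rewards = _fill_degenerate(traj.rewards)
    traj.validate()
    return traj, env.plan.copy()
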