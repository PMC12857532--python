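"""GAE, the clipped PPO objective, behavioral cloning, and the training loops.

Training is a nested loop: per iteration, for every patient, the MLC policy
runs one sequential aperture episode and is updated by PPO from its own
trajectory; then the MU policy runs its 8 global monitor-unit refinement
steps and is updated likewise.  Each patient keeps a progressively improving
baseline plan: the episode's final plan replaces it only on strict objective
improvement.  Inference is deterministic (mean actions) and alternates
MLC/MU passes until the plan stops improving, capped at 8 outer iterations.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from vmatrl.dose import BeamletBank, precompute_beamlets, KernelParams
from vmatrl.envs import PlanningEnv, Trajectory, run_mlc_episode, run_mu_episode
from vmatrl.machine import (ArcTemplate, ControlPoint, MachineModel, Plan,
                            build_arc_template, check_deliverability,
                            make_deliverable, project_action_to_bounds)
from vmatrl.nn import Adam, Tensor, minimum
from vmatrl.objectives import ObjectiveSpec
from vmatrl.phantoms import Phantom, generate_expert_demos
from vmatrl.policies import (TandemPolicy, build_network, gaussian_log_prob,
                             policy_entropy)

__all__ = ["TrainConfig", "AdvantageSet", "TrainResult", "compute_gae",
           "normalize_advantages", "ppo_loss", "ppo_update", "behavioral_cloning",
           "expert_plan", "train", "infer", "TrainingDiverged"]


class TrainingDiverged(RuntimeError):
    """The objective ran away for several consecutive iterations."""


@dataclass
class TrainConfig:
    """Hyperparameters; RL constants follow the published configuration.

    ``iterations``/``il_epochs`` default to the desk-scale values; the
    full-scale counterparts are 2000 RL iterations and 500 IL epochs.
    """

    gamma: float = 0.99
    lam: float = 0.95
    clip_eps: float = 0.15
    c1: float = 0.45
    c2: float = 0.005
    mu_steps: int = 8
    iterations: int = 50
    il_epochs: int = 50
    lr: float = 1e-4
    mu_lr: float = 1e-3  # the 24-172-dim MU head tolerates larger steps
    ppo_epochs: int = 4
    minibatch: int = 64
    grad_clip: float = 1.0
    reward_scale: float = 0.1
    reward_clip: float = 10.0
    seed: int = 0
    scale: str = "toy"
    expert_margin_cm: float = 0.3
    infer_max_outer: int = 8
    divergence_factor: float = 10.0
    divergence_patience: int = 5

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma <= 1.0 and 0.0 < self.lam <= 1.0):
            raise ValueError("gamma and lambda must lie in (0, 1]")
        if self.clip_eps <= 0:
            raise ValueError("clip epsilon must be positive")
        if min(self.mu_steps, self.iterations, self.il_epochs, self.ppo_epochs) < 1:
            raise ValueError("step counts must be >= 1")


@dataclass
class AdvantageSet:
    """Per-step advantages and returns (G_t = A_t + V_old(s_t) pre-normalization)."""

    advantages: np.ndarray
    returns: np.ndarray
    mean: float = 0.0
    std: float = 1.0


def compute_gae(traj, gamma: float = 0.99, lam: float = 0.95) -> AdvantageSet:
    """Generalized advantage estimation by backward recursion.

    delta_t = r_t + gamma * (1 - d_t) * V_{t+1} - V_t  (V past the terminal
    step is 0); A_t = delta_t + gamma * lam * (1 - d_t) * A_{t+1};
    G_t = A_t + V_t.  ``traj`` is a Trajectory or an (rewards, values, dones)
    triple of equal-length arrays.
    """
    if isinstance(traj, Trajectory):
        rewards, values, dones = traj.rewards, traj.values, traj.dones
    else:
        rewards, values, dones = traj
    r = np.asarray(rewards, dtype=float)
    v = np.asarray(values, dtype=float)
    d = np.asarray(dones, dtype=float)
    n = r.size
    if n == 0:
        raise ValueError("empty trajectory")
    v_next = np.append(v[1:], 0.0)
    delta = r + gamma * (1.0 - d) * v_next - v
    adv = np.empty(n)
    running = 0.0
    for t in range(n - 1, -1, -1):
        running = delta[t] + gamma * lam * (1.0 - d[t]) * running
        adv[t] = running
    return AdvantageSet(advantages=adv, returns=adv + v)


def normalize_advantages(adv: np.ndarray) -> tuple:
    """Standardize an advantage batch; returns (normalized, mean, std)."""
    adv = np.asarray(adv, dtype=float)
    mean = float(adv.mean())
    std = float(adv.std())
    if adv.size < 2 or std < 1e-12:
        return adv - mean, mean, 1.0
    return (adv - mean) / std, mean, std


def ppo_loss(new_log_prob: Tensor, old_log_prob: np.ndarray, advantages: np.ndarray,
             new_values: Tensor, returns: np.ndarray, entropy: Tensor,
             cfg: TrainConfig) -> tuple:
    """Clipped-surrogate PPO objective (to be maximized).

        L = E[ min(R A, clip(R, 1-eps, 1+eps) A) ] - c1 E[(V - G)^2] + c2 E[S]

    with R the importance ratio exp(log pi_new - log pi_old).  Returns
    ``(objective Tensor, components dict)``; training minimizes the negative.
    """
    adv = Tensor(np.asarray(advantages, dtype=float))
    ratio = (new_log_prob - Tensor(np.asarray(old_log_prob, dtype=float))).exp()
    surr = minimum(ratio * adv, ratio.clip(1.0 - cfg.clip_eps, 1.0 + cfg.clip_eps) * adv)
    l_clip = surr.mean()
    values = new_values.reshape(-1) if new_values.ndim > 1 else new_values
    l_vf = ((values - Tensor(np.asarray(returns, dtype=float))) ** 2).mean()
    s = entropy.mean() if entropy.ndim > 0 else entropy
    objective = l_clip - cfg.c1 * l_vf + cfg.c2 * s
    components = {"l_clip": float(l_clip.data), "l_vf": float(l_vf.data),
                  "entropy": float(s.data), "objective": float(objective.data)}
    if any(np.isnan(val) for val in components.values()):
        raise FloatingPointError(f"NaN in PPO loss components: {components}")
    return objective, components


def ppo_update(policy: TandemPolicy, optimizer: Adam, traj: Trajectory,
               cfg: TrainConfig, rng: np.random.Generator) -> dict:
    """One PPO update (several epochs of minibatch ascent) from a trajectory."""
    traj.validate()
    # rewards are scaled and clipped before GAE so value-regression targets
    # stay numerically comparable to the surrogate term (degenerate plans can
    # produce objective excursions orders of magnitude above the baseline);
    # trajectories keep the raw telescoping rewards
    r = np.asarray(traj.rewards, dtype=float) * cfg.reward_scale
    r = np.clip(r, -cfg.reward_clip, cfg.reward_clip)
    adv_set = compute_gae((r, traj.values, traj.dones), cfg.gamma, cfg.lam)
    adv_norm, mu, sd = normalize_advantages(adv_set.advantages)
    vols = np.stack(traj.vol_states)
    vecs = np.stack(traj.vec_states)
    actions = np.stack(traj.actions)
    old_logp = np.asarray(traj.log_probs)
    returns = adv_set.returns
    n = len(traj)
    policy.train(True)
    last = {}
    for _ in range(cfg.ppo_epochs):
        perm = rng.permutation(n)
        for start in range(0, n, cfg.minibatch):
            mb = perm[start:start + cfg.minibatch]
            out = policy(vols[mb], vecs[mb])
            logp = gaussian_log_prob(out.mean, out.log_std, actions[mb])
            ent = policy_entropy(out.log_std)
            objective, last = ppo_loss(logp, old_logp[mb], adv_norm[mb],
                                       out.value, returns[mb], ent, cfg)
            loss = -objective
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
    policy.train(False)
    last["adv_mean"], last["adv_std"] = mu, sd
    return last


def expert_plan(phantom: Phantom, arc: ArcTemplate, machine: MachineModel,
                margin_cm: float = 0.3, mu_fraction: float = 0.5) -> Plan:
    """Conformal expert plan: silhouette apertures + uniform per-CP MU."""
    demo = generate_expert_demos(phantom, arc, machine, margin_cm=margin_cm)
    mu0 = mu_fraction * machine.max_mu_per_cp
    cps = [ControlPoint.from_leaf_vector(angle, demo.apertures[i], mu0)
           for i, angle in enumerate(arc.angles())]
    return Plan(control_points=cps, patient_id=phantom.patient_id)


def behavioral_cloning(policy: TandemPolicy, envs: list, plans: list,
                       targets: list, cfg: TrainConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """Initialize the MLC policy by imitation of the conformal expert.

    States are rolled out from the expert plans and from aperture/MU-jittered
    variants of them (the conformal expert target depends only on geometry,
    so the relabelled targets stay exact; the jittered states guard against
    distribution shift once the policy rolls its own plans).  The MSE between
    the tanh mean head and the expert apertures (normalized to the tanh
    range) is minimized with Adam.  Returns the per-epoch loss curve.
    """
    vols, vecs, tgts = [], [], []
    for env, plan, target in zip(envs, plans, targets):
        variants = [plan]
        for _ in range(2):
            jit = plan.copy()
            for cp in jit.control_points:
                noise = 0.2 * rng.standard_normal(cp.leaf_positions.size)
                leaves = project_action_to_bounds(cp.leaf_positions + noise,
                                                  env.machine)
                n = env.machine.leaf_pairs
                cp.leaf_x1, cp.leaf_x2 = leaves[:n], leaves[n:]
                cp.mu = float(cp.mu * np.exp(0.1 * rng.standard_normal()))
            variants.append(jit)
        for variant in variants:
            env.reset(variant)
            for t in range(plan.n_cp):
                vol, vec = env.mlc_state(t)
                vols.append(vol)
                vecs.append(vec)
                tgts.append(np.clip(target[t] / env.machine.field_half_width,
                                    -0.99, 0.99))
    vols = np.stack(vols)
    vecs = np.stack(vecs)
    tgts = np.stack(tgts)
    optimizer = Adam(policy.parameters(), lr=1e-3, grad_clip_norm=cfg.grad_clip)
    curve = np.empty(cfg.il_epochs)
    policy.train(True)
    n = vols.shape[0]
    for epoch in range(cfg.il_epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.minibatch):
            mb = perm[start:start + cfg.minibatch]
            out = policy(vols[mb], vecs[mb])
            loss = ((out.mean - Tensor(tgts[mb])) ** 2).mean()
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data) * len(mb)
        curve[epoch] = epoch_loss / n
    policy.train(False)
    return curve


@dataclass
class TrainResult:
    mlc_policy: TandemPolicy
    mu_policy: TandemPolicy
    history: pd.DataFrame
    best_state: dict
    best_iteration: int
    baselines: list
    bc_curve: np.ndarray


def _patient_setup(phantom: Phantom, arc: ArcTemplate, machine: MachineModel,
                   spec: ObjectiveSpec, cfg: TrainConfig,
                   bank: BeamletBank | None, kernel: KernelParams | None):
    bank = bank or precompute_beamlets(phantom, arc, machine, kernel)
    env = PlanningEnv(phantom, bank, machine, arc, spec)
    plan = expert_plan(phantom, arc, machine, margin_cm=cfg.expert_margin_cm)
    return env, plan


def train(phantoms: list, cfg: TrainConfig | None = None,
          machine: MachineModel | None = None, arc: ArcTemplate | None = None,
          spec: ObjectiveSpec | None = None, banks: list | None = None,
          kernel: KernelParams | None = None) -> TrainResult:
    """Full tandem training run on a cohort of phantoms.

    Behavioral cloning initializes the MLC network from conformal expert
    apertures; the BC policy's own deterministic predictions then seed each
    patient's baseline plan.  The per-iteration log records the mean total
    plan reward (summed episode rewards), the mean baseline objective, and
    the mean satisfied-constraint count of the baselines; the
    parameters with the best mean total plan reward are retained as the
    checkpoint.  Raises :class:`TrainingDiverged` when the mean objective
    exceeds ``divergence_factor`` x its initial value for
    ``divergence_patience`` consecutive iterations.
    """
    cfg = cfg or TrainConfig()
    machine = machine or MachineModel()
    arc = arc or build_arc_template()
    spec = spec or ObjectiveSpec.default()
    rng = np.random.default_rng(cfg.seed)

    envs, plans = [], []
    for i, ph in enumerate(phantoms):
        bank = banks[i] if banks is not None else None
        env, plan = _patient_setup(ph, arc, machine, spec, cfg, bank, kernel)
        envs.append(env)
        plans.append(plan)

    grid = tuple(phantoms[0].grid_shape)
    mlc = build_network("mlc", cfg.scale, vol_shape=grid, n_cp=arc.n_cp,
                        leaf_pairs=machine.leaf_pairs, seed=cfg.seed)
    mu_net = build_network("mu", cfg.scale, vol_shape=grid, n_cp=arc.n_cp,
                           leaf_pairs=machine.leaf_pairs, seed=cfg.seed + 1)
    opt_mlc = Adam(mlc.parameters(), lr=cfg.lr, grad_clip_norm=cfg.grad_clip)
    opt_mu = Adam(mu_net.parameters(), lr=cfg.mu_lr, grad_clip_norm=cfg.grad_clip)

    bc_curve = behavioral_cloning(
        mlc, envs, plans, [_aperture_matrix(p) for p in plans], cfg, rng)

    # IL-predicted plans become the initial RL baselines
    baselines, base_obj, base_nsat = [], [], []
    for env, plan in zip(envs, plans):
        _, predicted = run_mlc_episode(plan, mlc, env, sample=False)
        try:
            env.reset(predicted)
            ov = env.objective()
            baselines.append(predicted)
        except Exception:
            env.reset(plan)
            ov = env.objective()
            baselines.append(plan)
        base_obj.append(ov.total)
        base_nsat.append(sum(ov.n_satisfied.values()))

    initial_mean_obj = float(np.mean(base_obj))
    rows = []
    best_reward = -np.inf
    best_state: dict = {}
    best_iteration = -1
    diverged_streak = 0
    for it in range(cfg.iterations):
        totals = []
        for pi, env in enumerate(envs):
            traj_mlc, plan_mlc = run_mlc_episode(baselines[pi], mlc, env, rng)
            ppo_update(mlc, opt_mlc, traj_mlc, cfg, rng)
            traj_mu, plan_mu = run_mu_episode(plan_mlc, mu_net, env, rng,
                                              steps=cfg.mu_steps)
            ppo_update(mu_net, opt_mu, traj_mu, cfg, rng)
            total = traj_mlc.total_reward() + traj_mu.total_reward()
            totals.append(total)
            try:
                env.reset(plan_mu)
                cand_ov = env.objective()
                cand = cand_ov.total
            except Exception:
                cand_ov, cand = None, np.inf
            if cand < base_obj[pi]:  # strict improvement replaces the baseline
                baselines[pi] = plan_mu
                base_obj[pi] = cand
                base_nsat[pi] = sum(cand_ov.n_satisfied.values())
        mean_reward = float(np.mean(totals))
        mean_obj = float(np.mean(base_obj))
        rows.append({"iteration": it, "mean_total_reward": mean_reward,
                     "mean_objective": mean_obj,
                     "mean_constraints_met": float(np.mean(base_nsat))})
        if mean_reward > best_reward:
            best_reward = mean_reward
            best_state = {"mlc": copy.deepcopy(mlc.state_dict()),
                          "mu": copy.deepcopy(mu_net.state_dict())}
            best_iteration = it
        if mean_obj > cfg.divergence_factor * max(initial_mean_obj, 1e-12):
            diverged_streak += 1
            if diverged_streak >= cfg.divergence_patience:
                raise TrainingDiverged(
                    f"mean objective {mean_obj:.3g} exceeded "
                    f"{cfg.divergence_factor}x initial for "
                    f"{cfg.divergence_patience} consecutive iterations")
        else:
            diverged_streak = 0

    history = pd.DataFrame(rows)
    return TrainResult(mlc_policy=mlc, mu_policy=mu_net, history=history,
                       best_state=best_state, best_iteration=best_iteration,
                       baselines=baselines, bc_curve=bc_curve)


def _aperture_matrix(plan: Plan) -> np.ndarray:
    return np.stack([cp.leaf_positions for cp in plan.control_points])


def infer(phantom: Phantom, mlc: TandemPolicy, mu_net: TandemPolicy,
          cfg: TrainConfig | None = None, machine: MachineModel | None = None,
          arc: ArcTemplate | None = None, spec: ObjectiveSpec | None = None,
          bank: BeamletBank | None = None,
          kernel: KernelParams | None = None,
          start_plan: Plan | None = None) -> Plan:
    """Deterministic plan generation with trained networks.

    Alternates a sequential MLC pass and the global MU refinement using mean
    actions, projecting each candidate onto the deliverable set before
    scoring; the loop stops when the total plan objective fails to strictly
    improve and is hard-capped at ``infer_max_outer`` (default 8) passes.
    ``start_plan`` overrides the initial state (for a training-cohort patient
    this is the patient's improving baseline; default is the IL-style
    conformal start).  The returned plan has an empty deliverability report.
    """
    cfg = cfg or TrainConfig()
    machine = machine or MachineModel()
    arc = arc or build_arc_template()
    spec = spec or ObjectiveSpec.default()
    env, plan = _patient_setup(phantom, arc, machine, spec, cfg, bank, kernel)
    if start_plan is not None:
        plan = start_plan
    plan = make_deliverable(plan, machine)
    env.reset(plan)
    best_obj = env.objective().total
    best_plan = plan

    def _passes(start):
        _, after_mlc = run_mlc_episode(start, mlc, env, sample=False)
        _, after_mu = run_mu_episode(after_mlc, mu_net, env, steps=cfg.mu_steps,
                                     sample=False)
        _, mu_only = run_mu_episode(start, mu_net, env, steps=cfg.mu_steps,
                                    sample=False)
        return (after_mlc, after_mu, mu_only)

    for _ in range(cfg.infer_max_outer):
        improved = False
        for cand in _passes(best_plan):
            cand = make_deliverable(cand, machine)
            try:
                env.reset(cand)
                obj = env.objective().total
            except Exception:
                continue
            if obj < best_obj:  # monotone acceptance of the best stage
                best_obj, best_plan = obj, cand
                improved = True
        if not improved:
            break
    report = check_deliverability(best_plan, machine)
    if not report.ok:
        best_plan = make_deliverable(best_plan, machine)
    return best_plan
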