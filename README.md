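# vmatrl

Tandem-policy reinforcement learning for VMAT machine-parameter
optimization, on synthetic pelvic phantoms with an analytic beamlet dose
engine.

Volumetric modulated arc therapy (VMAT) delivers radiation continuously
while the gantry rotates; planning means choosing, for every control point
(CP) of the arc, the 52 multi-leaf-collimator (MLC) positions and the
monitor units (MU) so that the target (PTV) is covered and organs at risk
(bladder, rectum, femoral heads) are spared.  `vmatrl` casts this machine
parameter optimization as a Markov decision process solved by two
cooperating Gaussian policies trained with proximal policy optimization
(PPO):

* the **MLC network** steps through the arc, re-aperturing one CP per step;
* the **MU network** acts as a segment-weight optimizer, rewriting all
  per-CP MUs for 8 refinement steps per episode.

Each step is rewarded by the decrease of a constraint-scaled dose objective
computed on dose normalized to 95 % target coverage:

    v = Σ_i  w_i · MSE_i · f_i^{n_i}

where `MSE_i` is the per-voxel mean squared deviation from the structure's
ideal dose (1.0 PTV, 0.0 OARs), and each satisfied dose-volume constraint
(PTV D2.0 cm³ < 135 %, bladder V50 % < 40 %, rectum V50 % < 50 % and
V80 % < 20 %) multiplies that structure's term by its factor f < 1
(0.75 / 0.5 / 0.7).  Advantages use generalized advantage estimation
(γ = 0.99, λ = 0.95); the PPO loss is the clipped surrogate (ε = 0.15)
minus a value-regression term (c₁ = 0.45) plus an entropy bonus
(c₂ = 0.005).  The MLC network is initialized by behavioral cloning of a
conformal-aperture expert; per patient, the best plan found so far serves
as a progressively improving baseline.  Everything runs on seeded synthetic
phantoms — no external data.

The policy networks (residual 3D convolutions + multi-head self-attention,
with tanh / softplus / linear heads), their reverse-mode autodiff, and the
Adam optimizer are implemented in-package on numpy.

See `docs/methods.md` for the model, parameters, and limitations.

## Worked example

```python
import numpy as np
from vmatrl import (generate_phantom, build_arc_template, precompute_beamlets,
                    plan_dose, normalize_d95, objective_value, gamma_pass_rate)
from vmatrl.machine import MachineModel, check_deliverability
from vmatrl.training import TrainConfig, train, infer, expert_plan
from vmatrl.evaluation import evaluate_plan

phantoms = [generate_phantom(s, "toy") for s in (1, 2)]
arc = build_arc_template(15.0, gap=None)            # 24-CP toy arc
machine = MachineModel(field_half_width=6.5, cp_delivery_time=3.75)

cfg = TrainConfig(iterations=50, il_epochs=50, seed=0)
result = train(phantoms, cfg, machine=machine, arc=arc)
print(result.history.tail(1))

plan = infer(phantoms[0], result.mlc_policy, result.mu_policy, cfg,
             machine=machine, arc=arc, start_plan=result.baselines[0])
bank = precompute_beamlets(phantoms[0], arc, machine)
report = evaluate_plan(plan, phantoms[0], bank, machine=machine)
print(report.metrics[("PTV", "D95%")], report.deliverability)
```

A run of this example printed:

```
    iteration  mean_total_reward  mean_objective
49         49         -11.074621        4.719904
36.24999999999999 deliverable (no violations)
```

The mean objective fell from 7.00 to 4.72 over the 50 iterations; the
generated plan's PTV D95 is the 36.25 Gy prescription (by construction of
the coverage anchoring), the plan satisfies the machine's leaf-speed and
dose-rate limits, and `report.constraint_flags` shows all four dose-volume
constraints met on this phantom.  `vmatrl.plots.plot_dvh` draws the
cumulative DVH.

The full arc geometry (2° spacing with the 4–23° cryostat gap, 172 CPs),
the gamma comparison (3 %/2 mm, 10 % threshold), and the cohort statistics
(Wilcoxon rank-sum) are available through the same modules or the `vmatrl`
command line (`vmatrl phantom`, `precompute`, `dose`, `gamma`, `train`,
`plan`, `eval`, `compare`, `net summary`).

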