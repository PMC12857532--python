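# Methods

`vmatrl` implements tandem-policy reinforcement learning for VMAT machine
parameter optimization (MPO) on synthetic pelvic phantoms.  Two cooperating
stochastic policies — an MLC network that sets the 52 leaf positions of one
control point (CP) at a time, and an MU network that rewrites all per-CP
monitor units at once — are trained with clipped-surrogate PPO against a
DVH-constraint-driven dose objective, after a behavioral-cloning warm start
from a conformal-aperture expert.

## Anatomy and machine model

Phantoms are labeled voxel masks on a regular grid: a central ellipsoidal
PTV (prostate-like, prescription 36.25 Gy in 5 fractions), an
anterior-superior bladder, a posterior rectum elongated along the
superior-inferior axis, and two lateral femoral heads.  Organ semi-axes
jitter by ±20 % and centroids by up to ±10 mm per seed; OAR masks are made
disjoint from the PTV so that per-structure ideal doses (1.0 for the PTV,
0.0 for OARs) stay meaningful.  Two size classes exist: `toy`
(16³ voxels at 8 mm — coarse but fast enough for CPU training loops) and
`standard` (48×48×32 at 5 mm isotropic).

The delivery machine is MR-linac-like: 26 central leaf pairs of 0.71 cm
projected width, 6 cm/s maximum leaf speed, 425 MU/min maximum dose rate.
A single arc has CPs every 2° with the 4–23° cryostat gap excluded; the gap
convention removes the eight even angles 6–20° (delivery retained at the
4° and 22° grid angles adjacent to the gap edges), which is the unique
even-spacing reading consistent with a 172-CP arc.  Toy configurations use a
24-CP arc (15° spacing, no gap) with the per-CP delivery time scaled
accordingly (3.75 s) so that leaf-speed and MU-rate limits remain physical.

## Dose engine

Each CP angle is a parallel beam decomposed into beamlets on a (leaf pair) ×
(travel bin) grid.  A beamlet deposits

    dose(v) = C · exp(−μ · depth(v)) · P_u(u_v) · P_z(z_v)

with μ = 0.005 mm⁻¹, depth the distance from the voxel to the phantom
surface toward the source, and P_u, P_z rectangular profiles convolved with
a Gaussian penumbra (σ = 3 mm, error-function edges).  C is calibrated so a
broad open field delivers 2 Gy per 100 MU at 10 cm depth.  Because the
three factors separate by coordinate, the beamlet bank stores them
factorized (per-angle attenuation and travel profiles, shared leaf-pair
profiles); composing an aperture is two small tensor contractions and dose
is exactly linear in MU and in per-beamlet open fractions — the
superposition structure the RL reward relies on.  Leaves crossing a travel
bin credit it by linear overlap fraction.  Heterogeneity, Monte Carlo
transport, and magnetic-field dose effects are out of scope.

An optional angular-blending mode supports beamlet banks coarser than the
CP spacing: a CP's fluence is split across its two nearest precomputed
angles with weights linear in angular distance.  It is off by default (the
bank is computed at the CP angles, where blending reduces to plain
summation).

Dose comparison uses a global 3 %/2 mm gamma index with a 10 % low-dose
threshold and an exhaustive neighborhood search within 3× the distance
criterion.

## Objective, constraints, reward

Doses are normalized so the PTV D95 equals the prescription (D95 computed
from the sorted PTV voxel doses without interpolation — the largest dose
received by at least 95 % of PTV voxels).  The plan objective is

    v = Σ_i  w_i · MSE_i · f_i^{n_i}

with per-structure weights w (PTV 50, bladder 20, rectum 20), per-voxel
mean squared deviation from the ideal dose, and a multiplicative bonus
factor f per satisfied dose-volume constraint: PTV D2.0 cm³ < 135 %
(f = 0.75), bladder V50 % < 40 % (f = 0.5), rectum V50 % < 50 % and
V80 % < 20 % (f = 0.7, applied once per satisfied constraint).  Constraint
comparisons are strict; ties count as unmet.  The step reward is the
objective decrease, so rewards telescope over an episode to
v(initial) − v(final).  Femoral heads are evaluated but carry no reward
term.

## Networks

Both policies share one topology: a residual 3D-convolution encoder over a
3-channel volumetric state, a multi-head self-attention encoder over the
machine-parameter vector (treated as a token sequence), a shared dense
trunk, and three heads — action means (tanh for the bounded MLC positions,
softplus for the positive MUs), action log standard deviations, and a
scalar value estimate.  Convolutions are separated by batch normalization
and ReLU, dense layers by layer normalization.  The MLC state is the
BEV-aligned cumulative dose plus PTV and OAR masks with a 53-vector (52
leaves + MU) for the current CP; the MU state is the unrotated dose and
masks with the full 53 × n_CP vector.  BEV alignment is implemented as a
rotation-resample of the state channels about the superior-inferior axis.
Capacity presets (`toy`, `paper`-shaped) change filter counts only; the
topology and head activations are fixed.

The networks, their autodiff, and Adam are implemented in-package on numpy
(reverse-mode tensor engine, gradient-checked against central differences).

Numerical choices that matter:

* Batch normalization always normalizes by running statistics (updated only
  during optimization passes).  Episode rollouts process one state at a
  time, where batch statistics are degenerate, and the PPO importance-ratio
  contract (new policy = old policy ⇒ R = 1) requires rollout and update
  forwards to agree.
* Log-stds are clamped to [−5, 0].  Initial exploration scales are set to
  the machine's sensitivity: σ ≈ e⁻⁴ for MLC actions (≈1 mm leaf jitter
  after scaling to the field half-width) and σ ≈ e⁻²·⁵ for the smooth MU
  fractions (≈8 % modulation).  Larger leaf noise destroys plans faster
  than the advantage signal can rank steps, and training destabilizes.
* Mean heads are small-initialized (×0.1) so untrained policies emit
  near-neutral actions (centred apertures, near-uniform MUs).

## Training

Behavioral cloning fits the MLC mean head to a conformal expert: per CP,
each leaf pair opens to the PTV silhouette projected into the isocenter
plane, grown by a 3 mm margin.  BC data also includes states from
aperture/MU-jittered variants of the expert plans (targets unchanged —
the conformal target depends only on geometry), which reduces the
distribution shift once the policy rolls its own plans.  MU values start
uniform at half the per-CP cap; D95 anchoring removes the global scale.

RL then runs the nested loop: per iteration, per patient, one sequential
MLC episode (sampled actions; invalid samples are repaired by clipping and
midpoint-closing crossed pairs, while the stored log-probability is of the
unprojected sample), one 8-step global MU episode, and a PPO update per
network from its own trajectory (γ = 0.99, λ = 0.95, ε = 0.15, c₁ = 0.45,
c₂ = 0.005, batch-normalized advantages, 4 epochs of minibatch ascent with
Adam and gradient-norm clipping).  A patient's baseline plan is replaced
only on strict objective improvement — the progressively improving
baseline doubles as a stochastic accept/reject search that retains lucky
episodes.  Rewards fed to GAE are uniformly scaled (×0.1) and clipped
(±10) so value-regression targets stay comparable to the surrogate term;
degenerate proposals (no anchorable PTV dose) are discarded and assigned
the episode's worst reward.  Trajectory rewards themselves stay raw, so
telescoping holds exactly.  The MU optimizer uses a larger step size
(10⁻³ vs 10⁻⁴): its action is low-dimensional and the dose response to MU
changes is smooth, and in practice it learns the transferable pattern
(e.g. lowering posterior-arc MUs to spare the rectum) much faster than the
MLC head learns aperture sculpting.

Inference is deterministic (mean actions) and alternates an MLC pass, an
MU refinement, and an MU-only refinement of the incumbent, keeping the best
deliverable plan at each stage and stopping when nothing improves, capped
at 8 outer iterations.  Plans are projected onto the deliverable set
(global MU rescale to the dose-rate cap; alternating leaf-travel /
non-crossing clipping sweeps) before scoring, so returned plans always pass
the deliverability check.

## Desk-scale study conditions

The shipped training configuration is deliberately small: cohorts of 2 toy
phantoms, 24 CPs, 50 RL iterations, 50 BC epochs, toy network capacities.
At this scale the MLC policy cannot learn transferable aperture sculpting
(the full-scale configuration this emulates trained 2000 iterations on 70
patients); plan improvement comes from the improving-baseline search, the
BC prior, and the MU network's learned modulation.  Tests passing at this
scale demonstrate the correctness of the mechanism — oracle-exact GAE and
PPO terms, telescoping rewards, constraint-factor jumps, deliverable
output — not clinical plan quality on real anatomy.  The synthetic
phantoms also omit CT heterogeneity, realistic organ shapes, and
inter-fraction variation; conclusions about real patients require the
full-scale engine and cohort.

## Known limitations

* The conformal expert is a geometric stand-in for clinical reference
  plans; its apertures ignore OARs entirely.
* The analytic beamlet engine has no scatter kernel beyond the Gaussian
  penumbra and no cryostat attenuation.
* The exact "field-edge distance" weighting of the original VMAT adaptation
  is not recoverable from its description; the linear angular-distance
  blend implemented here is one reasonable reading and is off by default.
* Wilcoxon rank-sum p-values use exact enumeration with midranks only up to
  combined n = 10, then a tie-corrected normal approximation.
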