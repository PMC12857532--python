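"""Tandem MLC / MU actor-critic policy networks.

Both networks share one topology: a residual 3D-convolution encoder for the
volumetric state channels, a multi-head self-attention encoder over the
machine-parameter vector (treated as a token sequence), a shared dense trunk,
and three heads — action means, action log standard deviations, and a scalar
value estimate.  The MLC network's mean head is tanh-squashed (leaf positions
are bounded; the (-1, 1) output maps linearly to +/- field half-width), the
MU network's mean head is softplus (monitor units are positive); log-std and
value heads are linear.  Actor and critic share the trunk and differ only in
their output layers.

State contracts
---------------
* MLC state: 3-channel volumetric tensor (BEV-aligned cumulative dose, PTV
  mask, OAR mask) + a machine-parameter vector of length 53
  (52 leaf positions + 1 MU) for the current control point.
* MU state: 3-channel volumetric tensor (cumulative dose, PTV mask, OAR
  mask) + a vector of length 53 x n_cp covering every control point
  (9116 for the full 172-CP arc).
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from vmatrl.nn import (BatchNorm3d, Conv3d, LayerNorm, Linear, Module,
                       MultiheadSelfAttention, Tensor, concatenate)

__all__ = ["PolicyOutput", "TandemPolicy", "build_network", "sample_action",
           "gaussian_log_prob", "policy_entropy", "save_checkpoint", "load_checkpoint",
           "PAPER_SCALE", "TOY_SCALE"]

LOG_STD_MIN, LOG_STD_MAX = -5.0, 0.0
# initial exploration scales, chosen so sampled perturbations are small on
# the machine scale: ~1 mm leaf jitter for the (bounded, +/-1) MLC actions,
# ~8 % modulation for the (smooth) MU-fraction actions
LOG_STD_INIT = {"mlc": -4.0, "mu": -2.5}

# capacity presets; topology and head activations are the contract, capacities
# are free parameters
TOY_SCALE = dict(conv_channels=(6, 12), d_model=8, n_heads=2, feat_dim=32, trunk_dim=64)
PAPER_SCALE = dict(conv_channels=(16, 32), d_model=32, n_heads=4, feat_dim=128,
                   trunk_dim=256)
_DEFAULT_VOL = {"mlc": (48, 48, 128), "mu": (48, 128, 128)}


@dataclass
class PolicyOutput:
    """One forward pass: diagonal-Gaussian action distribution + value."""

    mean: Tensor
    log_std: Tensor
    value: Tensor

    def numpy(self) -> tuple:
        return (self.mean.data.copy(), self.log_std.data.copy(),
                float(np.ravel(self.value.data)[0]))


class _ResidualConvBlock(Module):
    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv3d(channels, channels, 3, rng, stride=1, padding=1)
        self.bn1 = BatchNorm3d(channels)
        self.conv2 = Conv3d(channels, channels, 3, rng, stride=1, padding=1)
        self.bn2 = BatchNorm3d(channels)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h))
        return (h + x).relu()


class TandemPolicy(Module):
    """One of the two tandem networks (role 'mlc' or 'mu')."""

    def __init__(self, role: str, vol_shape: tuple, vec_len: int, action_dim: int,
                 token_dim: int, seed: int = 0, scale: dict | None = None):
        super().__init__()
        if role not in ("mlc", "mu"):
            raise ValueError(f"invalid network role {role!r}")
        if vec_len % token_dim != 0:
            raise ValueError("vector length must be a multiple of the token dim")
        cfg = dict(scale or TOY_SCALE)
        rng = np.random.default_rng(seed)
        self.role = role
        self.vol_shape = tuple(vol_shape)
        self.vec_len = vec_len
        self.action_dim = action_dim
        self.token_dim = token_dim
        self.n_tokens = vec_len // token_dim
        c1, c2 = cfg["conv_channels"]
        feat = cfg["feat_dim"]

        # volumetric encoder: strided conv -> residual block -> strided conv
        self.conv_in = Conv3d(3, c1, 3, rng, stride=2, padding=1)
        self.bn_in = BatchNorm3d(c1)
        self.res = _ResidualConvBlock(c1, rng)
        self.conv_out = Conv3d(c1, c2, 3, rng, stride=2, padding=1)
        self.bn_out = BatchNorm3d(c2)
        red = [((n + 1) // 2 + 1) // 2 for n in vol_shape]
        self.vol_flat = c2 * int(np.prod(red))
        self.vol_fc = Linear(self.vol_flat, feat, rng)
        self.vol_ln = LayerNorm(feat)

        # vector encoder: token embedding -> multi-head self-attention -> dense
        d_model = cfg["d_model"]
        self.embed = Linear(token_dim, d_model, rng)
        self.attn = MultiheadSelfAttention(d_model, cfg["n_heads"], rng)
        self.attn_ln = LayerNorm(d_model)
        self.vec_fc = Linear(self.n_tokens * d_model, feat, rng)
        self.vec_ln = LayerNorm(feat)

        # shared trunk and the three heads
        h = cfg["trunk_dim"]
        self.trunk = Linear(2 * feat, h, rng)
        self.trunk_ln = LayerNorm(h)
        self.head_mean = Linear(h, action_dim, rng)
        self.head_log_std = Linear(h, action_dim, rng)
        self.head_value = Linear(h, 1, rng)
        # small-init the mean head so initial actions sit near the activation's
        # neutral point (open-centred apertures / near-uniform MUs)
        self.head_mean.weight.data *= 0.1
        self.head_log_std.bias.data[:] = LOG_STD_INIT[role]

    def __call__(self, vol, vec) -> PolicyOutput:
        """Forward pass.  ``vol``: (B, 3, *vol_shape); ``vec``: (B, vec_len)."""
        vol = vol if isinstance(vol, Tensor) else Tensor(vol)
        vec = vec if isinstance(vec, Tensor) else Tensor(vec)
        B = vol.shape[0]

        h = self.bn_in(self.conv_in(vol)).relu()
        h = self.res(h)
        h = self.bn_out(self.conv_out(h)).relu()
        h = self.vol_ln(self.vol_fc(h.reshape(B, self.vol_flat))).relu()

        t = vec.reshape(B, self.n_tokens, self.token_dim)
        t = self.embed(t)
        t = self.attn_ln(t + self.attn(t))
        t = self.vec_ln(self.vec_fc(t.reshape(B, self.n_tokens * self.attn.d_head
                                              * self.attn.n_heads))).relu()

        z = self.trunk_ln(self.trunk(concatenate([h, t], axis=1))).relu()
        raw_mean = self.head_mean(z)
        mean = raw_mean.tanh() if self.role == "mlc" else raw_mean.softplus()
        log_std = self.head_log_std(z).clip(LOG_STD_MIN, LOG_STD_MAX)
        value = self.head_value(z)
        return PolicyOutput(mean=mean, log_std=log_std, value=value)

    def summary(self) -> str:
        lines = [f"TandemPolicy(role={self.role}, action_dim={self.action_dim}, "
                 f"vol_shape={self.vol_shape}, vec_len={self.vec_len})"]
        for name, m in self.named_modules():
            if name and m._params:
                shapes = {k: v.data.shape for k, v in m._params.items()}
                lines.append(f"  {name}: {shapes}")
        lines.append(f"  total parameters: {self.n_parameters()}")
        return "\n".join(lines)


def build_network(role: str, scale: str = "toy", vol_shape: tuple | None = None,
                  n_cp: int = 172, leaf_pairs: int = 26, seed: int = 0) -> TandemPolicy:
    """Build an MLC or MU network at a named capacity scale.

    The MLC network predicts 52 leaf positions from a per-CP state; the MU
    network predicts all ``n_cp`` monitor units from a whole-plan state.
    """
    if role not in ("mlc", "mu"):
        raise ValueError(f"invalid network role {role!r}; choose 'mlc' or 'mu'")
    if scale not in ("toy", "paper"):
        raise ValueError(f"unknown scale {scale!r}")
    cfg = TOY_SCALE if scale == "toy" else PAPER_SCALE
    vol_shape = vol_shape or _DEFAULT_VOL[role]
    per_cp = 2 * leaf_pairs + 1  # 52 leaves + 1 MU
    if role == "mlc":
        net = TandemPolicy("mlc", vol_shape, vec_len=per_cp, action_dim=2 * leaf_pairs,
                           token_dim=1, seed=seed, scale=cfg)
    else:
        net = TandemPolicy("mu", vol_shape, vec_len=per_cp * n_cp, action_dim=n_cp,
                           token_dim=per_cp, seed=seed, scale=cfg)
    # rollouts expect deterministic forwards; update passes switch to train mode
    return net.eval()


def sample_action(out: PolicyOutput, mode: str = "train",
                  rng: np.random.Generator | None = None) -> tuple:
    """Draw an action from the policy's diagonal Gaussian.

    ``train`` samples each component independently; ``infer`` returns the
    mean directly.  Returns ``(action, log_prob)`` with ``log_prob`` the
    diagonal-Gaussian log-density of the returned action.
    """
    mean = np.ravel(out.mean.data)
    log_std = np.ravel(out.log_std.data)
    if mode == "infer":
        action = mean.copy()
    elif mode == "train":
        if rng is None:
            raise ValueError("train-mode sampling needs an rng")
        action = mean + np.exp(log_std) * rng.standard_normal(mean.shape)
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")
    return action, float(_log_prob_np(action, mean, log_std))


def _log_prob_np(action, mean, log_std) -> float:
    z = (action - mean) / np.exp(log_std)
    return float(np.sum(-0.5 * z ** 2 - log_std - 0.5 * np.log(2.0 * np.pi)))


def gaussian_log_prob(mean: Tensor, log_std: Tensor, action: np.ndarray) -> Tensor:
    """Differentiable per-sample log-density; sums over action components.

    ``mean``/``log_std``: (B, A) Tensors; ``action``: (B, A) array.
    Returns a (B,) Tensor.
    """
    a = Tensor(np.asarray(action, dtype=float))
    z = (a - mean) * (-log_std).exp()
    terms = z ** 2 * (-0.5) - log_std - 0.5 * np.log(2.0 * np.pi)
    return terms.sum(axis=1)


def policy_entropy(out_or_log_std) -> Tensor:
    """Diagonal-Gaussian entropy: sum_j (0.5 ln(2*pi*e) + log_std_j).

    Accepts a PolicyOutput or a log-std Tensor of shape (B, A); returns a (B,)
    Tensor (or scalar for 1-D input).
    """
    log_std = (out_or_log_std.log_std if isinstance(out_or_log_std, PolicyOutput)
               else out_or_log_std)
    if not isinstance(log_std, Tensor):
        log_std = Tensor(log_std)
    const = 0.5 * np.log(2.0 * np.pi * np.e)
    axis = 1 if log_std.ndim > 1 else None
    return (log_std + const).sum(axis=axis)


def save_checkpoint(path, policies: dict, meta: dict | None = None) -> None:
    """Persist network parameters (one group per role) to an HDF5 container."""
    with h5py.File(path, "w") as fh:
        fh.attrs["format"] = "vmatrl-checkpoint-v1"
        for key, value in (meta or {}).items():
            fh.attrs[key] = value
        for role, policy in policies.items():
            g = fh.create_group(role)
            g.attrs["vol_shape"] = policy.vol_shape
            g.attrs["vec_len"] = policy.vec_len
            g.attrs["action_dim"] = policy.action_dim
            for name, arr in policy.state_dict().items():
                g.create_dataset(name, data=arr)


def load_checkpoint(path, policies: dict) -> dict:
    """Load parameters into pre-built networks; returns file metadata."""
    with h5py.File(path, "r") as fh:
        for role, policy in policies.items():
            g = fh[role]
            state = {name: g[name][...] for name in g}
            policy.load_state_dict(state)
        return dict(fh.attrs)
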