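"""Bernoulli block-keeping policy: network, sampling and exact probabilities.

The policy over an action vector a in {0,1}^N factorizes as

    pi_W(a | x) = prod_n  p_n^{a_n} (1 - p_n)^{1 - a_n},

where p_n = P(a_n = 1) is the probability of KEEPING block n, produced by a
small 3D CNN from the input volume via sigmoid activations. Note that a_n = 0
means the block is dropped, so p_n is a keep probability even though a low
p_n reads naturally as a high "drop likelihood".
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import nn

#: probabilities are clamped to this range before any logarithm
PROB_EPS = 1e-6


@dataclass
class PolicyConfig:
    """Architecture of the policy network.

    A 3D CNN far cheaper than the backbone it gates: optional in-plane
    average-pool downsampling of the input, four strided conv/norm/ReLU
    stages, global average pooling and one linear layer to N logits.
    """

    n_blocks: int
    in_channels: int = 1
    widths: tuple[int, ...] = (8, 16, 32, 32)
    downsample: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")

    def to_json(self) -> str:
        d = self.__dict__.copy()
        d["widths"] = list(self.widths)
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "PolicyConfig":
        d = json.loads(s)
        d["widths"] = tuple(d["widths"])
        return cls(**d)


class PolicyNetwork(nn.Module):
    """Maps a volume batch (B, C, D, H, W) to keep-probability logits (B, N)."""

    def __init__(self, config: PolicyConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.pool = (
            nn.AvgPool3d((1, config.downsample, config.downsample))
            if config.downsample > 1
            else None
        )
        stages = []
        cin = config.in_channels
        for w in config.widths:
            stages.append(
                nn.Sequential(
                    nn.Conv3d(cin, w, 3, stride=(1, 2, 2), bias=False, rng=rng),
                    nn.BatchNorm3d(w),
                    nn.ReLU(),
                )
            )
            cin = w
        self.stages = stages
        self.gap = nn.GlobalAvgPool3d()
        self.fc = nn.Linear(cin, config.n_blocks, rng=rng)

    @property
    def n_blocks(self) -> int:
        return self.config.n_blocks

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 5:
            raise ValueError(f"expected (B, C, D, H, W), got {x.shape}")
        h = self.pool.forward(x) if self.pool is not None else x
        for st in self.stages:
            h = st.forward(h)
        return self.fc.forward(self.gap.forward(h))

    def backward(self, glogits: np.ndarray) -> None:
        g = self.gap.backward(self.fc.backward(glogits))
        for st in reversed(self.stages):
            g = st.backward(g)
        if self.pool is not None:
            self.pool.backward(g)

    def keep_probabilities(self, x: np.ndarray) -> np.ndarray:
        """Per-block keep probabilities for one (D, H, W) volume."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None, None]
        logits = self.forward_logits(x)
        return _sigmoid(logits[0].astype(np.float64))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    e = np.exp(-np.abs(z))
    return np.where(z >= 0, 1.0 / (1.0 + e), e / (1.0 + e))


def build_policy(n_blocks: int, arch_config: PolicyConfig | None = None) -> PolicyNetwork:
    """Construct a policy network emitting ``n_blocks`` keep probabilities."""
    if arch_config is None:
        arch_config = PolicyConfig(n_blocks=n_blocks)
    elif arch_config.n_blocks != n_blocks:
        raise ValueError(
            f"arch_config.n_blocks={arch_config.n_blocks} inconsistent with n_blocks={n_blocks}"
        )
    return PolicyNetwork(arch_config)


def _validate_probs(p) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 1:
        raise ValueError("keep probabilities must be a 1D vector")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("keep probabilities must lie in [0, 1]")
    return p


def sample_actions(p, rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Independent Bernoulli draws with P(a_n = 1) = p_n."""
    p = _validate_probs(p)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return (rng.random(p.shape) < p).astype(np.int64)


def log_policy_prob(p, a) -> float:
    """log pi(a | x) = sum_n log[p_n a_n + (1 - p_n)(1 - a_n)].

    Probabilities are clamped to [1e-6, 1 - 1e-6] before the logarithm.
    """
    p = _validate_probs(p)
    a = np.asarray(a)
    if a.shape != p.shape:
        raise ValueError(f"length mismatch: p has {p.shape}, a has {a.shape}")
    if not np.isin(a, (0, 1)).all():
        raise ValueError("actions must be binary")
    pc = np.clip(p, PROB_EPS, 1.0 - PROB_EPS)
    term = pc * a + (1.0 - pc) * (1.0 - a)
    return float(np.log(term).sum())


def decide_actions(p, mode: str = "threshold", rng=None) -> np.ndarray:
    """Turn keep probabilities into actions.

    ``threshold``: deterministic, keep block n iff p_n >= 0.5.
    ``sample``: one Bernoulli draw (delegates to :func:`sample_actions`).
    """
    p = _validate_probs(p)
    if mode == "threshold":
        return (p >= 0.5).astype(np.int64)
    if mode == "sample":
        return sample_actions(p, rng)
    raise ValueError(f"unknown decision mode {mode!r}")


def save_policy(net: PolicyNetwork, path) -> None:
    with open(path, "wb") as fh:
        np.savez(fh, __config__=np.array(net.config.to_json()), **net.state_dict())


def load_policy(path) -> PolicyNetwork:
    with np.load(path, allow_pickle=False) as archive:
        config = PolicyConfig.from_json(str(archive["__config__"]))
        net = PolicyNetwork(config)
        state = {k: archive[k] for k in archive.files if k != "__config__"}
    net.load_state_dict(state)
    return net


def case_record(case_id: str, p: np.ndarray, a: np.ndarray) -> str:
    """One JSON line with a case's keep probabilities and chosen actions."""
    return json.dumps(
        {"case_id": case_id, "p": [round(float(v), 6) for v in p], "a": [int(v) for v in a]}
    )
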