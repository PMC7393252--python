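"""Voxel-level reward gated by the Voxel Dice Coefficient.

Each voxel i receives

    R_i(a) = 1 - (|a|_0 / N)^2   if VDC(i) = 1      (correctly predicted)
           = -tau                otherwise,

where |a|_0 is the number of kept blocks, so (|a|_0/N)^2 is the squared
block-usage fraction, and

    VDC(i) = (2 (y'_i AND y_i) + 1) / (y'_i + y_i + 1)

equals 1 exactly when prediction y' matches ground truth y at voxel i and 0.5
otherwise (binary masks). Correct voxels reward dropping blocks; wrong voxels
are penalized by tau, which balances compute savings against accuracy.
Per-voxel rewards are averaged into the scalar driving the policy gradient,
so tau keeps its meaning across volume sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: default penalty for a misclassified voxel
DEFAULT_TAU = 50.0


def _validate_binary(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m)
    if not np.isin(m, (0, 1)).all():
        raise ValueError(f"{name} must be binary")
    return m.astype(np.float64)


def vdc_map(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Voxel Dice Coefficient map: 1.0 where pred == truth, 0.5 elsewhere."""
    pred = _validate_binary(pred, "pred")
    truth = _validate_binary(truth, "truth")
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return (2.0 * (pred * truth) + 1.0) / (pred + truth + 1.0)


def usage_term(a) -> float:
    """Squared kept-block fraction (|a|_0 / N)^2."""
    a = np.asarray(a)
    if a.size == 0:
        raise ValueError("empty action vector")
    if not np.isin(a, (0, 1)).all():
        raise ValueError("actions must be binary")
    kept = int(np.count_nonzero(a))
    return (kept / a.size) ** 2


@dataclass
class RewardMap:
    values: np.ndarray
    usage: float
    tau: float


def reward_map(a, vdc: np.ndarray, tau: float = DEFAULT_TAU) -> RewardMap:
    """Per-voxel rewards: 1 - usage where VDC = 1, -tau elsewhere."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    u = usage_term(a)
    vdc = np.asarray(vdc, dtype=np.float64)
    values = np.where(vdc == 1.0, 1.0 - u, -float(tau))
    return RewardMap(values=values, usage=u, tau=float(tau))


def scalar_reward(rm: RewardMap | np.ndarray) -> float:
    """Mean voxel reward — the scalar R(a) fed to the policy gradient."""
    values = rm.values if isinstance(rm, RewardMap) else np.asarray(rm)
    if values.size == 0:
        raise ValueError("empty reward map")
    return float(values.mean())


def compute_reward(pred: np.ndarray, truth: np.ndarray, a, tau: float = DEFAULT_TAU) -> tuple[float, RewardMap]:
    """VDC -> reward map -> scalar, in one call."""
    rm = reward_map(a, vdc_map(pred, truth), tau)
    return scalar_reward(rm), rm
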