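"""Training loops: supervised backbone pretraining and REINFORCE policy learning.

The policy is trained to maximize the expected reward E_{a~pi}[R(a)] with the
score-function (REINFORCE) estimator

    grad_W E[R(a)] = E[ R(a) grad_W sum_n log(p_n a_n + (1-p_n)(1-a_n)) ],

approximated by Monte-Carlo sampling. For sigmoid outputs p = sigma(z) the
per-logit score is simply a_n - p_n, so the sampled loss gradient w.r.t. the
policy logits is -R (a - p), masked to the learnable blocks.

Curriculum: at epoch c (1-based), only the last min(c, N) blocks are
learnable; the first N - c blocks are forced to keep (a = 1) and excluded
from the log-probability sum, so their logits receive exactly zero gradient.
The segmentation network stays frozen throughout policy training.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .backbone import GatedBackbone, save_backbone
from .data_io import Case
from .nn import Adam, SegmentationLoss
from .nn.optim import step_decay
from .policy import PROB_EPS, PolicyNetwork, save_policy
from .reward import compute_reward


@dataclass
class CurriculumState:
    """Which blocks are learnable at a given epoch."""

    epoch: int
    n_blocks: int
    learnable: np.ndarray  # bool, True = action sampled/learned

    @property
    def forced_keep(self) -> np.ndarray:
        return ~self.learnable


def curriculum_mask(epoch: int, n_blocks: int) -> CurriculumState:
    """Epoch c: the first N - min(c, N) blocks are forced keep."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    c = min(epoch, n_blocks)
    learnable = np.zeros(n_blocks, dtype=bool)
    if c > 0:
        learnable[n_blocks - c :] = True
    return CurriculumState(epoch=epoch, n_blocks=n_blocks, learnable=learnable)


@dataclass
class TrainConfig:
    """Optimization settings; defaults follow the reference experimental setup.

    Adam for both networks; segmentation lr 0.01, policy lr 0.001, lr decayed
    x0.1 every 100 epochs, at most 400 epochs, misclassification penalty
    tau = 50. ``mc_samples`` is the number of Monte-Carlo action draws per
    image per step.
    """

    lr_seg: float = 0.01
    lr_policy: float = 0.001
    tau: float = 50.0
    max_epochs: int = 400
    batch_size_seg: int = 4
    batch_size_policy: int = 1
    lr_decay_step: int = 100
    lr_decay_gamma: float = 0.1
    mc_samples: int = 1
    seed: int = 0
    use_baseline: bool = False
    baseline_momentum: float = 0.9

    def __post_init__(self):
        if min(self.lr_seg, self.lr_policy, self.tau) <= 0:
            raise ValueError("rates and tau must be positive")
        if self.mc_samples < 1:
            raise ValueError("mc_samples must be >= 1")


def reinforce_loss(p, a, reward: float, mask: CurriculumState) -> float:
    """-R * sum over learnable blocks of log(p_n a_n + (1-p_n)(1-a_n))."""
    p = np.asarray(p, dtype=np.float64)
    a = np.asarray(a)
    if p.shape != a.shape or p.shape != mask.learnable.shape:
        raise ValueError("length mismatch between p, a and curriculum mask")
    if not np.isfinite(reward):
        raise ValueError("non-finite reward")
    pc = np.clip(p, PROB_EPS, 1.0 - PROB_EPS)
    term = np.log(pc * a + (1.0 - pc) * (1.0 - a))
    return float(-reward * term[mask.learnable].sum())


def reinforce_grad_logits(p, a, reward: float, mask: CurriculumState) -> np.ndarray:
    """Gradient of :func:`reinforce_loss` w.r.t. the policy logits.

    d/dz_n [-R log pi] = -R (a_n - p_n) for learnable n, exactly 0 for
    forced-keep blocks.
    """
    p = np.asarray(p, dtype=np.float64)
    a = np.asarray(a, dtype=np.float64)
    g = -reward * (a - p)
    g[~mask.learnable] = 0.0
    return g


def actions_with_curriculum(
    p: np.ndarray, mask: CurriculumState, rng: np.random.Generator
) -> np.ndarray:
    """Sample learnable entries from Bernoulli(p); force the rest to keep."""
    a = np.ones(mask.n_blocks, dtype=np.int64)
    idx = mask.learnable
    a[idx] = (rng.random(int(idx.sum())) < p[idx]).astype(np.int64)
    return a


def _stack_batch(cases: list[Case]) -> tuple[np.ndarray, np.ndarray]:
    vols = np.stack([c.volume.data for c in cases])[:, None]
    masks = np.stack([c.mask for c in cases])
    return vols, masks


def _dice(pred: np.ndarray, truth: np.ndarray) -> float:
    inter = np.count_nonzero(np.logical_and(pred, truth))
    size = np.count_nonzero(pred) + np.count_nonzero(truth)
    return 1.0 if size == 0 else 2.0 * inter / size


def evaluate_dice(net: GatedBackbone, cases: list[Case], actions=None) -> float:
    """Mean Dice over cases with a fixed action vector (default all-keep)."""
    was_training = net.training
    net.eval()
    scores = []
    for case in cases:
        probs = net.forward_probs(case.volume.data[None, None], actions)[0]
        pred = (probs[1] > probs[0]).astype(np.uint8)
        scores.append(_dice(pred, case.mask))
    if was_training:
        net.train()
    return float(np.mean(scores))


def pretrain_segmenter(
    net: GatedBackbone,
    cases: list[Case],
    cfg: TrainConfig,
    *,
    epochs: int | None = None,
    val_cases: list[Case] | None = None,
    checkpoint_path=None,
    log_path=None,
) -> dict:
    """Supervised pretraining with voxel cross-entropy + soft Dice (all blocks kept).

    Returns a history dict with per-epoch loss and, when a validation split is
    given, held-out Dice.
    """
    if not cases:
        raise ValueError("empty training dataset")
    epochs = epochs if epochs is not None else cfg.max_epochs
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5E6]))
    loss_fn = SegmentationLoss()
    opt = Adam(net.parameters(), lr=cfg.lr_seg)
    history = {"epoch": [], "loss": [], "val_dice": []}
    net.train()
    for epoch in range(epochs):
        opt.lr = step_decay(cfg.lr_seg, epoch, cfg.lr_decay_step, cfg.lr_decay_gamma)
        order = rng.permutation(len(cases))
        losses = []
        for start in range(0, len(cases), cfg.batch_size_seg):
            batch = [cases[i] for i in order[start : start + cfg.batch_size_seg]]
            x, y = _stack_batch(batch)
            logits = net.forward_logits(x)
            loss, glogits = loss_fn(logits, y)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: lr={opt.lr}, batch={[c.id for c in batch]}"
                )
            opt.zero_grad()
            net.backward(glogits)
            opt.step()
            losses.append(loss)
        val_dice = evaluate_dice(net, val_cases) if val_cases else float("nan")
        history["epoch"].append(epoch)
        history["loss"].append(float(np.mean(losses)))
        history["val_dice"].append(val_dice)
        if log_path is not None:
            with open(log_path, "a") as fh:
                fh.write(json.dumps({"epoch": epoch, "loss": history["loss"][-1],
                                     "val_dice": val_dice}) + "\n")
    net.eval()
    if checkpoint_path is not None:
        save_backbone(net, checkpoint_path)
    return history


def train_policy(
    policy: PolicyNetwork,
    frozen_net: GatedBackbone,
    cases: list[Case],
    cfg: TrainConfig,
    *,
    epochs: int | None = None,
    checkpoint_path=None,
    log_path=None,
    diagnostics_csv=None,
) -> dict:
    """REINFORCE training of the policy over a frozen segmentation network.

    Per epoch c (1-based): curriculum mask, then for each volume the policy
    emits keep probabilities, actions are sampled on the learnable blocks
    (``mc_samples`` draws), the gated segmentation runs, the voxel rewards are
    aggregated and the score-function gradient is applied. The backbone's
    weights are asserted bit-identical before and after.
    """
    if policy.n_blocks != frozen_net.n_blocks:
        raise ValueError(
            f"policy N={policy.n_blocks} != backbone N={frozen_net.n_blocks}"
        )
    if not cases:
        raise ValueError("empty training dataset")
    epochs = epochs if epochs is not None else cfg.max_epochs
    n = frozen_net.n_blocks
    seg_state_before = {k: v.copy() for k, v in frozen_net.state_dict().items()}
    frozen_net.eval()
    policy.train()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xAC70]))
    opt = Adam(policy.parameters(), lr=cfg.lr_policy)
    history = {"epoch": [], "mean_reward": [], "mean_kept": [], "dice": []}
    baseline = 0.0
    baseline_ready = False
    diag_rows = []
    step = 0
    for epoch_idx in range(epochs):
        c = epoch_idx + 1
        mask = curriculum_mask(c, n)
        opt.lr = step_decay(cfg.lr_policy, epoch_idx, cfg.lr_decay_step, cfg.lr_decay_gamma)
        order = rng.permutation(len(cases))
        ep_rewards, ep_kept, ep_dice = [], [], []
        for i in order:
            case = cases[i]
            x = case.volume.data[None, None]
            logits = policy.forward_logits(x)
            p = 1.0 / (1.0 + np.exp(-logits[0].astype(np.float64)))
            glogits = np.zeros(n, dtype=np.float64)
            for _ in range(cfg.mc_samples):
                a = actions_with_curriculum(p, mask, rng)
                probs = frozen_net.forward_probs(x, a)[0]
                pred = (probs[1] > probs[0]).astype(np.uint8)
                reward, rm = compute_reward(pred, case.mask, a, tau=cfg.tau)
                advantage = reward - baseline if (cfg.use_baseline and baseline_ready) else reward
                glogits += reinforce_grad_logits(p, a, advantage, mask) / cfg.mc_samples
                if cfg.use_baseline:
                    m = cfg.baseline_momentum
                    baseline = reward if not baseline_ready else m * baseline + (1 - m) * reward
                    baseline_ready = True
                frac_correct = float((pred == case.mask).mean())
                ep_rewards.append(reward)
                ep_kept.append(int(a.sum()))
                ep_dice.append(_dice(pred, case.mask))
                diag_rows.append(
                    {
                        "step": step,
                        "kept_count": int(a.sum()),
                        "usage_term": rm.usage,
                        "frac_correct_voxels": frac_correct,
                        "scalar_reward": reward,
                    }
                )
                step += 1
            opt.zero_grad()
            policy.backward(glogits[None].astype(np.float32))
            opt.step()
        history["epoch"].append(c)
        history["mean_reward"].append(float(np.mean(ep_rewards)))
        history["mean_kept"].append(float(np.mean(ep_kept)))
        history["dice"].append(float(np.mean(ep_dice)))
        if log_path is not None:
            with open(log_path, "a") as fh:
                fh.write(
                    json.dumps(
                        {
                            "epoch": c,
                            "mean_reward": history["mean_reward"][-1],
                            "mean_kept": history["mean_kept"][-1],
                            "dice": history["dice"][-1],
                        }
                    )
                    + "\n"
                )
    policy.eval()
    seg_state_after = frozen_net.state_dict()
    for key, before in seg_state_before.items():
        if not np.array_equal(before, seg_state_after[key]):
            raise AssertionError(f"frozen backbone changed during policy training: {key}")
    if diagnostics_csv is not None:
        with open(diagnostics_csv, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh,
                fieldnames=["step", "kept_count", "usage_term", "frac_correct_voxels",
                            "scalar_reward"],
            )
            writer.writeheader()
            writer.writerows(diag_rows)
    if checkpoint_path is not None:
        save_policy(policy, checkpoint_path)
    return history
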