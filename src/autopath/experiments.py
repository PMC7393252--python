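"""Heuristic dropping strategies, Dice evaluation, and strategy comparisons.

Implements the block-dependency and heuristic-baseline methodology: DropN
(drop one block), DropFirstN / DropLastN (drop a prefix/suffix of n blocks),
DropRandomN (drop n uniformly chosen blocks, repeated), the learned
image-specific policy, and the full backbone — all evaluated by volume-level
Dice and block-usage statistics, with a comparison table at matched dropping
level. Blocks are numbered 1..N in execution order; strategy sizes count
dropped blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .backbone import GatedBackbone
from .data_io import Case
from .policy import PolicyNetwork, decide_actions

STRATEGY_KINDS = ("full", "drop_n", "drop_first_n", "drop_last_n", "drop_random_n", "autopath")


@dataclass
class DropStrategySpec:
    kind: str
    n: int = 0
    repeats: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.kind not in STRATEGY_KINDS:
            raise ValueError(f"unknown strategy kind {self.kind!r}")
        if self.kind == "drop_random_n" and self.repeats < 1:
            raise ValueError("drop_random_n needs repeats >= 1")

    @property
    def label(self) -> str:
        return {"full": "Full backbone", "drop_n": f"DropN({self.n})",
                "drop_first_n": f"DropFirstN({self.n})", "drop_last_n": f"DropLastN({self.n})",
                "drop_random_n": f"DropRandomN({self.n})", "autopath": "AutoPath"}[self.kind]


def actions_for_strategy(
    spec: DropStrategySpec, n_blocks: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Action vector for a heuristic strategy (1 = keep, 0 = drop)."""
    k = spec.n
    a = np.ones(n_blocks, dtype=np.int64)
    if spec.kind == "full":
        return a
    if not 0 <= k <= n_blocks:
        raise ValueError(f"n={k} out of range for N={n_blocks}")
    if spec.kind == "drop_n":
        if not 1 <= k <= n_blocks:
            raise ValueError(f"drop_n block index {k} out of range 1..{n_blocks}")
        a[k - 1] = 0
    elif spec.kind == "drop_first_n":
        a[:k] = 0
    elif spec.kind == "drop_last_n":
        a[n_blocks - k :] = 0 if k else 1
    elif spec.kind == "drop_random_n":
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        dropped = rng.choice(n_blocks, size=k, replace=False)
        a[dropped] = 0
    else:
        raise ValueError(f"{spec.kind} actions come from a policy, not a heuristic")
    return a


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Volume Dice 2|P n T| / (|P| + |T|); 1.0 when both masks are empty."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    inter = np.count_nonzero(np.logical_and(pred, truth))
    size = np.count_nonzero(pred) + np.count_nonzero(truth)
    return 1.0 if size == 0 else 2.0 * inter / size


@dataclass
class EvaluationReport:
    strategy: str
    per_case: list[dict] = field(default_factory=list)
    mean_dice: float = float("nan")
    mean_dropped: float = float("nan")
    dropping_ratio: float = float("nan")
    n_blocks: int = 0
    dice_sd: float = float("nan")  # over repeats, random strategies only

    def finalize(self) -> "EvaluationReport":
        self.mean_dice = float(np.mean([r["dice"] for r in self.per_case]))
        self.mean_dropped = float(np.mean([r["dropped_count"] for r in self.per_case]))
        self.dropping_ratio = self.mean_dropped / self.n_blocks
        return self

    def dropped_histogram(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for r in self.per_case:
            counts[r["dropped_count"]] = counts.get(r["dropped_count"], 0) + 1
        return dict(sorted(counts.items()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_case)


def _predict(net: GatedBackbone, case: Case, actions) -> np.ndarray:
    probs = net.forward_probs(case.volume.data[None, None], actions)[0]
    return (probs[1] > probs[0]).astype(np.uint8)


def _evaluate_fixed_actions(net, cases, actions, strategy: str) -> EvaluationReport:
    n = net.n_blocks
    report = EvaluationReport(strategy=strategy, n_blocks=n)
    dropped = int(n - actions.sum())
    for case in cases:
        pred = _predict(net, case, actions)
        report.per_case.append(
            {"case_id": case.id, "dice": dice(pred, case.mask),
             "kept_count": int(actions.sum()), "dropped_count": dropped}
        )
    return report.finalize()


def run_drop_study(
    net: GatedBackbone, cases: list[Case], specs: Sequence[DropStrategySpec]
) -> dict[str, EvaluationReport]:
    """Evaluate each strategy spec on the dataset; a full-backbone reference
    row is always included. Random strategies are repeated ``repeats`` times
    (fresh actions per case per repeat) and report mean and sd over repeats.
    """
    if not cases:
        raise ValueError("empty dataset")
    net.eval()
    n = net.n_blocks
    reports: dict[str, EvaluationReport] = {}
    full_spec = DropStrategySpec(kind="full")
    reports[full_spec.label] = _evaluate_fixed_actions(
        net, cases, actions_for_strategy(full_spec, n), full_spec.label
    )
    for spec in specs:
        if spec.kind == "full":
            continue
        if spec.kind == "drop_random_n":
            rng = np.random.default_rng(spec.seed)
            repeat_means = []
            report = EvaluationReport(strategy=spec.label, n_blocks=n)
            for _ in range(spec.repeats):
                scores = []
                for case in cases:
                    a = actions_for_strategy(spec, n, rng)
                    pred = _predict(net, case, a)
                    score = dice(pred, case.mask)
                    scores.append(score)
                    report.per_case.append(
                        {"case_id": case.id, "dice": score,
                         "kept_count": int(a.sum()), "dropped_count": int(n - a.sum())}
                    )
                repeat_means.append(float(np.mean(scores)))
            report.finalize()
            report.dice_sd = float(np.std(repeat_means, ddof=1)) if spec.repeats > 1 else 0.0
            reports[spec.label] = report
        else:
            a = actions_for_strategy(spec, n)
            reports[spec.label] = _evaluate_fixed_actions(net, cases, a, spec.label)
    return reports


def run_autopath_eval(
    policy: PolicyNetwork,
    net: GatedBackbone,
    cases: list[Case],
    mode: str = "threshold",
    seed: int = 0,
) -> EvaluationReport:
    """Evaluate the learned image-specific policy case by case."""
    if policy.n_blocks != net.n_blocks:
        raise ValueError("policy and backbone block counts differ")
    net.eval()
    policy.eval()
    rng = np.random.default_rng(seed)
    report = EvaluationReport(strategy="AutoPath", n_blocks=net.n_blocks)
    for case in cases:
        p = policy.keep_probabilities(case.volume.data)
        a = decide_actions(p, mode=mode, rng=rng)
        pred = _predict(net, case, a)
        report.per_case.append(
            {"case_id": case.id, "dice": dice(pred, case.mask),
             "kept_count": int(a.sum()), "dropped_count": int(net.n_blocks - a.sum())}
        )
    return report.finalize()


def round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def compare_at_equal_dropping(
    net: GatedBackbone,
    cases: list[Case],
    autopath_report: EvaluationReport,
    *,
    repeats: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Comparison table: heuristics evaluated at n = round(AutoPath mean dropped).

    Rows: DropFirstN, DropLastN, DropRandomN at the matched dropping level,
    the image-specific policy, and the full backbone.
    """
    n_match = round_half_up(autopath_report.mean_dropped)
    specs = [
        DropStrategySpec(kind="drop_first_n", n=n_match),
        DropStrategySpec(kind="drop_last_n", n=n_match),
        DropStrategySpec(kind="drop_random_n", n=n_match, repeats=repeats, seed=seed),
    ]
    reports = run_drop_study(net, cases, specs)
    rows = []
    for spec in specs:
        rep = reports[spec.label]
        rows.append({"strategy": spec.label, "mean_dice": rep.mean_dice,
                     "mean_dropped": rep.mean_dropped, "dice_sd": rep.dice_sd})
    rows.append({"strategy": "AutoPath", "mean_dice": autopath_report.mean_dice,
                 "mean_dropped": autopath_report.mean_dropped, "dice_sd": float("nan")})
    full = reports["Full backbone"]
    rows.append({"strategy": "Full backbone", "mean_dice": full.mean_dice,
                 "mean_dropped": 0.0, "dice_sd": float("nan")})
    return pd.DataFrame(rows)


def dependency_study(net: GatedBackbone, cases: list[Case]) -> dict[str, EvaluationReport]:
    """DropN over every single block: one report per block index."""
    specs = [DropStrategySpec(kind="drop_n", n=k) for k in range(1, net.n_blocks + 1)]
    return run_drop_study(net, cases, specs)
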