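"""Curriculum schedule, REINFORCE estimator, pretraining and policy training."""

import numpy as np
import pytest

import autopath as ap
from autopath.backbone import save_backbone, load_backbone
from autopath.policy import PolicyConfig
from autopath.training import actions_with_curriculum, curriculum_mask


# ---------------------------------------------------------------- curriculum

def test_curriculum_prefix_is_forced_keep():
    state = curriculum_mask(1, 8)
    np.testing.assert_array_equal(state.learnable, [False] * 7 + [True])
    state = curriculum_mask(3, 8)
    np.testing.assert_array_equal(state.learnable, [False] * 5 + [True] * 3)


def test_curriculum_limits():
    assert not curriculum_mask(0, 8).learnable.any()
    assert curriculum_mask(8, 8).learnable.all()
    assert curriculum_mask(400, 8).learnable.all()
    with pytest.raises(ValueError):
        curriculum_mask(-1, 8)


def test_forced_blocks_always_keep_in_sampled_actions():
    rng = np.random.default_rng(0)
    state = curriculum_mask(2, 6)
    p = np.full(6, 0.01)  # would almost surely drop if sampled
    for _ in range(50):
        a = actions_with_curriculum(p, state, rng)
        assert (a[:4] == 1).all()


# ------------------------------------------------------------- REINFORCE math

def test_reinforce_loss_zero_reward_and_manual_value():
    state = curriculum_mask(3, 3)
    p = np.array([0.2, 0.5, 0.9])
    a = np.array([1, 0, 1])
    assert ap.reinforce_loss(p, a, 0.0, state) == 0.0
    expected = -(2.0) * (np.log(0.2) + np.log(0.5) + np.log(0.9))
    assert ap.reinforce_loss(p, a, 2.0, state) == pytest.approx(expected, rel=1e-12)


def test_reinforce_loss_excludes_forced_blocks():
    p = np.array([0.2, 0.5, 0.9])
    a = np.array([1, 1, 1])
    partial = curriculum_mask(1, 3)
    assert ap.reinforce_loss(p, a, 1.0, partial) == pytest.approx(-np.log(0.9), rel=1e-12)


def test_reinforce_grad_matches_finite_difference_through_sigmoid():
    rng = np.random.default_rng(1)
    z = rng.normal(size=4)
    a = np.array([1, 0, 1, 1])
    reward = 1.7
    state = curriculum_mask(4, 4)

    def loss_of(zv):
        return ap.reinforce_loss(1 / (1 + np.exp(-zv)), a, reward, state)

    grad = ap.reinforce_grad_logits(1 / (1 + np.exp(-z)), a, reward, state)
    eps = 1e-6
    for i in range(4):
        zp, zm = z.copy(), z.copy()
        zp[i] += eps
        zm[i] -= eps
        num = (loss_of(zp) - loss_of(zm)) / (2 * eps)
        assert grad[i] == pytest.approx(num, rel=1e-5)


def test_forced_blocks_get_exactly_zero_gradient():
    state = curriculum_mask(2, 5)
    p = np.array([0.3, 0.6, 0.2, 0.9, 0.5])
    a = np.array([1, 1, 1, 0, 1])
    g = ap.reinforce_grad_logits(p, a, 3.0, state)
    assert (g[:3] == 0.0).all()
    assert (g[3:] != 0.0).all()


def test_monte_carlo_gradient_matches_enumeration():
    """Score-function estimate of grad E[R(a)] vs exhaustive enumeration, N=3."""
    p = np.full(3, 0.5)
    w = np.array([2.0, 2.0, 2.0])
    state = curriculum_mask(3, 3)

    def reward_of(a):
        return float(w @ a) - 2.5

    exact = np.zeros(3)
    for i in range(8):
        a = np.array([(i >> j) & 1 for j in range(3)])
        pi = np.exp(ap.log_policy_prob(p, a))
        exact += pi * reward_of(a) * (a - p)

    rng = np.random.default_rng(12345)
    est = np.zeros(3)
    n_samples = 20_000
    for _ in range(n_samples):
        a = ap.sample_actions(p, rng)
        est -= ap.reinforce_grad_logits(p, a, reward_of(a), state)
    est /= n_samples
    np.testing.assert_allclose(est, exact, rtol=0.05)


# ------------------------------------------------------------ training loops

def test_pretraining_learns_the_phantom_task(tiny4_trained, tmp_path, splits40):
    net, history = tiny4_trained
    assert history["val_dice"][-1] >= 0.80
    assert history["loss"][0] > history["loss"][-1]
    # checkpoint reload reproduces the validation Dice exactly
    _, val, _ = splits40
    path = tmp_path / "seg.npz"
    save_backbone(net, path)
    reloaded = load_backbone(path)
    assert ap.evaluate_dice(reloaded, val) == ap.evaluate_dice(net, val)


def test_pretraining_rejects_empty_dataset():
    net = ap.build_backbone(ap.BackboneConfig(depth_variant="tiny-2"))
    with pytest.raises(ValueError):
        ap.pretrain_segmenter(net, [], ap.TrainConfig(), epochs=1)


def test_policy_training_requires_matching_block_count(splits40):
    train, _, _ = splits40
    net = ap.build_backbone(ap.BackboneConfig(depth_variant="tiny-2"))
    policy = ap.build_policy(4)
    with pytest.raises(ValueError):
        ap.train_policy(policy, net, train, ap.TrainConfig(), epochs=1)


def test_policy_training_is_deterministic_and_freezes_backbone(splits40, tmp_path):
    train, _, _ = splits40
    subset = train[:6]
    histories = []
    for _ in range(2):
        net = ap.build_backbone(ap.BackboneConfig(depth_variant="tiny-2", seed=4)).eval()
        before = {k: v.copy() for k, v in net.state_dict().items()}
        policy = ap.build_policy(2, PolicyConfig(n_blocks=2, seed=5))
        hist = ap.train_policy(policy, net, subset, ap.TrainConfig(seed=5), epochs=2)
        after = net.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)
        histories.append(hist)
    assert histories[0] == histories[1]


def test_policy_training_emits_logs_and_diagnostics(splits40, tmp_path):
    import csv, json

    train, _, _ = splits40
    net = ap.build_backbone(ap.BackboneConfig(depth_variant="tiny-2", seed=4)).eval()
    policy = ap.build_policy(2, PolicyConfig(n_blocks=2, seed=5))
    log = tmp_path / "train.jsonl"
    diag = tmp_path / "diag.csv"
    ap.train_policy(policy, net, train[:4], ap.TrainConfig(seed=5), epochs=2,
                    log_path=log, diagnostics_csv=diag)
    lines = [json.loads(l) for l in log.read_text().splitlines()]
    assert len(lines) == 2 and {"epoch", "mean_reward", "mean_kept", "dice"} <= set(lines[0])
    rows = list(csv.DictReader(diag.open()))
    assert len(rows) == 8  # 4 cases x 2 epochs x 1 MC sample
    assert {"step", "kept_count", "usage_term", "frac_correct_voxels",
            "scalar_reward"} <= set(rows[0])


def test_large_tau_keeps_all_blocks(splits40):
    """Penalty-dominated limit: with an enormous misclassification penalty and
    a backbone whose every block carries accuracy, the policy learns to keep
    everything."""
    train, val, test = splits40
    net = ap.build_backbone(ap.BackboneConfig(depth_variant="tiny-2", seed=1))
    ap.pretrain_segmenter(net, train, ap.TrainConfig(seed=1), epochs=15)
    policy = ap.build_policy(2, PolicyConfig(n_blocks=2, seed=3))
    ap.train_policy(policy, net, train, ap.TrainConfig(seed=3, lr_policy=0.01, tau=1e6),
                    epochs=15)
    kept = [
        ap.decide_actions(policy.keep_probabilities(c.volume.data)).mean()
        for c in val + test
    ]
    assert np.mean(kept) >= 0.95


def test_mean_kept_blocks_trend_downward_on_redundant_task(policy6_trained):
    _, history = policy6_trained
    kept = np.array(history["mean_kept"])
    early = kept[:5].mean()
    late = kept[-5:].mean()
    assert late < early
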