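"""Shared fixtures: phantom datasets and (expensively) pretrained networks.

Heavy fixtures are session-scoped so the supervised pretraining and the
policy-gradient run happen once for the whole suite. Tests must not mutate
them (use fresh small nets for destructive operations).
"""

import numpy as np
import pytest

import autopath as ap


@pytest.fixture(scope="session")
def dataset40():
    """Default-condition phantom dataset: 40 cases, seed 7."""
    return ap.make_dataset(40, seed=7)


@pytest.fixture(scope="session")
def splits40(dataset40):
    return ap.split_cases(dataset40)


@pytest.fixture(scope="session")
def tiny4_trained(splits40):
    """tiny-4 backbone pretrained 30 epochs on the default phantom task."""
    train, val, _ = splits40
    net = ap.build_backbone(ap.BackboneConfig(depth_variant="tiny-4", seed=1))
    history = ap.pretrain_segmenter(
        net, train, ap.TrainConfig(seed=1), epochs=30, val_cases=val
    )
    return net, history


@pytest.fixture(scope="session")
def redundant6(splits40):
    """tiny-6 pretrained with blocks at indices 4 and 5 as frozen exact no-ops.

    The two zeroed residual branches make those blocks provably redundant:
    dropping them cannot change any output voxel.
    """
    train, _, _ = splits40
    net = ap.build_backbone(ap.BackboneConfig(depth_variant="tiny-6", seed=1))
    ap.zero_residual_branch(net.blocks[4])
    ap.zero_residual_branch(net.blocks[5])
    ap.pretrain_segmenter(net, train, ap.TrainConfig(seed=1), epochs=30)
    # verify the no-op property before handing the net to tests
    x = train[0].volume.data
    full = ap.forward_with_actions(net, x, np.ones(6, dtype=int))
    dropped = ap.forward_with_actions(net, x, np.array([1, 1, 1, 1, 0, 0]))
    assert np.array_equal(full, dropped), "constructed no-op blocks are not no-ops"
    return net


@pytest.fixture(scope="session")
def policy6_trained(redundant6, splits40):
    """Policy trained by REINFORCE over the frozen redundant tiny-6 backbone."""
    train, _, _ = splits40
    policy = ap.build_policy(6, ap.PolicyConfig(n_blocks=6, seed=2))
    cfg = ap.TrainConfig(seed=2, lr_policy=0.01)
    history = ap.train_policy(policy, redundant6, train, cfg, epochs=30)
    return policy, history
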