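"""Heuristic dropping strategies, Dice metric, and the evaluation harness."""

import numpy as np
import pandas as pd
import pytest

import autopath as ap
from autopath.experiments import DropStrategySpec, round_half_up
from autopath.policy import PolicyConfig


# ------------------------------------------------------------------ strategies

def test_strategy_action_definitions():
    spec = DropStrategySpec(kind="drop_first_n", n=2)
    np.testing.assert_array_equal(
        ap.actions_for_strategy(spec, 8), [0, 0, 1, 1, 1, 1, 1, 1]
    )
    spec = DropStrategySpec(kind="drop_last_n", n=4)
    a = ap.actions_for_strategy(spec, 16)
    np.testing.assert_array_equal(a[-4:], 0)
    np.testing.assert_array_equal(a[:-4], 1)
    spec = DropStrategySpec(kind="drop_n", n=3)
    a = ap.actions_for_strategy(spec, 8)
    assert a[2] == 0 and a.sum() == 7
    a = ap.actions_for_strategy(DropStrategySpec(kind="full"), 8)
    assert a.sum() == 8


def test_drop_random_n_counts_and_seed_dependence():
    spec = DropStrategySpec(kind="drop_random_n", n=3, seed=1)
    a = ap.actions_for_strategy(spec, 8)
    assert (a == 0).sum() == 3
    positions = {tuple(ap.actions_for_strategy(DropStrategySpec(kind="drop_random_n", n=3, seed=s), 8))
                 for s in range(10)}
    assert len(positions) > 1  # positions vary with seed


def test_strategy_validation():
    with pytest.raises(ValueError):
        DropStrategySpec(kind="drop_everything")
    with pytest.raises(ValueError):
        ap.actions_for_strategy(DropStrategySpec(kind="drop_first_n", n=9), 8)
    with pytest.raises(ValueError):
        ap.actions_for_strategy(DropStrategySpec(kind="drop_n", n=0), 8)


def test_dropn_specs_cover_each_block_exactly_once():
    n = 6
    specs = [DropStrategySpec(kind="drop_n", n=k) for k in range(1, n + 1)]
    dropped = np.zeros(n, dtype=int)
    for s in specs:
        dropped += 1 - ap.actions_for_strategy(s, n)
    np.testing.assert_array_equal(dropped, 1)


# ------------------------------------------------------------------------ dice

def test_dice_reference_values():
    m = np.zeros((10, 10), dtype=np.uint8)
    m[:5] = 1
    assert ap.dice(m, m) == 1.0
    disjoint = 1 - m
    assert ap.dice(m, disjoint) == 0.0
    p = np.zeros(200, dtype=np.uint8)
    t = np.zeros(200, dtype=np.uint8)
    p[:100] = 1
    t[50:150] = 1  # |P|=|T|=100, overlap 50
    assert ap.dice(p, t) == 0.5
    assert ap.dice(np.zeros(4), np.zeros(4)) == 1.0
    with pytest.raises(ValueError):
        ap.dice(np.zeros(3), np.zeros(4))


# ------------------------------------------------------------------- harness

def test_drop_study_reports(redundant6, splits40):
    _, _, test = splits40
    reports = ap.run_drop_study(
        redundant6, test, [DropStrategySpec(kind="drop_n", n=5)]
    )
    full = reports["Full backbone"]
    assert all(r["dropped_count"] == 0 for r in full.per_case)
    # block 5 (index 4) has a zeroed residual branch: dropping it is free
    noop = reports["DropN(5)"]
    assert noop.mean_dice == pytest.approx(full.mean_dice, abs=1e-6)
    for rep in reports.values():
        for r in rep.per_case:
            assert r["dropped_count"] + r["kept_count"] == redundant6.n_blocks


def test_dependency_study_has_one_report_per_block(redundant6, splits40):
    _, _, test = splits40
    reports = ap.dependency_study(redundant6, test[:2])
    labels = [k for k in reports if k.startswith("DropN")]
    assert len(labels) == redundant6.n_blocks


def test_random_strategy_reports_are_reproducible(redundant6, splits40):
    _, _, test = splits40
    spec = DropStrategySpec(kind="drop_random_n", n=2, repeats=3, seed=9)
    r1 = ap.run_drop_study(redundant6, test, [spec])["DropRandomN(2)"]
    r2 = ap.run_drop_study(redundant6, test, [spec])["DropRandomN(2)"]
    assert r1.per_case == r2.per_case
    assert r1.mean_dice == r2.mean_dice and r1.dice_sd == r2.dice_sd


def test_random_dropping_degrades_with_n_on_average(redundant6, splits40):
    _, _, test = splits40
    specs = [DropStrategySpec(kind="drop_random_n", n=k, repeats=6, seed=3) for k in (1, 5)]
    reports = ap.run_drop_study(redundant6, test, specs)
    assert reports["DropRandomN(1)"].mean_dice > reports["DropRandomN(5)"].mean_dice


def test_autopath_eval_degenerate_keep_all_policy(redundant6, splits40):
    _, _, test = splits40
    policy = ap.build_policy(6, PolicyConfig(n_blocks=6, seed=1)).eval()
    policy.fc.weight.data[...] = 0.0
    policy.fc.bias.data[...] = 10.0  # p ~ sigmoid(10) ~ 1: keep everything
    rep = ap.run_autopath_eval(policy, redundant6, test)
    assert rep.dropping_ratio == 0.0
    full = ap.run_drop_study(redundant6, test, [])["Full backbone"]
    assert rep.mean_dice == pytest.approx(full.mean_dice, abs=1e-12)


def test_autopath_report_aggregation_identity(policy6_trained, redundant6, splits40):
    policy, _ = policy6_trained
    _, _, test = splits40
    rep = ap.run_autopath_eval(policy, redundant6, test)
    assert rep.mean_dropped == pytest.approx(
        np.mean([r["dropped_count"] for r in rep.per_case])
    )
    hist = rep.dropped_histogram()
    assert sum(hist.values()) == len(test)


def test_comparison_table_at_matched_dropping_level(policy6_trained, redundant6, splits40, tmp_path):
    policy, _ = policy6_trained
    _, val, test = splits40
    rep = ap.run_autopath_eval(policy, redundant6, val + test)
    table = ap.compare_at_equal_dropping(redundant6, val + test, rep, repeats=5, seed=2)
    n_match = round_half_up(rep.mean_dropped)
    heuristics = table[table.strategy.str.startswith("Drop")]
    assert (heuristics.mean_dropped == n_match).all()
    assert "Full backbone" in set(table.strategy)
    assert table[table.strategy == "Full backbone"].mean_dropped.iloc[0] == 0.0
    # CSV round-trip preserves the table
    path = tmp_path / "table.csv"
    table.to_csv(path, index=False)
    back = pd.read_csv(path)
    assert list(back.strategy) == list(table.strategy)
    np.testing.assert_allclose(back.mean_dice, table.mean_dice)


def test_round_half_up_convention():
    assert round_half_up(2.4) == 2
    assert round_half_up(2.5) == 3
    assert round_half_up(4.5) == 5
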