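"""Optimizer schedule, early stopping, CV bookkeeping, and grid search."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import legnet
from legnet.errors import ContractError
from legnet.train import learning_rate_at


HP_TINY = legnet.HyperParams(k=2, d0=2, d1=3, d2=2, d3=3)
TC_FAST = legnet.TrainConfig(max_epochs=30, patience=30, seed=0)


@pytest.fixture(scope="module")
def tiny_training_cohort(small_cohort):
    return (small_cohort.connectivity, small_cohort.spared, small_cohort.scores)


def test_learning_rate_schedule():
    tc = legnet.TrainConfig()
    assert learning_rate_at(0, tc) == pytest.approx(0.01)
    assert learning_rate_at(19, tc) == pytest.approx(0.01)
    assert learning_rate_at(20, tc) == pytest.approx(0.01 * 0.95)
    assert learning_rate_at(40, tc) == pytest.approx(0.01 * 0.95 ** 2)


def test_training_reduces_loss(tiny_training_cohort):
    model, hist = legnet.train(tiny_training_cohort, HP_TINY, TC_FAST)
    assert hist["train_loss"][-1] < hist["train_loss"][0]
    assert np.all(np.isfinite(hist["train_loss"]))


def test_training_deterministic(tiny_training_cohort):
    m1, _ = legnet.train(tiny_training_cohort, HP_TINY, TC_FAST)
    m2, _ = legnet.train(tiny_training_cohort, HP_TINY, TC_FAST)
    for name, arr in m1.params.arrays().items():
        assert np.array_equal(arr, getattr(m2.params, name)), name


def test_early_stopping_restores_best(tiny_training_cohort):
    tc = dataclasses.replace(TC_FAST, max_epochs=60, patience=5)
    model, hist = legnet.train(tiny_training_cohort, HP_TINY, tc)
    # the restored parameters achieve the best recorded validation loss
    X, p, y = tiny_training_cohort
    assert min(hist["val_loss"]) <= hist["val_loss"][-1] + 1e-12
    assert len(hist["val_loss"]) <= 60


def test_patience_one_stops_quickly(tiny_training_cohort):
    tc = dataclasses.replace(TC_FAST, patience=1, max_epochs=50)
    _, hist = legnet.train(tiny_training_cohort, HP_TINY, tc)
    assert len(hist["train_loss"]) < 50


def test_init_checkpoint_is_used(tiny_training_cohort):
    init = legnet.init_params(8, HP_TINY, seed=9)
    tc = dataclasses.replace(TC_FAST, max_epochs=1, patience=1)
    model, _ = legnet.train(tiny_training_cohort, HP_TINY, tc, init=init)
    # one Adam step moves each coordinate by at most the learning rate
    for name, arr in model.params.arrays().items():
        assert np.all(np.abs(arr - getattr(init, name)) <= 0.011), name


# ---------------------------------------------------------------------------
# cross-validation plans


def test_cv_plan_partitions_subjects():
    plan = legnet.CVPlan(n_folds=10, n_repeats=3, seed=1)
    assign = plan.assignments(50)
    assert assign.shape == (3, 50)
    for rep in range(3):
        counts = np.bincount(assign[rep], minlength=10)
        assert np.all(counts == 5)
    assert np.array_equal(assign, plan.assignments(50))  # reproducible
    assert not np.array_equal(assign[0], assign[1])      # reshuffled per repeat


def test_cv_plan_rejects_small_cohorts():
    with pytest.raises(ContractError):
        legnet.CVPlan(n_folds=10).assignments(5)


def test_kfold_cv_shape_and_coverage(small_cohort):
    tc = dataclasses.replace(TC_FAST, max_epochs=3)
    plan = legnet.CVPlan(n_folds=3, n_repeats=2, seed=0)
    table, scores = legnet.kfold_cv(small_cohort, HP_TINY, tc, plan,
                                    collect_scores=True)
    assert len(table) == 6  # repeats x folds
    assert table.groupby("repeat")["n_test"].sum().eq(12).all()
    assert scores.shape == (2, 12, 8, HP_TINY.k)
    assert np.allclose(scores.sum(axis=-1), 1.0, atol=1e-9)  # softmax rows


def test_summarize_cv_repeat_aggregation():
    table = pd.DataFrame({
        "repeat": [0, 0, 1, 1], "fold": [0, 1, 0, 1],
        "rmse": [1.0, 3.0, 2.0, 4.0], "mae": [1, 1, 1, 1],
        "r2": [0.5, 0.5, 0.7, 0.7], "pearson": [0.8, 0.8, 0.9, 0.9]})
    s = legnet.summarize_cv(table)
    assert s.loc["rmse", "mean"] == pytest.approx(2.5)
    assert s.loc["rmse", "sd"] == pytest.approx(np.std([2.0, 3.0], ddof=1))


# ---------------------------------------------------------------------------
# grid search (stub evaluator keeps this instantaneous)


def test_grid_search_finds_stub_minimum():
    def evaluator(hp):
        return (hp.k - 8) ** 2 + (hp.d1 - 10) ** 2 + abs(np.log10(hp.lam) + 2)

    best, table = legnet.grid_search(
        cohort=None, tc=TC_FAST, search_widths=("k", "d1"),
        evaluator=evaluator, lambdas=(1e-4, 1e-2, 1.0))
    assert best.k == 8
    assert best.d1 == 10  # fine stage refines 8 -> 10
    assert best.lam == pytest.approx(1e-2)
    assert set(table["stage"]) == {"coarse", "fine"}
    coarse_k = sorted(table.loc[table["stage"] == "coarse", "k"].unique())
    assert coarse_k == [2, 4, 8, 16, 32, 64]


def test_grid_search_degenerate_space():
    best, table = legnet.grid_search(
        cohort=None, tc=TC_FAST, search_widths=(),
        evaluator=lambda hp: hp.lam, lambdas=(0.25,))
    assert best.lam == 0.25 and len(table) == 2  # coarse + fine revisit


# ---------------------------------------------------------------------------
# pretrain -> fine-tune protocol


def test_pretrain_finetune_passes_checkpoint(monkeypatch, small_cohort):
    captured = []
    import importlib
    T = importlib.import_module("legnet.train")
    real_train = T.train

    def spy(cohort, hp, tc, init=None):
        captured.append(init)
        return real_train(cohort, hp, dataclasses.replace(tc, max_epochs=1), init=init)

    monkeypatch.setattr(T, "train", spy)
    plan = legnet.CVPlan(n_folds=3, n_repeats=1, seed=0)
    table, pretrained = T.pretrain_finetune(small_cohort, small_cohort,
                                            HP_TINY, TC_FAST, plan)
    # first call pretrains from scratch; the next 3 folds start from the
    # checkpoint; the final 3 folds start from scratch
    assert captured[0] is None
    assert all(c is pretrained.params for c in captured[1:4])
    assert all(c is None for c in captured[4:])
    assert set(table["condition"]) == {"pretrained", "scratch"}
    assert len(table) == 6


def test_pretrain_finetune_rejects_mismatched_n(small_cohort):
    rng = np.random.default_rng(0)
    other = (rng.uniform(0.5, 2.5, (12, 5, 5)), rng.uniform(0, 1, (12, 5)),
             rng.uniform(0, 100, 12))
    with pytest.raises(ContractError):
        legnet.pretrain_finetune(small_cohort, other, HP_TINY, TC_FAST,
                                 legnet.CVPlan(n_folds=3))
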