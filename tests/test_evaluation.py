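"""Confusion metrics, AUC, cross-validation protocol and correlations."""

import math

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import phoglysite as pg
from phoglysite.evaluation import ConfusionCounts, METRIC_NAMES

from conftest import random_feature_table


def test_confusion_hand_count():
    c = pg.confusion([1, 1, 0, 0], [1, 0, 0, 1])
    assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)


def test_confusion_identical_sequences():
    c = pg.confusion([1, 0, 1], [1, 0, 1])
    assert c.fp == 0 and c.fn == 0
    assert c.total == 3


def test_confusion_matches_loop_oracle():
    rng = np.random.default_rng(31)
    y = rng.integers(0, 2, size=1000)
    p = rng.integers(0, 2, size=1000)
    c = pg.confusion(y, p)
    counts = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
    for yi, pi in zip(y, p):
        if yi == 1 and pi == 1:
            counts["tp"] += 1
        elif yi == 0 and pi == 0:
            counts["tn"] += 1
        elif yi == 0 and pi == 1:
            counts["fp"] += 1
        else:
            counts["fn"] += 1
    assert (c.tp, c.tn, c.fp, c.fn) == tuple(counts.values())


def test_confusion_length_mismatch():
    with pytest.raises(ValueError, match="mismatch"):
        pg.confusion([1, 0], [1])


def test_metrics_perfect_classifier():
    rep = pg.metrics(ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
    for name in METRIC_NAMES[:5]:
        assert getattr(rep, name) == 1.0


def test_metrics_hand_arithmetic():
    rep = pg.metrics(ConfusionCounts(tp=3, fn=2, tn=4, fp=1))
    assert rep.sensitivity == 0.6
    assert rep.specificity == 0.8
    assert rep.precision == 0.75
    assert rep.accuracy == 0.7
    np.testing.assert_allclose(rep.mcc, 10 / math.sqrt(600))


def test_metrics_undefined_denominators_are_nan_not_zero():
    rep = pg.metrics(ConfusionCounts(tp=0, fp=0, tn=4, fn=2))
    assert math.isnan(rep.precision)
    assert math.isnan(rep.mcc)
    assert rep.specificity == 1.0


def test_mcc_bounds_and_extremes():
    rng = np.random.default_rng(32)
    for _ in range(200):
        tp, tn, fp, fn = rng.integers(0, 7, size=4)
        rep = pg.metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
        if not math.isnan(rep.mcc):
            assert -1.0 - 1e-12 <= rep.mcc <= 1.0 + 1e-12
    perfect = pg.metrics(ConfusionCounts(tp=3, tn=5, fp=0, fn=0))
    assert perfect.mcc == 1.0


def test_auc_perfect_ordering():
    assert pg.auc([1, 1, 0, 0], [4.0, 3.0, 2.0, 1.0]) == 1.0
    assert pg.auc([1, 1, 0, 0], [1.0, 2.0, 3.0, 4.0]) == 0.0


def test_auc_all_ties_is_half():
    assert pg.auc([1, 0, 1, 0], [0.5] * 4) == 0.5


def test_auc_single_class_undefined():
    assert math.isnan(pg.auc([1, 1], [0.2, 0.4]))


def test_auc_matches_pair_counting_oracle():
    rng = np.random.default_rng(33)
    y = rng.integers(0, 2, size=80)
    s = np.round(rng.normal(size=80), 1)  # rounding forces ties
    wins = ties = 0
    pos = s[y == 1]
    neg = s[y == 0]
    for sp in pos:
        for sn in neg:
            wins += sp > sn
            ties += sp == sn
    expected = (wins + 0.5 * ties) / (len(pos) * len(neg))
    np.testing.assert_allclose(pg.auc(y, s), expected, atol=1e-12)
    # independent library cross-check
    np.testing.assert_allclose(pg.auc(y, s), roc_auc_score(y, s), atol=1e-12)


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(34)
    y = rng.integers(0, 2, size=60)
    s = rng.normal(size=60)
    base = pg.auc(y, s)
    assert pg.auc(y, 3 * s + 7) == base
    assert pg.auc(y, np.exp(s)) == base


def test_cross_validate_fold_sizes_partition():
    rng = np.random.default_rng(35)
    table = random_feature_table(rng, n_pos=10, n_neg=10)
    rep = pg.cross_validate(table, n_folds=10, seed=0)
    sizes = [f["n"] for f in rep.per_fold]
    assert sizes == [2] * 10
    assert rep.n_folds == 10


def test_cross_validate_deterministic_by_seed():
    rng = np.random.default_rng(36)
    table = random_feature_table(rng, n_pos=15, n_neg=25)
    r1 = pg.cross_validate(table, n_folds=5, seed=3)
    r2 = pg.cross_validate(table, n_folds=5, seed=3)
    assert r1.as_dict() == r2.as_dict()


def test_cross_validate_separable_data_accurate():
    rng = np.random.default_rng(37)
    X = np.vstack(
        [
            rng.normal(4.0, 0.3, size=(40, 3)),
            rng.normal(-4.0, 0.3, size=(40, 3)),
        ]
    )
    table = pg.FeatureTable(
        X=X,
        labels=np.array([1] * 40 + [0] * 40),
        site_ids=[("p", i + 1) for i in range(80)],
        column_names=["a", "b", "c"],
    )
    rep = pg.cross_validate(table, n_folds=10, seed=0)
    assert rep.accuracy >= 0.95


def test_cross_validate_errors_on_single_class_fold():
    rng = np.random.default_rng(38)
    table = random_feature_table(rng, n_pos=3, n_neg=37)
    with pytest.raises(ValueError, match="single class"):
        pg.cross_validate(table, n_folds=10, seed=0)


def test_mean_aggregation_recomputable_from_folds():
    rng = np.random.default_rng(39)
    table = random_feature_table(rng, n_pos=20, n_neg=30)
    rep = pg.cross_validate(table, n_folds=5, seed=1)
    for name in METRIC_NAMES:
        vals = [f[name] for f in rep.per_fold]
        expected = float(np.nanmean(vals))
        agg = getattr(rep, name)
        if math.isnan(expected):
            assert math.isnan(agg)
        else:
            np.testing.assert_allclose(agg, expected)


def test_abs_pearson_identity_and_sign():
    rng = np.random.default_rng(40)
    a = rng.normal(size=100)
    assert pg.abs_pearson(a, a) == pytest.approx(1.0)
    assert pg.abs_pearson(a, -a) == pytest.approx(1.0)


def test_abs_pearson_recovers_known_correlation():
    rng = np.random.default_rng(41)
    n = 10_000
    x = rng.normal(size=n)
    y = 0.5 * x + math.sqrt(1 - 0.25) * rng.normal(size=n)
    assert abs(pg.abs_pearson(x, y) - 0.5) < 0.05


def test_abs_pearson_zero_variance_undefined():
    assert math.isnan(pg.abs_pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


def test_coil_strand_correlation_groups(tiny_table):
    out = pg.coil_strand_correlation(tiny_table)
    assert set(out) == {"positive", "negative", "all"}
    for v in out.values():
        assert 0.0 <= v <= 1.0
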