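"""Metric oracles, subset evaluation, and Shapley importance behavior."""

import numpy as np
import pandas as pd
import pytest

from ketopred.evaluation import (
    FEATURE_SUBSETS,
    MetricError,
    evaluate_subsets,
    pr_auc,
    roc_auc,
    shap_importance,
)
from ketopred.features import FEATURE_COLUMNS
from ketopred.model import GridSpec, cross_val_models, make_folds
from test_model import toy_table


def pairwise_concordance(y, s):
    """O(n^2) Mann-Whitney oracle: ties counted half."""
    y, s = np.asarray(y), np.asarray(s)
    pos, neg = s[y == 1], s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_roc_auc_hand_examples():
    assert roc_auc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8]) == 0.75
    assert roc_auc([0, 1], [0.2, 0.9]) == 1.0
    assert roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5


def test_roc_auc_matches_concordance_oracle():
    rng = np.random.default_rng(123)
    for _ in range(200):
        n = rng.integers(4, 40)
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        s = np.round(rng.normal(size=n), 1)  # rounding forces ties
        assert roc_auc(y, s) == pytest.approx(pairwise_concordance(y, s), abs=1e-12)


def test_pr_auc_hand_examples():
    assert pr_auc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.6]) == pytest.approx(5 / 6)
    assert pr_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
    # constant scorer collapses to a single PR point at (1, prevalence)
    assert pr_auc([1, 0, 0, 0], [0.5] * 4) == pytest.approx(0.25)


def test_metric_errors():
    with pytest.raises(MetricError):
        roc_auc([1, 1, 1], [0.1, 0.2, 0.3])
    with pytest.raises(MetricError):
        pr_auc([0, 0, 0], [0.1, 0.2, 0.3])


def test_pr_auc_random_scorer_near_prevalence():
    rng = np.random.default_rng(7)
    n = 10_000
    y = (rng.random(n) < 0.2).astype(int)
    s = rng.random(n)
    assert abs(pr_auc(y, s) - y.mean()) < 0.05


def test_combined_report_has_five_folds():
    t = toy_table(n=200, n_events=50, seed=1)
    reports, _ = evaluate_subsets(t, GridSpec.fast(), subsets=["combined"],
                                  subgroups=("all",), seed=1)
    (rep,) = reports
    assert len(rep.per_fold_roc_auc) == len(rep.per_fold_pr_auc) == 5
    assert rep.sd_roc_auc == pytest.approx(np.std(rep.per_fold_roc_auc, ddof=1))


def test_under18_subgroup_filters_ages():
    t = toy_table(n=400, n_events=120, seed=3)
    reports, _ = evaluate_subsets(t, GridSpec.fast(), subsets=["combined"],
                                  subgroups=("under18",), seed=3)
    (rep,) = reports
    assert rep.n_rows == (t["age_years"] < 18).sum()


def test_subset_definitions_partition_sensibly():
    assert len(FEATURE_SUBSETS["combined"]) == 26
    assert len(FEATURE_SUBSETS["insulin"]) == 6
    assert len(FEATURE_SUBSETS["smbg"]) == 3
    assert FEATURE_SUBSETS["current_glucose"] == ["cgm12_latest"]
    assert len(FEATURE_SUBSETS["cgm6"]) == 9  # 8 stats + hour of day
    assert len(FEATURE_SUBSETS["cgm12"]) == 8


def test_cgm_driven_labels_favor_cgm_subset():
    """When only a CGM feature carries signal, CGM beats the insulin subset."""
    rng = np.random.default_rng(11)
    t = toy_table(n=400, n_events=0, seed=11)
    logits = 2.0 * t["cgm12_mean"].to_numpy() + rng.normal(scale=0.5, size=len(t))
    t["label"] = (logits > np.quantile(logits, 0.75)).astype(int)
    reports, _ = evaluate_subsets(t, GridSpec.fast(), subsets=["cgm12", "insulin"],
                                  subgroups=("all",), seed=11)
    by = {r.feature_subset: r.mean_roc_auc for r in reports}
    assert by["cgm12"] > by["insulin"]


def test_shap_single_signal_ranked_first_and_constants_zero():
    t = toy_table(n=300, n_events=0, seed=13)
    rng = np.random.default_rng(13)
    t["label"] = (t["cgm12_latest"] + 0.2 * rng.normal(size=len(t)) > 0.5).astype(int)
    t["cgm6_sd"] = 1.234  # constant feature: no split possible
    folds = make_folds(t, seed=13)
    fitted = cross_val_models(t, folds, GridSpec.fast().points()[0], seed=13)
    report = shap_importance(fitted, t)
    assert report.ranking[0] == "cgm12_latest"
    const_attr = report.table.set_index("feature").loc["cgm6_sd", "mean_abs_shap"]
    assert const_attr == 0.0
    assert sorted(report.ranking) == sorted(FEATURE_COLUMNS)
    assert (report.table["mean_abs_shap"] >= 0).all()


def test_noise_feature_ranks_below_signal_over_seeds():
    """A pure-noise column loses to the generative column across seeds."""
    wins = 0
    for seed in range(10):
        t = toy_table(n=250, n_events=0, seed=seed)
        rng = np.random.default_rng(seed)
        t["label"] = (t["cgm6_mean"] > 0.3).astype(int)
        t["bgm_min"] = rng.normal(size=len(t))  # pure noise stand-in
        folds = make_folds(t, seed=seed)
        fitted = cross_val_models(t, folds, GridSpec.fast().points()[0], seed=seed)
        ranking = shap_importance(fitted, t).ranking
        wins += ranking.index("cgm6_mean") < ranking.index("bgm_min")
    assert wins >= 9
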