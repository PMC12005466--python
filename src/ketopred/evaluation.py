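"""Discrimination metrics, fold-wise uncertainty, Shapley importance,
feature-subset comparison and the pediatric sensitivity mode.

ROC-AUC is the Mann–Whitney concordance probability (ties counted half);
PR-AUC is average precision (sum over recall increments of precision at
each threshold), whose chance level equals the event prevalence — the
honest baseline for imbalanced event detection.  Uncertainty of both is
reported as the standard deviation across the five cross-validation folds.

Shapley attributions use exact TreeSHAP as implemented inside XGBoost
(``pred_contribs``), computed on each fold's validation rows only and
aggregated as the mean absolute attribution per feature, averaged across
folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost
from sklearn.metrics import average_precision_score, roc_auc_score

from .features import FEATURE_COLUMNS
from .model import FoldAssignment, GridSpec, cross_val_models, grid_search, make_folds

__all__ = [
    "FEATURE_SUBSETS",
    "MetricError",
    "CvReport",
    "ImportanceReport",
    "roc_auc",
    "pr_auc",
    "evaluate_subsets",
    "shap_importance",
]

#: The feature subsets compared in the subset analysis.
FEATURE_SUBSETS: dict[str, list[str]] = {
    "insulin": [c for c in FEATURE_COLUMNS if c.startswith("ins_")],
    "smbg": [c for c in FEATURE_COLUMNS if c.startswith("bgm_")],
    "current_glucose": ["cgm12_latest"],
    "cgm6": [c for c in FEATURE_COLUMNS if c.startswith("cgm6_")] + ["hour_of_day"],
    "cgm12": [c for c in FEATURE_COLUMNS if c.startswith("cgm12_")],
    "combined": list(FEATURE_COLUMNS),
}


class MetricError(ValueError):
    """Metric undefined for the given labels (e.g. a single class)."""


@dataclass
class CvReport:
    """Per-fold and aggregate discrimination for one subset × subgroup."""

    feature_subset: str
    subgroup: str
    per_fold_roc_auc: list[float]
    per_fold_pr_auc: list[float]
    hyperparameters: dict
    n_rows: int
    n_events: int

    @property
    def mean_roc_auc(self) -> float:
        return float(np.mean(self.per_fold_roc_auc))

    @property
    def sd_roc_auc(self) -> float:
        return float(np.std(self.per_fold_roc_auc, ddof=1))

    @property
    def mean_pr_auc(self) -> float:
        return float(np.mean(self.per_fold_pr_auc))

    @property
    def sd_pr_auc(self) -> float:
        return float(np.std(self.per_fold_pr_auc, ddof=1))

    def as_row(self) -> dict:
        return {
            "feature_subset": self.feature_subset,
            "subgroup": self.subgroup,
            "mean_roc_auc": self.mean_roc_auc,
            "sd_roc_auc": self.sd_roc_auc,
            "mean_pr_auc": self.mean_pr_auc,
            "sd_pr_auc": self.sd_pr_auc,
            "n_rows": self.n_rows,
            "n_events": self.n_events,
            **{f"roc_auc_fold{f}": v for f, v in enumerate(self.per_fold_roc_auc)},
            **{f"pr_auc_fold{f}": v for f, v in enumerate(self.per_fold_pr_auc)},
        }


@dataclass
class ImportanceReport:
    """Mean |Shapley attribution| per feature, averaged across folds."""

    table: pd.DataFrame  # columns: feature, mean_abs_shap, rank (1 = largest)

    def top(self, k: int = 10) -> pd.DataFrame:
        return self.table.nsmallest(k, "rank").reset_index(drop=True)

    @property
    def ranking(self) -> list[str]:
        return self.table.sort_values("rank")["feature"].tolist()


def roc_auc(labels, scores) -> float:
    """Probability a random event outranks a random non-event (ties half)."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise MetricError("roc_auc needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def pr_auc(labels, scores) -> float:
    """Average precision; equals prevalence for an uninformative scorer."""
    y = np.asarray(labels)
    if y.sum() == 0:
        raise MetricError("pr_auc needs at least one event")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def _subgroup_table(table: pd.DataFrame, subgroup: str) -> pd.DataFrame:
    if subgroup == "all":
        return table
    if subgroup == "under18":
        return table[table["age_years"] < 18].reset_index(drop=True)
    raise ValueError(f"unknown subgroup {subgroup!r}")


def evaluate_subsets(
    table: pd.DataFrame,
    grid: GridSpec,
    k: int = 5,
    grouped: bool = False,
    seed: int = 2024,
    subsets: list[str] | None = None,
    subgroups: tuple[str, ...] = ("all", "under18"),
) -> tuple[list[CvReport], dict[str, FoldAssignment]]:
    """Train/tune/evaluate once per feature subset and subgroup.

    Folds are drawn once per subgroup and shared across subsets so the
    subset comparison is paired.  Raises with the subgroup named when a
    subgroup is too small for stratified folds.
    """
    subsets = subsets or list(FEATURE_SUBSETS)
    reports: list[CvReport] = []
    folds_by_subgroup: dict[str, FoldAssignment] = {}
    for subgroup in subgroups:
        sub = _subgroup_table(table, subgroup)
        try:
            folds = make_folds(sub, k=k, stratified=True, grouped=grouped, seed=seed)
        except ValueError as exc:
            raise type(exc)(f"subgroup {subgroup!r}: {exc}") from exc
        folds_by_subgroup[subgroup] = folds
        for name in subsets:
            cols = FEATURE_SUBSETS[name]
            best, _ = grid_search(sub, folds, grid, feature_cols=cols, seed=seed)
            fitted = cross_val_models(sub, folds, best, feature_cols=cols, seed=seed)
            y = sub["label"].to_numpy()
            rocs = [roc_auc(y[val], p) for _, val, p in fitted]
            prs = [pr_auc(y[val], p) for _, val, p in fitted]
            reports.append(
                CvReport(
                    feature_subset=name,
                    subgroup=subgroup,
                    per_fold_roc_auc=rocs,
                    per_fold_pr_auc=prs,
                    hyperparameters=best,
                    n_rows=len(sub),
                    n_events=int(y.sum()),
                )
            )
    return reports, folds_by_subgroup


def shap_importance(
    fold_models: list,
    table: pd.DataFrame,
    feature_cols: list[str] | None = None,
) -> ImportanceReport:
    """Aggregate TreeSHAP attributions over each fold's validation rows.

    ``fold_models`` is the (model, val_idx, val_scores) list produced by
    ``cross_val_models``.  A constant feature receives attribution exactly 0
    (no tree can split on it).
    """
    feature_cols = feature_cols or FEATURE_COLUMNS
    X = table[feature_cols]
    per_fold = []
    for clf, val, _ in fold_models:
        booster = clf.get_booster()
        if booster.num_features() != len(feature_cols):
            raise ValueError(
                f"model expects {booster.num_features()} features, "
                f"got {len(feature_cols)}"
            )
        dm = xgboost.DMatrix(X.iloc[val], missing=np.nan)
        contribs = booster.predict(dm, pred_contribs=True)  # (n, p+1), last = bias
        per_fold.append(np.abs(contribs[:, :-1]).mean(axis=0))
    mean_abs = np.mean(per_fold, axis=0)
    order = np.argsort(-mean_abs, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(1, len(order) + 1)
    tbl = pd.DataFrame(
        {"feature": feature_cols, "mean_abs_shap": mean_abs, "rank": rank}
    )
    return ImportanceReport(tbl.sort_values("rank").reset_index(drop=True))
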