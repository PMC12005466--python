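"""Static figures: ROC / PR curves, importance bars, a probability trace.

Thin presentation layer over the evaluation outputs; nothing here feeds
back into any computed number.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from sklearn.metrics import precision_recall_curve, roc_curve


def write_figures(features, folds, fitted, importance, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    y = features["label"].to_numpy()
    scores = np.empty(len(y))
    for _, val, p in fitted:
        scores[val] = p

    fpr, tpr, _ = roc_curve(y, scores)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.plot(fpr, tpr)
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title("Combined model ROC (pooled CV predictions)")
    fig.tight_layout()
    fig.savefig(out / "roc.png", dpi=150)
    plt.close(fig)

    prec, rec, _ = precision_recall_curve(y, scores)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.plot(rec, prec)
    ax.axhline(y.mean(), ls="--", c="grey", lw=0.8)
    ax.set_xlabel("Recall")
    ax.set_ylabel("Precision")
    ax.set_title("Combined model PR (pooled CV predictions)")
    fig.tight_layout()
    fig.savefig(out / "pr.png", dpi=150)
    plt.close(fig)

    top = importance.top(10).iloc[::-1]
    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.barh(top["feature"], top["mean_abs_shap"])
    ax.set_xlabel("mean |SHAP| (averaged across folds)")
    fig.tight_layout()
    fig.savefig(out / "importance.png", dpi=150)
    plt.close(fig)

    # probability trace for the patient with the most windows
    pid = features["patient_id"].value_counts().idxmax()
    mask = (features["patient_id"] == pid).to_numpy()
    fig, ax = plt.subplots(figsize=(6, 3))
    t = features.loc[mask, "ketone_time"] / 1440.0
    ax.plot(t, scores[mask], "o-")
    ax.set_xlabel("day")
    ax.set_ylabel("P(elevated ketones)")
    ax.set_title(f"Predicted event probability, patient {pid}")
    fig.tight_layout()
    fig.savefig(out / "probability_trace.png", dpi=150)
    plt.close(fig)
    return out
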