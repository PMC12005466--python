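"""The 26-predictor feature vector engineered from one observation window.

Per glucose stream (CGM over 6 h and over 12 h) eight statistics are
computed: latest, maximum, minimum, mean, sample standard deviation,
fraction of readings strictly above 300 mg/dL, decrease ratio, and mean
decrease.  The hour of day of the ketone check, six insulin sums (basal /
bolus / meal crossed with the 0-6 h and 6-12 h sub-windows), and three SMBG
statistics (latest, maximum, minimum) complete the 26.

The decrease statistics capture fine-scale glucose dynamics: with CGM
readings x1..xn, ``decreases`` counts consecutive pairs with
x_{i+1} − x_i < 0; ``decrease_ratio`` is decreases / n and ``mean_decrease``
the mean absolute drop over the decreasing pairs (0 when none decrease).
A steadily climbing glucose ramp, the signature of insulin deprivation,
has a decrease ratio near zero.

SMBG readings are patient-initiated and often absent from a window; their
three features are then NaN, the native missing marker the gradient-boosted
learner consumes directly.  No imputation is ever performed.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .windowing import ObservationWindow

__all__ = [
    "FEATURE_COLUMNS",
    "META_COLUMNS",
    "DegenerateInputError",
    "IneligibleWindowError",
    "decrease_stats",
    "frac_above_threshold",
    "summary_features",
    "insulin_sums",
    "build_feature_vector",
    "build_feature_table",
]

HYPER_THRESHOLD_MG_DL = 300.0

#: Fixed predictor order — the model contract.  26 columns.
FEATURE_COLUMNS: list[str] = [
    "cgm6_latest", "cgm6_max", "cgm6_min", "cgm6_mean", "cgm6_sd",
    "cgm6_frac_above_300", "cgm6_decrease_ratio", "cgm6_mean_decrease",
    "hour_of_day",
    "cgm12_latest", "cgm12_max", "cgm12_min", "cgm12_mean", "cgm12_sd",
    "cgm12_frac_above_300", "cgm12_decrease_ratio", "cgm12_mean_decrease",
    "ins_basal_sum_0_6", "ins_basal_sum_6_12",
    "ins_bolus_sum_0_6", "ins_bolus_sum_6_12",
    "ins_meal_sum_0_6", "ins_meal_sum_6_12",
    "bgm_latest", "bgm_max", "bgm_min",
]

META_COLUMNS: list[str] = ["patient_id", "ketone_time", "age_years", "label"]


class DegenerateInputError(ValueError):
    """A glucose series too short for the requested statistic."""


class IneligibleWindowError(ValueError):
    """Feature extraction was asked for a window that failed eligibility."""


def decrease_stats(series: np.ndarray) -> tuple[float, float]:
    """(decrease_ratio, mean_decrease) of an ordered glucose series.

    Requires n >= 2 consecutive readings; an eligible window always has
    far more.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise DegenerateInputError("decrease_stats needs at least 2 samples")
    diffs = np.diff(x)
    drops = -diffs[diffs < 0]
    ratio = drops.size / x.size
    mean_dec = float(drops.mean()) if drops.size else 0.0
    return float(ratio), mean_dec


def frac_above_threshold(series: np.ndarray, threshold: float = HYPER_THRESHOLD_MG_DL) -> float:
    """Fraction of readings strictly greater than ``threshold``."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise DegenerateInputError("frac_above_threshold needs a nonempty series")
    return float((x > threshold).mean())


def summary_features(series: np.ndarray) -> tuple[float, float, float, float, float]:
    """(latest, max, min, mean, sd) of an ordered series.

    ``sd`` uses the sample (n−1) denominator; a single-sample series has
    sd 0 by convention.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise DegenerateInputError("summary_features needs a nonempty series")
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    return float(x[-1]), float(x.max()), float(x.min()), float(x.mean()), sd


def insulin_sums(window: ObservationWindow) -> dict[str, float]:
    """Six insulin-unit sums: {basal, bolus, meal} × {0-6 h, 6-12 h}."""
    out: dict[str, float] = {}
    for typ in ("basal", "bolus", "meal"):
        for tag, bucket in (("0_6", window.ins_recent), ("6_12", window.ins_early)):
            amounts = np.asarray(bucket.get(typ, ()), dtype=float)
            if amounts.size and (amounts < 0).any():
                raise ValueError(f"negative {typ} insulin amount in window")
            # exactly-rounded sum: independent of record storage order
            out[f"ins_{typ}_sum_{tag}"] = math.fsum(amounts)
    return out


def build_feature_vector(window: ObservationWindow) -> dict[str, float]:
    """All 26 predictors plus metadata for one eligible window."""
    if not window.eligible:
        raise IneligibleWindowError(
            f"{window.patient_id} @ {window.ketone_time}: window failed eligibility"
        )
    vec: dict[str, float] = {}
    for prefix, values in (("cgm6", window.cgm6_values), ("cgm12", window.cgm12_values)):
        latest, mx, mn, mean, sd = summary_features(values)
        ratio, mean_dec = decrease_stats(values)
        vec[f"{prefix}_latest"] = latest
        vec[f"{prefix}_max"] = mx
        vec[f"{prefix}_min"] = mn
        vec[f"{prefix}_mean"] = mean
        vec[f"{prefix}_sd"] = sd
        vec[f"{prefix}_frac_above_300"] = frac_above_threshold(values)
        vec[f"{prefix}_decrease_ratio"] = ratio
        vec[f"{prefix}_mean_decrease"] = mean_dec
    vec["hour_of_day"] = float((window.ketone_time // 60) % 24)
    vec.update(insulin_sums(window))
    if window.smbg_values.size:
        latest, mx, mn, _, _ = summary_features(window.smbg_values)
        vec["bgm_latest"], vec["bgm_max"], vec["bgm_min"] = latest, mx, mn
    else:
        vec["bgm_latest"] = vec["bgm_max"] = vec["bgm_min"] = np.nan
    row = {
        "patient_id": window.patient_id,
        "ketone_time": window.ketone_time,
        "age_years": window.age_years,
        "label": window.label,
    }
    row.update({c: vec[c] for c in FEATURE_COLUMNS})
    return row


def build_feature_table(windows: list[ObservationWindow]) -> pd.DataFrame:
    """Feature rows for the eligible windows, in the fixed column order."""
    rows = [build_feature_vector(w) for w in windows if w.eligible]
    return pd.DataFrame(rows, columns=META_COLUMNS + FEATURE_COLUMNS)
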