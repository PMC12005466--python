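"""Feature formulas against frozen hand-derived values and brute-force oracles."""

import math

import numpy as np
import pytest

from ketopred.features import (
    FEATURE_COLUMNS,
    DegenerateInputError,
    IneligibleWindowError,
    build_feature_table,
    build_feature_vector,
    decrease_stats,
    frac_above_threshold,
    insulin_sums,
    summary_features,
)
from ketopred.synthetic import SimConfig, generate_cohort
from ketopred.windowing import assemble_dataset, extract_window
from conftest import full_grid_patient


# ---------------------------------------------------------------- decrease


@pytest.mark.parametrize(
    "series, ratio, mean_dec",
    [
        ([100, 110, 120, 130], 0.0, 0.0),       # monotone nondecreasing
        ([100, 90, 100, 90], 0.5, 10.0),        # 2 decreasing pairs of n=4
        ([5, 4, 3, 2, 1], 0.8, 1.0),            # 4 decreasing pairs of n=5
        ([200, 200], 0.0, 0.0),                 # flat pair is not a decrease
    ],
)
def test_decrease_stats_hand_examples(series, ratio, mean_dec):
    assert decrease_stats(np.array(series, dtype=float)) == (ratio, mean_dec)


def test_decrease_stats_rejects_short_series():
    with pytest.raises(DegenerateInputError):
        decrease_stats(np.array([100.0]))


# ---------------------------------------------------------------- fraction above


@pytest.mark.parametrize(
    "series, expected",
    [
        ([310, 290, 305, 300], 0.5),  # strictly above only: 310, 305
        ([100, 200, 300], 0.0),
        ([301, 400], 1.0),
    ],
)
def test_frac_above_300(series, expected):
    assert frac_above_threshold(np.array(series, dtype=float), 300.0) == expected


# ---------------------------------------------------------------- summaries


def test_summary_single_sample_sd_zero():
    assert summary_features(np.array([200.0])) == (200, 200, 200, 200, 0.0)


def test_summary_two_point():
    latest, mx, mn, mean, sd = summary_features(np.array([100.0, 300.0]))
    assert (latest, mx, mn, mean) == (300, 300, 100, 200)
    assert sd == pytest.approx(np.sqrt(2 * 100.0**2))  # n-1 denominator


# ---------------------------------------------------------------- insulin sums


def test_insulin_sums_basal_half_hourly(eligible_window):
    t = eligible_window.ketone_time
    eligible_window.ins_recent = {"basal": np.full(12, 0.5), "bolus": np.array([]), "meal": np.array([])}
    eligible_window.ins_early = {"basal": np.array([]), "bolus": np.array([]), "meal": np.array([4.0])}
    sums = insulin_sums(eligible_window)
    assert sums["ins_basal_sum_0_6"] == 6.0
    assert sums["ins_meal_sum_6_12"] == 4.0
    assert sums["ins_meal_sum_0_6"] == 0.0
    assert sums["ins_bolus_sum_0_6"] == sums["ins_bolus_sum_6_12"] == 0.0


def test_insulin_sums_reject_negative(eligible_window):
    eligible_window.ins_recent["basal"] = np.array([-0.1])
    with pytest.raises(ValueError, match="negative"):
        insulin_sums(eligible_window)


# ---------------------------------------------------------------- vectors


def test_vector_has_exactly_26_predictors(eligible_window):
    row = build_feature_vector(eligible_window)
    preds = set(row) - {"patient_id", "ketone_time", "age_years", "label"}
    assert preds == set(FEATURE_COLUMNS)
    assert len(FEATURE_COLUMNS) == 26


def test_missing_smbg_gives_nan_markers():
    w = extract_window(full_grid_patient(with_smbg=False), 1440)
    row = build_feature_vector(w)
    assert all(np.isnan(row[c]) for c in ("bgm_latest", "bgm_max", "bgm_min"))
    others = [c for c in FEATURE_COLUMNS if not c.startswith("bgm_")]
    assert all(np.isfinite(row[c]) for c in others)


def test_constant_cgm_yields_zero_spread():
    w = extract_window(full_grid_patient(), 1440)
    w.cgm6_values = np.full(72, 250.0)
    w.cgm12_values = np.full(144, 250.0)
    row = build_feature_vector(w)
    assert row["cgm6_sd"] == row["cgm12_sd"] == 0.0
    assert row["cgm6_decrease_ratio"] == row["cgm12_decrease_ratio"] == 0.0


def test_ineligible_window_rejected():
    w = extract_window(full_grid_patient(with_insulin=False), 1440)
    with pytest.raises(IneligibleWindowError):
        build_feature_vector(w)


# ---------------------------------------------------------------- oracles


def brute_force_features(w):
    """Naive per-window recomputation, independent of the features module."""
    out = {}
    for prefix, vals in (("cgm6", list(w.cgm6_values)), ("cgm12", list(w.cgm12_values))):
        out[f"{prefix}_latest"] = vals[-1]
        out[f"{prefix}_max"] = max(vals)
        out[f"{prefix}_min"] = min(vals)
        mean = sum(vals) / len(vals)
        out[f"{prefix}_mean"] = mean
        var = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1) if len(vals) > 1 else 0.0
        out[f"{prefix}_sd"] = var ** 0.5
        out[f"{prefix}_frac_above_300"] = sum(v > 300 for v in vals) / len(vals)
        drops = [vals[i] - vals[i + 1] for i in range(len(vals) - 1) if vals[i + 1] < vals[i]]
        out[f"{prefix}_decrease_ratio"] = len(drops) / len(vals)
        out[f"{prefix}_mean_decrease"] = sum(drops) / len(drops) if drops else 0.0
    out["hour_of_day"] = (w.ketone_time // 60) % 24
    for typ in ("basal", "bolus", "meal"):
        out[f"ins_{typ}_sum_0_6"] = math.fsum(w.ins_recent[typ])
        out[f"ins_{typ}_sum_6_12"] = math.fsum(w.ins_early[typ])
    if len(w.smbg_values):
        out["bgm_latest"] = w.smbg_values[-1]
        out["bgm_max"] = max(w.smbg_values)
        out["bgm_min"] = min(w.smbg_values)
    else:
        out["bgm_latest"] = out["bgm_max"] = out["bgm_min"] = np.nan
    return out


def _oracle_check(windows):
    exact = {c for c in FEATURE_COLUMNS
             if "sum" in c or "frac" in c or c in ("hour_of_day",)}
    checked = 0
    for w in windows:
        if not w.eligible:
            continue
        got = build_feature_vector(w)
        want = brute_force_features(w)
        for c in FEATURE_COLUMNS:
            if np.isnan(want[c]):
                assert np.isnan(got[c]), c
            elif c in exact:
                assert got[c] == want[c], c
            else:
                assert got[c] == pytest.approx(want[c], rel=1e-9), c
        checked += 1
    return checked


def test_features_match_brute_force_oracle(small_cohort):
    assert _oracle_check(assemble_dataset(small_cohort)) >= 50


def test_features_invariant_to_record_storage_order(small_cohort):
    """Shuffling raw records then re-sorting by time changes no feature."""
    rng = np.random.default_rng(0)
    p = small_cohort[0]
    perm = rng.permutation(len(p.cgm_times))
    order = np.argsort(p.cgm_times[perm], kind="stable")
    shuffled = type(p)(
        patient_id=p.patient_id,
        age_years=p.age_years,
        cgm_times=p.cgm_times[perm][order],
        cgm_values=p.cgm_values[perm][order],
        insulin_times=p.insulin_times,
        insulin_amounts=p.insulin_amounts,
        insulin_types=p.insulin_types,
        smbg_times=p.smbg_times,
        smbg_values=p.smbg_values,
        ketone_times=p.ketone_times,
        ketone_values=p.ketone_values,
    )
    for kt in p.ketone_times[:5]:
        a = extract_window(p, int(kt))
        b = extract_window(shuffled, int(kt))
        if a.eligible:
            assert build_feature_vector(a) == build_feature_vector(b)


def test_subwindow_extremes_nested(small_cohort):
    table = build_feature_table(assemble_dataset(small_cohort))
    assert (table["cgm6_max"] <= table["cgm12_max"]).all()
    assert (table["cgm6_min"] >= table["cgm12_min"]).all()
    assert ((table["cgm6_decrease_ratio"] >= 0) & (table["cgm6_decrease_ratio"] < 1)).all()
    assert table.filter(like="ins_").ge(0).all().all()
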