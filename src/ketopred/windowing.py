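"""12-hour pre-ketone observation windows and eligibility filtering.

Every ketone-meter sample anchors one observation window covering the
preceding 12 hours of CGM, insulin and SMBG data.  Window boundaries are
half-open on the left and closed on the right: the 12-h window is
(t − 12 h, t], the recent sub-window (t − 6 h, t], and the insulin stream
is split into (t − 6 h, t] ("0-6 h") and (t − 12 h, t − 6 h] ("6-12 h").
The anchor sample itself is therefore included, so the latest glucose value
is always the reading closest to the ketone check.

Eligibility mirrors the trial inclusion rule: at least ``min_cgm_samples``
CGM readings in the 12-h window (72 at 5-minute sampling), CGM wear time
of at least ``wear_min`` (50 %), and at least one insulin delivery record
anywhere in the window.  The two CGM conditions coincide at 5-minute
sampling but are checked independently so coarser grids behave correctly.
SMBG is never required; its features may be missing downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .synthetic import ELEVATED_KETONE_MMOL_L, PatientRecord

__all__ = [
    "WindowConfig",
    "ObservationWindow",
    "KetoneLookupError",
    "extract_window",
    "assemble_dataset",
]

logger = logging.getLogger(__name__)


class KetoneLookupError(KeyError):
    """The requested anchor time is not a ketone sample of the patient."""


@dataclass(frozen=True)
class WindowConfig:
    """Windowing thresholds; defaults are the protocol constants."""

    window_h: float = 12.0
    subwindow_h: float = 6.0
    wear_min: float = 0.5
    min_cgm_samples: int = 72
    label_threshold_mmol_l: float = ELEVATED_KETONE_MMOL_L
    cgm_interval_min: int = 5
    min_gap_h: float | None = None  # optionally skip ketone checks closer than this

    def validate(self) -> None:
        if not 0.0 <= self.wear_min <= 1.0:
            raise ValueError("wear_min must lie in [0, 1]")
        if self.window_h <= 0 or self.subwindow_h <= 0 or self.subwindow_h > self.window_h:
            raise ValueError("need 0 < subwindow_h <= window_h")
        if self.min_cgm_samples < 1:
            raise ValueError("min_cgm_samples must be >= 1")
        if self.cgm_interval_min < 1:
            raise ValueError("cgm_interval_min must be >= 1")
        if self.label_threshold_mmol_l <= 0:
            raise ValueError("label_threshold_mmol_l must be positive")


@dataclass
class ObservationWindow:
    """All streams in the 12 h before one ketone sample, plus eligibility."""

    patient_id: str
    age_years: float
    ketone_time: int
    ketone_value: float
    label: int
    cgm12_times: np.ndarray
    cgm12_values: np.ndarray
    cgm6_times: np.ndarray
    cgm6_values: np.ndarray
    ins_recent: dict[str, np.ndarray] = field(default_factory=dict)  # (t-6h, t] amounts by type
    ins_early: dict[str, np.ndarray] = field(default_factory=dict)   # (t-12h, t-6h]
    smbg_times: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    smbg_values: np.ndarray = field(default_factory=lambda: np.array([]))
    wear_fraction: float = 0.0
    eligible: bool = False


def _slice_halfopen(times: np.ndarray, values: np.ndarray, lo: float, hi: float):
    """Return entries with lo < t <= hi (streams assumed time-sorted)."""
    i = np.searchsorted(times, lo, side="right")
    j = np.searchsorted(times, hi, side="right")
    return times[i:j], values[i:j]


def _dedup_last(times: np.ndarray, values: np.ndarray):
    """Keep the last record at each duplicated timestamp (device overwrite)."""
    if len(times) < 2:
        return times, values
    keep = np.append(np.diff(times) > 0, True)
    return times[keep], values[keep]


def extract_window(
    patient: PatientRecord,
    ketone_time: int,
    config: WindowConfig | None = None,
) -> ObservationWindow:
    """Slice the 12-h observation window anchored at one ketone sample."""
    config = config or WindowConfig()
    config.validate()
    idx = np.flatnonzero(patient.ketone_times == ketone_time)
    if idx.size == 0:
        raise KetoneLookupError(
            f"{patient.patient_id}: no ketone sample at t={ketone_time} min"
        )
    ketone_value = float(patient.ketone_values[idx[-1]])
    t = float(ketone_time)
    w = config.window_h * 60.0
    sw = config.subwindow_h * 60.0

    cgm_t, cgm_v = _dedup_last(patient.cgm_times, patient.cgm_values)
    c12_t, c12_v = _slice_halfopen(cgm_t, cgm_v, t - w, t)
    c6_t, c6_v = _slice_halfopen(cgm_t, cgm_v, t - sw, t)
    smbg_t, smbg_v = _dedup_last(patient.smbg_times, patient.smbg_values)
    s_t, s_v = _slice_halfopen(smbg_t, smbg_v, t - w, t)

    ins_recent: dict[str, np.ndarray] = {}
    ins_early: dict[str, np.ndarray] = {}
    for typ in ("basal", "bolus", "meal"):
        mask = patient.insulin_types == typ
        it = patient.insulin_times[mask]
        ia = patient.insulin_amounts[mask]
        _, a_recent = _slice_halfopen(it, ia, t - sw, t)
        _, a_early = _slice_halfopen(it, ia, t - w, t - sw)
        ins_recent[typ] = a_recent
        ins_early[typ] = a_early

    expected = w / config.cgm_interval_min
    wear_fraction = min(1.0, len(c12_t) / expected)
    has_insulin = any(len(a) for a in ins_recent.values()) or any(
        len(a) for a in ins_early.values()
    )
    eligible = (
        len(c12_t) >= config.min_cgm_samples
        and wear_fraction >= config.wear_min
        and has_insulin
    )
    return ObservationWindow(
        patient_id=patient.patient_id,
        age_years=patient.age_years,
        ketone_time=int(ketone_time),
        ketone_value=ketone_value,
        label=int(ketone_value >= config.label_threshold_mmol_l),
        cgm12_times=c12_t,
        cgm12_values=c12_v,
        cgm6_times=c6_t,
        cgm6_values=c6_v,
        ins_recent=ins_recent,
        ins_early=ins_early,
        smbg_times=s_t,
        smbg_values=s_v,
        wear_fraction=wear_fraction,
        eligible=bool(eligible),
    )


def assemble_dataset(
    cohort: list[PatientRecord],
    config: WindowConfig | None = None,
) -> list[ObservationWindow]:
    """One window per ketone sample across the cohort.

    Ineligible windows are retained with ``eligible=False`` so callers can
    audit the filter; modeling stages use only the eligible subset.  With
    ``min_gap_h`` set, ketone checks closer than that to the previously kept
    check of the same patient are skipped (overlapping-window control).
    """
    if not cohort:
        raise ValueError("cohort is empty")
    config = config or WindowConfig()
    windows: list[ObservationWindow] = []
    for patient in cohort:
        last_kept = -np.inf
        for kt in patient.ketone_times:
            if (
                config.min_gap_h is not None
                and kt - last_kept < config.min_gap_h * 60.0
            ):
                continue
            windows.append(extract_window(patient, int(kt), config))
            last_kept = kt
    n_eligible = sum(w.eligible for w in windows)
    n_events = sum(w.label for w in windows if w.eligible)
    logger.info(
        "assembled %d windows (%d eligible, %d events)",
        len(windows), n_eligible, n_events,
    )
    return windows
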