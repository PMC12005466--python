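"""Flat-file layout for cohorts, windows and features.

A cohort directory holds `patients.csv` (patient_id, age_years) plus one
sub-directory per patient containing `cgm.csv` (timestamp_min,
glucose_mg_dl), `insulin.csv` (timestamp_min, amount_u, type), `smbg.csv`
(timestamp_min, glucose_mg_dl) and `ketones.csv` (timestamp_min,
ketone_mmol_l).  UTF-8, header rows, "." decimal separator throughout.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import PatientRecord
from .windowing import ObservationWindow

__all__ = ["write_cohort", "read_cohort", "windows_to_frame"]


def write_cohort(cohort: list[PatientRecord], out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"patient_id": [p.patient_id for p in cohort],
         "age_years": [p.age_years for p in cohort]}
    ).to_csv(out / "patients.csv", index=False)
    for p in cohort:
        d = out / p.patient_id
        d.mkdir(exist_ok=True)
        pd.DataFrame({"timestamp_min": p.cgm_times, "glucose_mg_dl": p.cgm_values}
                     ).to_csv(d / "cgm.csv", index=False)
        pd.DataFrame({"timestamp_min": p.insulin_times, "amount_u": p.insulin_amounts,
                      "type": p.insulin_types}).to_csv(d / "insulin.csv", index=False)
        pd.DataFrame({"timestamp_min": p.smbg_times, "glucose_mg_dl": p.smbg_values}
                     ).to_csv(d / "smbg.csv", index=False)
        pd.DataFrame({"timestamp_min": p.ketone_times, "ketone_mmol_l": p.ketone_values}
                     ).to_csv(d / "ketones.csv", index=False)
    return out


def read_cohort(cohort_dir: str | Path) -> list[PatientRecord]:
    root = Path(cohort_dir)
    patients = pd.read_csv(root / "patients.csv")
    cohort = []
    for _, row in patients.iterrows():
        d = root / str(row["patient_id"])
        cgm = pd.read_csv(d / "cgm.csv")
        ins = pd.read_csv(d / "insulin.csv")
        smbg = pd.read_csv(d / "smbg.csv")
        ket = pd.read_csv(d / "ketones.csv")
        rec = PatientRecord(
            patient_id=str(row["patient_id"]),
            age_years=float(row["age_years"]),
            cgm_times=cgm["timestamp_min"].to_numpy(),
            cgm_values=cgm["glucose_mg_dl"].to_numpy(dtype=float),
            insulin_times=ins["timestamp_min"].to_numpy(dtype=float),
            insulin_amounts=ins["amount_u"].to_numpy(dtype=float),
            insulin_types=ins["type"].to_numpy(dtype=object),
            smbg_times=smbg["timestamp_min"].to_numpy(),
            smbg_values=smbg["glucose_mg_dl"].to_numpy(dtype=float),
            ketone_times=ket["timestamp_min"].to_numpy(),
            ketone_values=ket["ketone_mmol_l"].to_numpy(dtype=float),
        )
        rec.validate()
        cohort.append(rec)
    return cohort


def windows_to_frame(windows: list[ObservationWindow]) -> pd.DataFrame:
    """One audit row per window (streams stay referenced by patient/time)."""
    return pd.DataFrame(
        [
            {
                "patient_id": w.patient_id,
                "ketone_time": w.ketone_time,
                "ketone_value": w.ketone_value,
                "label": w.label,
                "n_cgm_12h": len(w.cgm12_times),
                "n_cgm_6h": len(w.cgm6_times),
                "n_insulin": int(
                    sum(len(a) for a in w.ins_recent.values())
                    + sum(len(a) for a in w.ins_early.values())
                ),
                "n_smbg": len(w.smbg_times),
                "wear_fraction": w.wear_fraction,
                "eligible": w.eligible,
            }
            for w in windows
        ]
    )
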