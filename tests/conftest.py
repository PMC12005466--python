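import numpy as np
import pytest

from ketopred.synthetic import PatientRecord, SimConfig, generate_cohort
from ketopred.windowing import WindowConfig, extract_window


@pytest.fixture(scope="session")
def small_cohort():
    """20 patients x 30 days; enough ketone checks for windowing tests."""
    return generate_cohort(SimConfig(n_patients=20, days_per_patient=30, seed=7))


def make_patient(
    patient_id="T0",
    age_years=30.0,
    cgm=None,
    insulin=None,
    smbg=None,
    ketones=None,
):
    """Hand-built PatientRecord for boundary-condition tests.

    ``cgm``/``smbg`` are (times, values); ``insulin`` is (times, amounts,
    types); ``ketones`` is (times, values).
    """
    empty_i = np.array([], dtype=np.int64)
    empty_f = np.array([], dtype=float)
    cgm = cgm or (empty_i, empty_f)
    smbg = smbg or (empty_i, empty_f)
    ketones = ketones or (empty_i, empty_f)
    if insulin is None:
        insulin = (empty_f, empty_f, np.array([], dtype=object))
    return PatientRecord(
        patient_id=patient_id,
        age_years=age_years,
        cgm_times=np.asarray(cgm[0], dtype=np.int64),
        cgm_values=np.asarray(cgm[1], dtype=float),
        insulin_times=np.asarray(insulin[0], dtype=float),
        insulin_amounts=np.asarray(insulin[1], dtype=float),
        insulin_types=np.asarray(insulin[2], dtype=object),
        smbg_times=np.asarray(smbg[0], dtype=np.int64),
        smbg_values=np.asarray(smbg[1], dtype=float),
        ketone_times=np.asarray(ketones[0], dtype=np.int64),
        ketone_values=np.asarray(ketones[1], dtype=float),
    )


def full_grid_patient(ketone_time=1440, ketone_value=0.8, n_cgm_dropped=0,
                      with_insulin=True, with_smbg=True):
    """Patient with a complete 5-min CGM grid around one ketone check."""
    t0 = ketone_time - 720
    cgm_t = np.arange(t0 + 5, ketone_time + 1, 5)
    if n_cgm_dropped:
        cgm_t = cgm_t[n_cgm_dropped:]
    rng = np.random.default_rng(0)
    cgm_v = 180 + 40 * rng.standard_normal(len(cgm_t))
    cgm_v = np.clip(cgm_v, 40, 400)
    if with_insulin:
        ins_t = np.arange(t0 + 30, ketone_time + 1, 30, dtype=float)
        ins = (ins_t, np.full(len(ins_t), 0.4), np.array(["basal"] * len(ins_t), dtype=object))
    else:
        ins = None
    smbg = (np.array([ketone_time - 100]), np.array([210.0])) if with_smbg else None
    return make_patient(
        cgm=(cgm_t, cgm_v),
        insulin=ins,
        smbg=smbg,
        ketones=(np.array([ketone_time]), np.array([ketone_value])),
    )


@pytest.fixture
def eligible_window():
    return extract_window(full_grid_patient(), 1440, WindowConfig())
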