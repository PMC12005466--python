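"""Synthetic closed-loop T1D cohort generator.

Emulates the data streams of a closed-loop (automated insulin delivery)
trial: a CGM sampling interstitial glucose every 5 minutes with wear-time
gaps, pump-logged basal/bolus/meal insulin deliveries, sparse fingerstick
SMBG readings, and ketone-meter samples taken when glucose surpasses a
trigger threshold (300 mg/dL by default).

Elevated ketones arise mechanistically from two kinds of ketosis episode:
infusion failures, which suppress basal delivery while glucose drifts
upward, and illness ("sick-day") episodes, during which insulin delivery
continues as logged but relative insulin deficiency still drives glucose
and ketones up.  A latent ketone level rises for the duration of either
episode and decays afterwards.  A ketone check is prompted when CGM
surpasses the trigger threshold, and is performed after a short random
patient delay, so episode ramps keep pushing glucose past the threshold
while transient post-meal spikes fall back.  Checks fired during ordinary
post-meal hyperglycemia read normal ketones.  This gives the binary label
a learnable signal in the glucose and insulin histories — strongest in the
CGM stream, since only the infusion-failure subset of events leaves a
signature in the pump log — without any physiological ODE model.

Time is integer minutes since a cohort epoch (day 0, 00:00).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimConfig",
    "PatientRecord",
    "SimConfigError",
    "simulate_patient",
    "generate_cohort",
]

ELEVATED_KETONE_MMOL_L = 0.6

# Stand-in physiology constants (not estimates of any trial).
_BASELINE_MEAN = 150.0       # mg/dL, population mean of per-patient baseline
_BASELINE_SD = 18.0
_DIURNAL_AMP = 18.0          # mg/dL, sinusoidal day/night swing
_DIURNAL_PEAK_H = 16.0       # hour of day at which the sinusoid peaks
_CGM_NOISE_SD = 12.0         # mg/dL, iid sensor noise
_MEAL_RISE_MIN = 30.0        # minutes to excursion peak
_MEAL_DECAY_MIN = 100.0      # exponential decay constant after peak
_MEAL_AMP_MEDIAN = 65.0      # mg/dL, median meal excursion height
_MEAL_AMP_SIGMA = 0.33       # lognormal sigma of excursion height
_FAILURE_DECAY_MIN = 70.0    # glucose relaxation after an episode ends
_KETONE_BASE_MEAN = 0.12     # mmol/L resting ketone level
_KETONE_BASE_SD = 0.03
_KETONE_DECAY_MIN = 180.0    # ketone clearance constant after an episode
_KETONE_NOISE_SD = 0.05      # meter noise, floored at 0
_KETONE_RATE_SIGMA = 0.30    # per-episode lognormal spread of the rise rate
_ILLNESS_RATE_PER_DAY = 0.05  # sick-day ketosis episodes (insulin logged as usual)
_ILLNESS_DURATION_FACTOR = (1.0, 1.8)  # sick days last longer than pump failures
_CHECK_DELAY_MIN = (10.0, 70.0)  # patient delay from glucose alert to meter use
_SMBG_PER_DAY = 1.5          # Poisson rate of fingerstick checks
_SMBG_NOISE_SD = 10.0
_CORRECTION_BOLUS_U = 1.5    # closed-loop correction dose
_CORRECTION_THRESHOLD = 260.0
_CORRECTION_REFRACTORY_MIN = 180
_BASAL_RECORD_MIN = 30       # pump logs basal in 30-min aliquots
_TRIGGER_REFRACTORY_MIN = 240  # one ketone check per 4-h hyperglycemic span
_GLUCOSE_LO, _GLUCOSE_HI = 40.0, 400.0  # sensor reporting range


class SimConfigError(ValueError):
    """Raised when a SimConfig field is out of its admissible range."""


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation settings.

    The defaults define the package's reference study conditions: a cohort
    of 200 patients monitored for 90 days with 5-minute CGM sampling,
    infusion failures arriving at ~0.15/day, and a class balance of roughly
    one elevated-ketone sample per four ketone checks.
    """

    n_patients: int = 200
    days_per_patient: int = 90
    cgm_interval_min: int = 5
    basal_rate_u_per_h: float = 0.8
    meal_times_h: tuple[float, ...] = (7.5, 12.5, 18.5)
    meal_bolus_u: float = 5.0
    failure_rate_per_day: float = 0.15
    failure_duration_h: float = 4.0
    glucose_drift_mg_dl_per_h: float = 20.0
    ketone_rise_mmol_l_per_h: float = 0.11
    dropout_prob: float = 0.08
    trigger_threshold_mg_dl: float = 300.0
    age_range_years: tuple[float, float] = (6.0, 79.0)
    pediatric_fraction: float = 0.36
    seed: int = 2024

    def validate(self) -> None:
        if self.n_patients < 1:
            raise SimConfigError("n_patients must be >= 1")
        if self.days_per_patient < 1:
            raise SimConfigError("days_per_patient must be >= 1")
        if self.cgm_interval_min < 1 or 60 % self.cgm_interval_min != 0:
            raise SimConfigError("cgm_interval_min must divide 60")
        for name in ("dropout_prob", "failure_rate_per_day", "pediatric_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must lie in [0, 1]")
        for name in (
            "basal_rate_u_per_h",
            "meal_bolus_u",
            "failure_duration_h",
            "glucose_drift_mg_dl_per_h",
            "ketone_rise_mmol_l_per_h",
        ):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        if self.trigger_threshold_mg_dl <= 0:
            raise SimConfigError("trigger_threshold_mg_dl must be positive")
        if not all(0 <= t < 24 for t in self.meal_times_h):
            raise SimConfigError("meal_times_h entries must lie in [0, 24)")
        lo, hi = self.age_range_years
        if not (0 < lo < hi):
            raise SimConfigError("age_range_years must be an increasing positive pair")


@dataclass
class PatientRecord:
    """One patient's four device streams plus age.

    All timestamps are integer minutes since the cohort epoch and strictly
    increasing within each stream.  ``failure_episodes`` is simulation
    ground truth (start, end) pairs kept for mechanism diagnostics; real
    ingested data would leave it empty.
    """

    patient_id: str
    age_years: float
    cgm_times: np.ndarray        # int64 minutes
    cgm_values: np.ndarray       # float mg/dL
    insulin_times: np.ndarray    # int64 minutes
    insulin_amounts: np.ndarray  # float U
    insulin_types: np.ndarray    # str in {basal, bolus, meal}
    smbg_times: np.ndarray
    smbg_values: np.ndarray
    ketone_times: np.ndarray
    ketone_values: np.ndarray    # float mmol/L
    failure_episodes: list[tuple[float, float]] = field(default_factory=list)
    illness_episodes: list[tuple[float, float]] = field(default_factory=list)

    @property
    def ketosis_episodes(self) -> list[tuple[float, float]]:
        """All episodes that drive the latent ketone level upward."""
        return sorted(self.failure_episodes + self.illness_episodes)

    def validate(self) -> None:
        for times in (self.cgm_times, self.insulin_times, self.smbg_times, self.ketone_times):
            if len(times) > 1 and not np.all(np.diff(times) > 0):
                raise ValueError(f"{self.patient_id}: timestamps not strictly increasing")
        for vals in (self.cgm_values, self.smbg_values):
            if len(vals) and not ((vals > 20) & (vals < 600)).all():
                raise ValueError(f"{self.patient_id}: glucose outside (20, 600) mg/dL")
        if len(self.ketone_values) and (self.ketone_values < 0).any():
            raise ValueError(f"{self.patient_id}: negative ketone value")
        if len(self.insulin_amounts) and (self.insulin_amounts < 0).any():
            raise ValueError(f"{self.patient_id}: negative insulin amount")


def _meal_kernel(offsets_min: np.ndarray) -> np.ndarray:
    """Unit-height post-meal excursion: linear rise, exponential decay."""
    k = np.zeros_like(offsets_min, dtype=float)
    rising = (offsets_min >= 0) & (offsets_min < _MEAL_RISE_MIN)
    k[rising] = offsets_min[rising] / _MEAL_RISE_MIN
    decaying = offsets_min >= _MEAL_RISE_MIN
    k[decaying] = np.exp(-(offsets_min[decaying] - _MEAL_RISE_MIN) / _MEAL_DECAY_MIN)
    return k


def _draw_episodes(rng: np.random.Generator, total_min: float, rate_per_day: float,
                   duration_min: float) -> list[tuple[float, float]]:
    """Non-overlapping Poisson-arriving failure episodes within [0, total_min)."""
    episodes: list[tuple[float, float]] = []
    if rate_per_day <= 0 or duration_min <= 0:
        return episodes
    rate_per_min = rate_per_day / 1440.0
    t = rng.exponential(1.0 / rate_per_min)
    while t < total_min:
        dur = duration_min * rng.uniform(0.7, 1.3)
        end = min(t + dur, total_min)
        episodes.append((t, end))
        t = end + rng.exponential(1.0 / rate_per_min)
    return episodes


def simulate_patient(
    config: SimConfig,
    patient_id: str,
    age_years: float,
    rng: np.random.Generator,
) -> PatientRecord:
    """Simulate one patient's CGM, insulin, SMBG and ketone streams.

    Glucose is a diurnal sinusoid plus meal excursions plus sensor noise;
    during each infusion-failure episode basal deliveries are zeroed and
    glucose ramps upward at ``glucose_drift_mg_dl_per_h`` while a latent
    ketone level rises at a (per-episode jittered) ``ketone_rise_mmol_l_per_h``
    and decays after the episode ends.  A ketone measurement is emitted at
    the first CGM reading above ``trigger_threshold_mg_dl`` in any 4-hour
    span, recording the latent ketone value plus meter noise.
    """
    config.validate()
    total_min = config.days_per_patient * 1440
    grid = np.arange(0, total_min, config.cgm_interval_min, dtype=np.int64)
    hours = (grid / 60.0) % 24.0

    baseline_mean = float(np.clip(rng.normal(_BASELINE_MEAN, _BASELINE_SD), 110.0, 210.0))
    basal_rate = max(0.0, rng.normal(config.basal_rate_u_per_h, 0.25 * config.basal_rate_u_per_h))
    glucose = baseline_mean + _DIURNAL_AMP * np.sin(
        2 * np.pi * (hours - _DIURNAL_PEAK_H + 6.0) / 24.0
    )

    # Meal excursions (one per configured meal time per day, jittered ±20 min).
    meal_events: list[tuple[float, float]] = []  # (time_min, amplitude)
    for day in range(config.days_per_patient):
        for mt in config.meal_times_h:
            t_meal = day * 1440 + mt * 60 + rng.uniform(-20, 20)
            amp = _MEAL_AMP_MEDIAN * rng.lognormal(0.0, _MEAL_AMP_SIGMA)
            meal_events.append((t_meal, amp))
    for t_meal, amp in meal_events:
        lo = np.searchsorted(grid, t_meal)
        hi = np.searchsorted(grid, t_meal + 6 * 60)
        if lo < hi:
            glucose[lo:hi] += amp * _meal_kernel(grid[lo:hi] - t_meal)

    # Ketosis episodes: infusion failures (basal suppressed) plus sick-day
    # illness (insulin logged as usual); both ramp glucose during the
    # episode with exponential relaxation after, and both raise ketones.
    episodes = _draw_episodes(
        rng, total_min, config.failure_rate_per_day, config.failure_duration_h * 60.0
    )
    illness = _draw_episodes(
        rng, total_min, _ILLNESS_RATE_PER_DAY,
        config.failure_duration_h * 60.0 * rng.uniform(*_ILLNESS_DURATION_FACTOR),
    )
    ketone_base = float(max(0.02, rng.normal(_KETONE_BASE_MEAN, _KETONE_BASE_SD)))
    latent_ketone = np.full(grid.shape, ketone_base)
    for start, end in episodes + illness:
        k_rate = config.ketone_rise_mmol_l_per_h * rng.lognormal(0.0, _KETONE_RATE_SIGMA)
        in_ep = (grid >= start) & (grid < end)
        elapsed_h = (grid[in_ep] - start) / 60.0
        glucose[in_ep] += config.glucose_drift_mg_dl_per_h * elapsed_h
        latent_ketone[in_ep] += k_rate * elapsed_h
        after = grid >= end
        peak_g = config.glucose_drift_mg_dl_per_h * (end - start) / 60.0
        peak_k = k_rate * (end - start) / 60.0
        tail = (grid[after] - end).astype(float)
        glucose[after] += peak_g * np.exp(-tail / _FAILURE_DECAY_MIN)
        latent_ketone[after] += peak_k * np.exp(-tail / _KETONE_DECAY_MIN)

    glucose_clean = glucose.copy()
    glucose = np.clip(glucose + rng.normal(0.0, _CGM_NOISE_SD, grid.shape),
                      _GLUCOSE_LO, _GLUCOSE_HI)

    # Wear-time gaps: each scheduled sample independently missing.
    kept = rng.random(grid.shape) >= config.dropout_prob
    cgm_times = grid[kept]
    cgm_values = glucose[kept]

    # Insulin log: basal aliquots (suppressed inside infusion-failure
    # episodes, logged as usual through illness), meal boluses, and
    # closed-loop correction boluses.  Correction doses are commanded from
    # CGM feedback and are logged even during an episode.
    ins: list[tuple[float, float, str]] = []
    basal_grid = np.arange(0, total_min, _BASAL_RECORD_MIN, dtype=np.int64)
    in_failure = np.zeros(basal_grid.shape, dtype=bool)
    for start, end in episodes:
        in_failure |= (basal_grid >= start) & (basal_grid < end)
    basal_amt = basal_rate * _BASAL_RECORD_MIN / 60.0
    for t in basal_grid[~in_failure]:
        ins.append((float(t), basal_amt, "basal"))
    for t_meal, _amp in meal_events:
        if 0 <= t_meal < total_min:
            amt = config.meal_bolus_u * rng.lognormal(0.0, 0.2)
            ins.append((float(int(t_meal)), amt, "meal"))
    last_corr = -np.inf
    for t, g in zip(cgm_times, cgm_values):
        if g > _CORRECTION_THRESHOLD and t - last_corr >= _CORRECTION_REFRACTORY_MIN:
            ins.append((float(t) + 1.0, _CORRECTION_BOLUS_U, "bolus"))
            last_corr = t
    ins.sort(key=lambda r: r[0])
    # nudge colliding timestamps so streams stay strictly increasing
    cleaned: list[tuple[float, float, str]] = []
    prev_t = -1.0
    for t, a, typ in ins:
        if t <= prev_t:
            t = prev_t + 0.5
        cleaned.append((t, a, typ))
        prev_t = t
    ins = cleaned

    # SMBG fingersticks at Poisson-random times, read from the clean signal.
    n_smbg = rng.poisson(_SMBG_PER_DAY * config.days_per_patient)
    smbg_t = np.sort(rng.uniform(0, total_min, n_smbg))
    smbg_t = np.unique(np.floor(smbg_t).astype(np.int64))
    idx = np.clip(np.searchsorted(grid, smbg_t), 0, len(grid) - 1)
    smbg_v = np.clip(glucose_clean[idx] + rng.normal(0.0, _SMBG_NOISE_SD, smbg_t.shape),
                     _GLUCOSE_LO, _GLUCOSE_HI)

    # Ketone checks: the first recorded CGM reading above the trigger
    # threshold in any 4-h span prompts a meter measurement, performed
    # after a random patient delay and reading the latent level then.
    ket_t: list[int] = []
    ket_v: list[float] = []
    last_trig = -np.inf
    for t, g in zip(cgm_times, cgm_values):
        if g > config.trigger_threshold_mg_dl and t - last_trig >= _TRIGGER_REFRACTORY_MIN:
            last_trig = t
            tm = int(t + rng.uniform(*_CHECK_DELAY_MIN))
            if tm >= total_min:
                continue
            k = latent_ketone[np.searchsorted(grid, tm, side="right") - 1]
            ket_t.append(tm)
            ket_v.append(max(0.0, k + rng.normal(0.0, _KETONE_NOISE_SD)))

    record = PatientRecord(
        patient_id=patient_id,
        age_years=float(age_years),
        cgm_times=cgm_times,
        cgm_values=cgm_values,
        insulin_times=np.array([r[0] for r in ins]),
        insulin_amounts=np.array([r[1] for r in ins]),
        insulin_types=np.array([r[2] for r in ins], dtype=object),
        smbg_times=smbg_t,
        smbg_values=smbg_v,
        ketone_times=np.array(ket_t, dtype=np.int64),
        ketone_values=np.array(ket_v),
        failure_episodes=episodes,
        illness_episodes=illness,
    )
    record.validate()
    return record


def generate_cohort(config: SimConfig) -> list[PatientRecord]:
    """Simulate ``config.n_patients`` patients deterministically.

    Each patient draws from an independent child stream of the master seed,
    so the cohort is reproducible and individual patients do not depend on
    generation order.  Ages mix a pediatric block (6-17 years, drawn with
    probability ``pediatric_fraction``) with adults up to the configured
    maximum, mirroring a mixed pediatric/adult trial cohort.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_patients + 1)
    age_rng = np.random.default_rng(children[0])
    lo, hi = config.age_range_years
    ped_hi = min(hi, 18.0)
    ages = np.where(
        (age_rng.random(config.n_patients) < config.pediatric_fraction) & (lo < ped_hi),
        age_rng.uniform(lo, ped_hi, config.n_patients),
        age_rng.uniform(min(ped_hi, hi), hi, config.n_patients),
    )
    cohort = []
    for i in range(config.n_patients):
        rng = np.random.default_rng(children[i + 1])
        pid = f"P{i:04d}"
        cohort.append(simulate_patient(config, pid, float(ages[i]), rng))
    return cohort
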