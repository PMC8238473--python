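"""Seeded synthetic data: training cohort and operational sources.

The cohort generator draws each numeric risk attribute from a truncated
normal whose location is solved numerically so that the *truncated*
distribution's mean matches the calibrated target mean. A configurable
contamination fraction then overwrites values of selected attributes with
gross out-of-range extremes (e.g. negative blood pressures), emulating the
dirty upstream feed that the cleansing stage must catch. Class labels come
from a logit-linear latent model in the standardized risk attributes, so
downstream classifiers have real signal to learn.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

__all__ = [
    "NumericSpec",
    "CohortCalibration",
    "generate_cohort",
    "generate_user_sources",
    "district_fixture",
    "read_table_csv",
    "write_table_csv",
    "COHORT_NUMERIC",
    "COHORT_NOMINAL",
    "COHORT_COLUMNS",
    "DISEASE",
    "NO_DISEASE",
]

DISEASE = "Disease"
NO_DISEASE = "No disease"

COHORT_NUMERIC = [
    "age",
    "systolic_bp",
    "diastolic_bp",
    "cholesterol",
    "fast_glucose",
    "smoke_years",
    "cigarettes_per_day",
    "bmi",
]
COHORT_NOMINAL = [
    "family_history",
    "pain_after_effort",
    "physical_exercise",
    "smoking",
    "hypertension",
    "hypothyroid",
    "gender",
]
# 8 numeric + 7 nominal + record date + (always-missing) diabetes = 17 risk
# attributes; `class` is the label.
COHORT_COLUMNS = COHORT_NUMERIC + COHORT_NOMINAL + ["record_date", "diabetes", "class"]

EXERCISE_LEVELS = ["None", "Low", "Moderate", "High"]


@dataclass(frozen=True)
class NumericSpec:
    """Marginal calibration of one numeric attribute.

    ``mean``/``sd``/``min``/``max`` are the raw-feed statistics (outliers
    included); ``clean_lo``/``clean_hi`` bound the truncated normal used for
    uncontaminated draws. When ``contaminate`` is set, a contamination draw
    replaces the value with a uniform extreme between the raw min/max and
    the clean bound on the corresponding side.
    """

    mean: float
    sd: float
    min: float
    max: float
    clean_lo: float
    clean_hi: float
    contaminate: bool = False
    clean_sd: float | None = None

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if not (self.min <= self.mean <= self.max):
            raise ValueError("need min <= mean <= max")
        if self.clean_lo >= self.clean_hi:
            raise ValueError("clean range is empty")

    @property
    def draw_sd(self) -> float:
        return self.clean_sd if self.clean_sd is not None else self.sd


def _default_numeric() -> dict[str, NumericSpec]:
    # Raw-feed stats; blood pressures and BMI carry gross outliers, so their
    # clean draws use a plausible physiological spread instead of the
    # outlier-inflated raw sd.
    return {
        "age": NumericSpec(52.8, 6.8, 29, 64, 29, 64),
        "systolic_bp": NumericSpec(128.9, 159.6, -150, 16020, 60, 250,
                                   contaminate=True, clean_sd=15.0),
        "diastolic_bp": NumericSpec(96.9, 188.1, -70, 11000, 30, 150,
                                    contaminate=True, clean_sd=12.0),
        "cholesterol": NumericSpec(170.1, 52.5, 100, 320, 100, 320),
        "fast_glucose": NumericSpec(119.6, 56.4, 80, 400, 80, 400),
        "smoke_years": NumericSpec(5.4, 12.0, 0, 50, 0, 50),
        "cigarettes_per_day": NumericSpec(7.1, 14.6, 0, 50, 0, 50),
        "bmi": NumericSpec(27.6, 6.1, 3.5, 298.7, 10, 70,
                           contaminate=True, clean_sd=5.0),
    }


def _default_nominal() -> dict[str, dict[str, int]]:
    return {
        "family_history": {"Yes": 8_459, "No": 56_541},
        "pain_after_effort": {"Yes": 8_620, "No": 56_380},
        "physical_exercise": {"None": 6_352, "Low": 6_413,
                              "Moderate": 26_054, "High": 26_181},
        "smoking": {"Yes": 6_651, "No": 23_393},
        "hypertension": {"Yes": 25_225, "No": 39_775},
        "hypothyroid": {"Yes": 13_501, "No": 51_499},
        "gender": {"Male": 28_326, "Female": 36_674},
    }


def _default_beta() -> dict[str, float]:
    # Signs follow established CVD risk directions: exercise is protective,
    # everything else raises risk (hypothyroid only weakly).
    return {
        "age": 0.6,
        "systolic_bp": 0.8,
        "diastolic_bp": 0.3,
        "cholesterol": 0.6,
        "fast_glucose": 0.5,
        # smoking status is ~54% masked downstream, so most of the smoking
        # signal rides on the always-observed years/cigarettes counts
        "smoke_years": 0.5,
        "cigarettes_per_day": 0.5,
        "bmi": 0.5,
        "family_history": 0.8,
        "pain_after_effort": 0.5,
        "physical_exercise": -0.6,
        "smoking": 0.1,
        "hypertension": 0.9,
        "hypothyroid": 0.15,
        "gender": 0.25,
    }


@dataclass(frozen=True)
class CohortCalibration:
    """Calibration targets for :func:`generate_cohort`."""

    numeric: Mapping[str, NumericSpec] = field(default_factory=_default_numeric)
    nominal: Mapping[str, Mapping[str, int]] = field(default_factory=_default_nominal)
    cohort_size: int = 65_000
    disease_count: int = 32_509
    smoking_missing: int = 34_956
    diabetes_missing: int = 65_000
    contamination_rate: float = 0.005
    beta: Mapping[str, float] = field(default_factory=_default_beta)
    record_year: int = 2019

    def __post_init__(self) -> None:
        if not 0.0 <= self.contamination_rate <= 1.0:
            raise ValueError("contamination_rate must be in [0, 1]")
        if not 0 <= self.disease_count <= self.cohort_size:
            raise ValueError("class counts inconsistent with cohort size")
        for attr, freqs in self.nominal.items():
            total = sum(freqs.values())
            missing = self.smoking_missing if attr == "smoking" else 0
            if total + missing != self.cohort_size:
                raise ValueError(
                    f"{attr}: frequencies + missing ({total + missing}) "
                    f"do not sum to cohort size ({self.cohort_size})"
                )

    @property
    def prevalence(self) -> float:
        return self.disease_count / self.cohort_size

    @property
    def smoking_missing_rate(self) -> float:
        return self.smoking_missing / self.cohort_size

    def with_strong_effects(self, factor: float = 4.0) -> "CohortCalibration":
        """Calibration with effect sizes scaled up: a highly separable cohort."""
        return replace(self, beta={k: v * factor for k, v in self.beta.items()})


def _solve_trunc_loc(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Location of a truncated normal on [lo, hi] whose mean hits ``target_mean``."""

    def gap(mu: float) -> float:
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return truncnorm.mean(a, b, loc=mu, scale=sd) - target_mean

    return brentq(gap, lo - 8.0 * sd, hi, xtol=1e-10)


def _draw_truncnorm(rng: np.random.Generator, n: int, loc: float, sd: float,
                    lo: float, hi: float) -> np.ndarray:
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return truncnorm.rvs(a, b, loc=loc, scale=sd, size=n, random_state=rng)


def _nominal_probs(freqs: Mapping[str, int]) -> tuple[list[str], np.ndarray]:
    values = list(freqs)
    counts = np.array([freqs[v] for v in values], dtype=float)
    return values, counts / counts.sum()


def _standardize_nominal(values: np.ndarray, freqs: Mapping[str, int]) -> np.ndarray:
    """Encode a nominal column as a standardized numeric score for the latent model."""
    names, probs = _nominal_probs(freqs)
    if set(names) <= {"Yes", "No"}:
        p = probs[names.index("Yes")]
        x = (values == "Yes").astype(float)
        return (x - p) / np.sqrt(p * (1 - p))
    if set(names) <= {"Male", "Female"}:
        p = probs[names.index("Male")]
        x = (values == "Male").astype(float)
        return (x - p) / np.sqrt(p * (1 - p))
    # ordered exercise levels
    level = {name: EXERCISE_LEVELS.index(name) for name in names}
    codes = np.array([level[v] for v in values], dtype=float)
    mean = float(np.dot(probs, [level[n] for n in names]))
    var = float(np.dot(probs, [(level[n] - mean) ** 2 for n in names]))
    return (codes - mean) / np.sqrt(var) if var > 0 else codes - mean


def _latent_probabilities(numeric: dict[str, np.ndarray],
                          nominal: dict[str, np.ndarray],
                          cal: CohortCalibration) -> np.ndarray:
    eta = np.zeros(len(next(iter(numeric.values()))))
    for attr, values in numeric.items():
        spec = cal.numeric[attr]
        eta += cal.beta.get(attr, 0.0) * (values - spec.mean) / max(spec.draw_sd, 1e-12)
    for attr, values in nominal.items():
        eta += cal.beta.get(attr, 0.0) * _standardize_nominal(values, cal.nominal[attr])

    target = cal.prevalence

    def gap(b0: float) -> float:
        return float(np.mean(expit(b0 + eta))) - target

    beta0 = brentq(gap, -30.0, 30.0, xtol=1e-10)
    return expit(beta0 + eta)


def generate_cohort(n: int, seed: int,
                    calibration: CohortCalibration | None = None,
                    exact_balance: bool = False) -> pd.DataFrame:
    """Generate ``n`` classified risk-factor records.

    Deterministic given ``seed``. In ``exact_balance`` mode the number of
    ``Disease`` rows equals ``round(n * disease_count / cohort_size)``
    exactly: rows are ranked by latent disease probability and the label cut
    is placed at that count (ties broken by record index). Otherwise labels
    are Bernoulli draws from the latent probability.
    """
    if n < 1:
        raise ValueError("n must be a positive integer")
    cal = calibration if calibration is not None else CohortCalibration()
    rng = np.random.default_rng(seed)

    numeric: dict[str, np.ndarray] = {}
    for attr in COHORT_NUMERIC:
        spec = cal.numeric[attr]
        if attr == "diastolic_bp":
            continue  # drawn jointly with systolic below
        loc = _solve_trunc_loc(spec.mean, spec.draw_sd, spec.clean_lo, spec.clean_hi)
        numeric[attr] = _draw_truncnorm(rng, n, loc, spec.draw_sd,
                                        spec.clean_lo, spec.clean_hi)

    # Diastolic = systolic - positive gap, truncated per-record so that the
    # result stays inside the diastolic clean range and below systolic.
    sbp = numeric["systolic_bp"]
    dspec = cal.numeric["diastolic_bp"]
    gap_mean = cal.numeric["systolic_bp"].mean - dspec.mean
    gap_sd = dspec.draw_sd
    gap_lo = np.maximum(5.0, sbp - dspec.clean_hi)
    gap_hi = np.maximum(sbp - dspec.clean_lo, gap_lo + 1e-6)
    a = (gap_lo - gap_mean) / gap_sd
    b = (gap_hi - gap_mean) / gap_sd
    u = rng.random(n)
    gaps = truncnorm.ppf(u, a, b, loc=gap_mean, scale=gap_sd)
    numeric["diastolic_bp"] = sbp - gaps

    nominal: dict[str, np.ndarray] = {}
    for attr in COHORT_NOMINAL:
        values, probs = _nominal_probs(cal.nominal[attr])
        nominal[attr] = rng.choice(values, p=probs, size=n)

    p = _latent_probabilities(numeric, nominal, cal)
    if exact_balance:
        k = int(round(n * cal.prevalence))
        order = np.argsort(-p, kind="stable")
        labels = np.full(n, NO_DISEASE, dtype=object)
        labels[order[:k]] = DISEASE
    else:
        labels = np.where(rng.random(n) < p, DISEASE, NO_DISEASE)

    # Contamination is applied after labelling so the latent model sees only
    # physiological values.
    if cal.contamination_rate > 0:
        for attr in COHORT_NUMERIC:
            spec = cal.numeric[attr]
            if not spec.contaminate:
                continue
            hit = rng.random(n) < cal.contamination_rate
            side_high = rng.random(n) < 0.5
            low = rng.uniform(spec.min, spec.clean_lo, size=n)
            high = rng.uniform(spec.clean_hi, spec.max, size=n)
            numeric[attr] = np.where(hit, np.where(side_high, high, low),
                                     numeric[attr])

    start = date(cal.record_year, 1, 1)
    offsets = rng.integers(0, 365, size=n)
    record_dates = [(start + timedelta(days=int(d))).isoformat() for d in offsets]

    smoking = nominal["smoking"].astype(object)
    smoking[rng.random(n) < cal.smoking_missing_rate] = np.nan

    frame = pd.DataFrame({attr: numeric[attr] for attr in COHORT_NUMERIC})
    for attr in COHORT_NOMINAL:
        frame[attr] = smoking if attr == "smoking" else nominal[attr]
    frame["record_date"] = record_dates
    frame["diabetes"] = np.nan  # emulates the fully missing source column
    frame["class"] = labels
    return frame[COHORT_COLUMNS]


# ---------------------------------------------------------------------------
# Operational sources

EDUCATION_LEVELS = ["Basic", "Secondary", "Bachelor", "Master", "Doctorate"]

USER_COLUMNS = [
    "id_user", "district", "education_level", "salary", "gender",
    "weight", "height", "family_history", "diabetes", "hypertension",
    "pain_after_effort", "hypothyroidism", "total_cholesterol",
    "fast_glucose", "clinical_analysis_date", "date_of_birth",
    "cigarettes_per_day", "smoke_years",
]
MEASUREMENT_COLUMNS = ["id_user", "index_date", "calories",
                       "systolic_bp", "diastolic_bp"]


def generate_user_sources(n_users: int, n_days: int, seed: int,
                          change_rate: float = 0.0,
                          start: date = date(2019, 1, 1),
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthesize the slowly-varying user source and the daily measurements.

    Every user gets one snapshot dated ``start``; a ``change_rate`` fraction
    additionally gets a later snapshot with a modified district, education
    level and/or salary (to exercise dimension-history tracking). Daily
    measurements cover ``n_days`` consecutive days per user.
    """
    if n_users < 1 or n_days < 1:
        raise ValueError("n_users and n_days must be positive")
    if not 0.0 <= change_rate <= 1.0:
        raise ValueError("change_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    codes = district_fixture()["code"].tolist()

    rows = []
    for uid in range(1, n_users + 1):
        smoker = rng.random() < 0.25
        birth = date(1950, 1, 1) + timedelta(days=int(rng.integers(0, 365 * 41)))
        rows.append({
            "id_user": uid,
            "district": str(rng.choice(codes)),
            "education_level": str(rng.choice(EDUCATION_LEVELS)),
            "salary": int(rng.integers(600, 6001)),
            "gender": "Male" if rng.random() < 0.44 else "Female",
            "weight": int(rng.integers(48, 115)),
            "height": int(rng.integers(150, 196)),
            "family_history": "Yes" if rng.random() < 0.13 else "No",
            "diabetes": "Yes" if rng.random() < 0.08 else "No",
            "hypertension": "Yes" if rng.random() < 0.39 else "No",
            "pain_after_effort": "Yes" if rng.random() < 0.13 else "No",
            "hypothyroidism": "Yes" if rng.random() < 0.21 else "No",
            "total_cholesterol": int(rng.integers(110, 300)),
            "fast_glucose": int(rng.integers(80, 300)),
            "clinical_analysis_date": start.isoformat(),
            "date_of_birth": birth.isoformat(),
            "cigarettes_per_day": int(rng.integers(1, 40)) if smoker else 0,
            "smoke_years": int(rng.integers(1, 40)) if smoker else 0,
        })

    changed = rng.random(n_users) < change_rate
    horizon = max(n_days, 30)
    for uid in np.flatnonzero(changed) + 1:
        base = dict(rows[uid - 1])
        change_day = int(rng.integers(1, horizon + 1))
        base["clinical_analysis_date"] = (start + timedelta(days=change_day)).isoformat()
        other = [c for c in codes if c != base["district"]]
        which = rng.random(3) < 0.7
        if not which.any():
            which[0] = True
        if which[0]:
            base["district"] = str(rng.choice(other))
        if which[1]:
            base["education_level"] = str(
                rng.choice([e for e in EDUCATION_LEVELS if e != base["education_level"]]))
        if which[2]:
            base["salary"] = int(base["salary"] + rng.integers(500, 3000))
        rows.append(base)

    users = pd.DataFrame(rows, columns=USER_COLUMNS)

    uid_col, date_col, cal_col, sbp_col, dbp_col = [], [], [], [], []
    for uid in range(1, n_users + 1):
        cal_base = float(rng.normal(2200, 500))
        sbp_base = float(rng.normal(129, 14))
        walk = np.cumsum(rng.normal(0, 2.0, size=n_days))
        for day in range(n_days):
            uid_col.append(uid)
            date_col.append((start + timedelta(days=day)).isoformat())
            cal_col.append(int(np.clip(cal_base + rng.normal(0, 300), 20, 6000)))
            sbp = float(np.clip(sbp_base + walk[day] + rng.normal(0, 4), 80, 220))
            sbp_col.append(int(round(sbp)))
            dbp_col.append(int(round(np.clip(sbp - abs(rng.normal(32, 8)), 40, 140))))
    measurements = pd.DataFrame({
        "id_user": uid_col, "index_date": date_col, "calories": cal_col,
        "systolic_bp": sbp_col, "diastolic_bp": dbp_col,
    }, columns=MEASUREMENT_COLUMNS)
    return users, measurements


_DISTRICTS: Sequence[tuple[str, str, str, str, str]] = [
    ("AVR", "Aveiro", "Beira Litoral", "Centro", "Yes"),
    ("BJA", "Beja", "Baixo Alentejo", "Alentejo", "Yes"),
    ("BRG", "Braga", "Minho", "Norte", "Yes"),
    ("BGC", "Bragança", "Trás-os-Montes", "Norte", "No"),
    ("CTB", "Castelo Branco", "Beira Baixa", "Centro", "No"),
    ("CBR", "Coimbra", "Beira Litoral", "Centro", "Yes"),
    ("EVR", "Évora", "Alto Alentejo", "Alentejo", "No"),
    ("FAR", "Faro", "Algarve", "Algarve", "Yes"),
    ("GRD", "Guarda", "Beira Alta", "Centro", "No"),
    ("LRA", "Leiria", "Beira Litoral", "Centro", "Yes"),
    ("LSB", "Lisboa", "Estremadura", "Lisboa", "Yes"),
    ("PTG", "Portalegre", "Alto Alentejo", "Alentejo", "No"),
    ("PRT", "Porto", "Douro Litoral", "Norte", "Yes"),
    ("STR", "Santarém", "Ribatejo", "Centro", "No"),
    ("STB", "Setúbal", "Estremadura", "Lisboa", "Yes"),
    ("VCT", "Viana do Castelo", "Minho", "Norte", "Yes"),
    ("VRL", "Vila Real", "Trás-os-Montes", "Norte", "No"),
    ("VIS", "Viseu", "Beira Alta", "Centro", "No"),
]


def district_fixture() -> pd.DataFrame:
    """The packaged 18-district Portugal lookup (codes LSB, VCT, ...)."""
    return pd.DataFrame(_DISTRICTS,
                        columns=["code", "name", "province", "region", "coastal"])


# ---------------------------------------------------------------------------
# CSV round-trip helpers (empty string encodes missing; "None" is a real
# exercise category, so pandas' default NA tokens must not apply)

def write_table_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_table_csv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False, na_values=[""], **kwargs)
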