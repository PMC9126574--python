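"""Synthetic autopsy-cohort generator and cohort CSV I/O.

The generator emulates a community-based adult autopsy series (deceased
subjects aged 50+) with the joint structure the downstream analysis
relies on:

* demographics — sex, truncated-normal age, three-level education;
* anthropometry — height by sex, head circumference (HC) linear in
  height with a sex offset, brain volume linear in HC;
* a small "low-tail" mixture component shifted down in HC, so that the
  fraction of subjects below stratified mean − 2SD cutoffs can exceed
  the ≈ 2.3% a pure Gaussian implies;
* nine independent Bernoulli comorbidity flags;
* a latent cognitive-impairment state whose probability rises with age
  ≥ 70 and with membership in the low-HC component, expressed through a
  CDR value (> 0.5 when impaired) and an IQCODE score (≥ 3.4 with a
  configurable agreement probability given impairment).

All randomness flows from one :class:`numpy.random.Generator` seeded in
the config; repeated calls with the same config are bitwise identical.
Records are carried as a :class:`pandas.DataFrame` with one row per
subject (see :data:`COHORT_COLUMNS`); :class:`SubjectRecord` offers a
typed row view for callers that prefer objects.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, ParseError, SchemaError

__all__ = [
    "COHORT_COLUMNS",
    "CLINICAL_FLAGS",
    "GeneratorConfig",
    "SubjectRecord",
    "generate_cohort",
    "read_cohort",
    "write_cohort",
    "frame_to_records",
    "records_to_frame",
]

#: Binary clinical-history flags, in schema order.
CLINICAL_FLAGS: tuple[str, ...] = (
    "hypertension",
    "diabetes",
    "coronary_artery_disease",
    "congestive_heart_failure",
    "dyslipidemia",
    "cardiac_arrhythmia",
    "stroke",
    "alcohol_abuse",
    "tobacco_use",
)

#: Exact column set (and order) of a cohort CSV.
COHORT_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "age",
    "sex",
    "education_years",
    "height_m",
    "hc_cm",
    "brain_volume_ml",
    *CLINICAL_FLAGS,
    "cdr",
    "iqcode",
)

_SEXES = ("male", "female")

_NUMERIC_COLUMNS = tuple(c for c in COHORT_COLUMNS if c not in ("subject_id", "sex"))


def _default_prevalences() -> dict[str, float]:
    # Marginal prevalences of the clinical-history flags in the emulated
    # autopsy series (proportions of n = 2,508).
    return {
        "hypertension": 0.647,
        "diabetes": 0.278,
        "coronary_artery_disease": 0.204,
        "congestive_heart_failure": 0.168,
        "dyslipidemia": 0.097,
        "cardiac_arrhythmia": 0.069,
        "stroke": 0.119,
        "alcohol_abuse": 0.150,
        "tobacco_use": 0.315,
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the marginal and conditional structure of the
    emulated autopsy series: 47.7% female; age ~ N(70.8, 12.7²) years
    truncated at 50; heights N(1.73, 0.07²) m for men and N(1.62,
    0.07²) m for women (pooled mean ≈ 1.68 m); HC linear in height
    (4.3 cm/m, the regression slope scale) with a male offset
    calibrated to sex means 56.3/54.2 cm; brain volume linear in HC
    calibrated to pooled mean ≈ 1,169 mL, SD ≈ 163 mL.

    ``low_tail_inflation`` is the mixture weight of an HC component
    shifted down by ``low_tail_shift_cm``; with the defaults the
    implied fraction below stratified mean − 2SD cutoffs is ≈ 4.5%
    rather than the Gaussian 2.28%. Set it to 0 for a pure Gaussian HC.

    Cognitive impairment (the latent state behind CDR > 0.5) follows a
    logistic model in the age ≥ 70 indicator and low-tail membership;
    given impairment the IQCODE crosses its 3.4 cutoff with probability
    ``cdr_iqcode_agreement``.
    """

    n_subjects: int = 2508
    seed: int = 0
    p_female: float = 0.477
    age_mean: float = 70.8
    age_sd: float = 12.7
    age_min: float = 50.0
    height_mean_male: float = 1.73
    height_mean_female: float = 1.62
    height_sd: float = 0.07
    # HC model: hc = intercept + slope * height_m + male_offset * [male] + eps
    hc_intercept_cm: float = 47.234
    hc_height_slope_cm_per_m: float = 4.3
    hc_male_offset_cm: float = 1.627
    hc_residual_sd_cm: float = 2.3
    low_tail_inflation: float = 0.055
    low_tail_shift_cm: float = 8.0
    # Brain volume model: bv = intercept + slope * hc_cm + eps
    bv_intercept_ml: float = -385.0
    bv_hc_slope_ml_per_cm: float = 28.1
    bv_residual_sd_ml: float = 144.0
    comorbidity_prevalences: dict[str, float] = field(
        default_factory=_default_prevalences
    )
    p_educ_illiterate: float = 0.158
    p_educ_1_4: float = 0.548
    p_educ_ge5: float = 0.294
    # Logistic model for the latent impairment state.
    cognition_intercept: float = -3.03
    cognition_age_coef: float = 2.11
    cognition_lowhc_coef: float = 0.60
    cdr_iqcode_agreement: float = 0.95
    p_iqcode_noise: float = 0.017

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ConfigError("n_subjects must be >= 0")
        proportions = {
            "p_female": self.p_female,
            "low_tail_inflation": self.low_tail_inflation,
            "p_educ_illiterate": self.p_educ_illiterate,
            "p_educ_1_4": self.p_educ_1_4,
            "p_educ_ge5": self.p_educ_ge5,
            "cdr_iqcode_agreement": self.cdr_iqcode_agreement,
            "p_iqcode_noise": self.p_iqcode_noise,
            **{f"prevalence[{k}]": v for k, v in self.comorbidity_prevalences.items()},
        }
        for name, value in proportions.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be a proportion in [0, 1], got {value}")
        for name, value in (
            ("age_sd", self.age_sd),
            ("height_sd", self.height_sd),
            ("hc_residual_sd_cm", self.hc_residual_sd_cm),
            ("bv_residual_sd_ml", self.bv_residual_sd_ml),
        ):
            if value <= 0:
                raise ConfigError(f"{name} must be > 0, got {value}")
        if set(self.comorbidity_prevalences) != set(CLINICAL_FLAGS):
            raise ConfigError(
                "comorbidity_prevalences must have exactly the keys "
                + ", ".join(CLINICAL_FLAGS)
            )
        p_edu = self.p_educ_illiterate + self.p_educ_1_4 + self.p_educ_ge5
        if abs(p_edu - 1.0) > 1e-9:
            raise ConfigError(f"education proportions must sum to 1, got {p_edu}")

    # -- model-implied quantities used by calibration tests ---------------

    def implied_p_age_ge70(self) -> float:
        """P(age >= 70) under the truncated-normal age model."""
        z70 = (70.0 - self.age_mean) / self.age_sd
        zmin = (self.age_min - self.age_mean) / self.age_sd
        return stats.norm.sf(z70) / stats.norm.sf(zmin)

    def implied_p_impaired(self) -> float:
        """Marginal P(CDR > 0.5) implied by the logistic impairment model."""
        p70 = self.implied_p_age_ge70()
        pi = self.low_tail_inflation
        total = 0.0
        for age_ind, p_age in ((1.0, p70), (0.0, 1.0 - p70)):
            for low_ind, p_low in ((1.0, pi), (0.0, 1.0 - pi)):
                eta = (
                    self.cognition_intercept
                    + self.cognition_age_coef * age_ind
                    + self.cognition_lowhc_coef * low_ind
                )
                total += p_age * p_low / (1.0 + math.exp(-eta))
        return total


@dataclass(frozen=True)
class SubjectRecord:
    """Typed view of one cohort row."""

    subject_id: str
    age: float
    sex: str
    education_years: int
    height_m: float
    hc_cm: float
    brain_volume_ml: float
    hypertension: int
    diabetes: int
    coronary_artery_disease: int
    congestive_heart_failure: int
    dyslipidemia: int
    cardiac_arrhythmia: int
    stroke: int
    alcohol_abuse: int
    tobacco_use: int
    cdr: float
    iqcode: float


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a synthetic cohort of ``config.n_subjects`` subjects.

    Returns a DataFrame with columns :data:`COHORT_COLUMNS`, one row per
    subject. Deterministic for a fixed config (including the seed).
    """
    n = config.n_subjects
    rng = np.random.default_rng(config.seed)
    if n == 0:
        return pd.DataFrame(
            {c: pd.Series(dtype=_empty_dtype(c)) for c in COHORT_COLUMNS}
        )

    female = rng.random(n) < config.p_female
    sex = np.where(female, "female", "male")

    a = (config.age_min - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(
        a, np.inf, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )

    edu_cat = rng.choice(
        3, size=n, p=[config.p_educ_illiterate, config.p_educ_1_4, config.p_educ_ge5]
    )
    education = np.zeros(n, dtype=np.int64)
    education[edu_cat == 1] = rng.integers(1, 5, size=int((edu_cat == 1).sum()))
    education[edu_cat == 2] = rng.integers(5, 16, size=int((edu_cat == 2).sum()))

    height = np.where(
        female, config.height_mean_female, config.height_mean_male
    ) + config.height_sd * rng.standard_normal(n)

    low_tail = rng.random(n) < config.low_tail_inflation
    hc = (
        config.hc_intercept_cm
        + config.hc_height_slope_cm_per_m * height
        + config.hc_male_offset_cm * (~female)
        - config.low_tail_shift_cm * low_tail
        + config.hc_residual_sd_cm * rng.standard_normal(n)
    )
    hc = np.clip(hc, 40.0, 70.0)  # plausibility bound on an adult skull

    bv = (
        config.bv_intercept_ml
        + config.bv_hc_slope_ml_per_cm * hc
        + config.bv_residual_sd_ml * rng.standard_normal(n)
    )
    bv = np.maximum(bv, 1.0)

    flags = {
        name: (rng.random(n) < config.comorbidity_prevalences[name]).astype(np.int64)
        for name in CLINICAL_FLAGS
    }

    eta = (
        config.cognition_intercept
        + config.cognition_age_coef * (age >= 70.0)
        + config.cognition_lowhc_coef * low_tail
    )
    impaired = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))

    iqcode_flag = np.where(
        impaired,
        rng.random(n) < config.cdr_iqcode_agreement,
        rng.random(n) < config.p_iqcode_noise,
    )
    cdr = np.where(
        impaired,
        rng.choice([1.0, 2.0, 3.0], size=n, p=[0.5, 0.3, 0.2]),
        rng.choice([0.0, 0.5], size=n, p=[0.7, 0.3]),
    )
    # uniform() excludes its upper bound, so the unimpaired branch stays < 3.4
    iqcode = np.where(
        iqcode_flag, rng.uniform(3.4, 5.0, size=n), rng.uniform(1.0, 3.4, size=n)
    )

    frame = pd.DataFrame(
        {
            "subject_id": [f"S{i:06d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "education_years": education,
            "height_m": height,
            "hc_cm": hc,
            "brain_volume_ml": bv,
            **flags,
            "cdr": cdr,
            "iqcode": iqcode,
        },
        columns=list(COHORT_COLUMNS),
    )
    return frame


def _empty_dtype(column: str) -> str:
    if column in ("subject_id", "sex"):
        return "object"
    if column == "education_years" or column in CLINICAL_FLAGS:
        return "int64"
    return "float64"


def write_cohort(frame: pd.DataFrame, path) -> None:
    """Write a cohort to CSV (UTF-8, header row, one subject per row)."""
    _check_schema(frame.columns)
    frame.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Raises :class:`SchemaError` if a required column is missing or
    duplicated, and :class:`ParseError` (naming the data row) for
    non-numeric cells or unrecognised sex codes.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    # pandas renames duplicated headers to "col.1"; detect both directions.
    _check_schema(raw.columns)
    frame = pd.DataFrame(index=raw.index)
    frame["subject_id"] = raw["subject_id"]
    bad_sex = ~raw["sex"].isin(_SEXES)
    if bad_sex.any():
        row = int(np.flatnonzero(bad_sex.to_numpy())[0])
        raise ParseError(
            f"row {row + 1}: sex code {raw['sex'].iloc[row]!r} not recognised; "
            f"accepted codes are {_SEXES[0]!r} and {_SEXES[1]!r}"
        )
    frame["sex"] = raw["sex"]
    for column in _NUMERIC_COLUMNS:
        values = pd.to_numeric(raw[column], errors="coerce")
        bad = values.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"row {row + 1}: non-numeric value {raw[column].iloc[row]!r} "
                f"in column {column!r}"
            )
        if column == "education_years" or column in CLINICAL_FLAGS:
            frame[column] = values.astype(np.int64)
        else:
            frame[column] = values.astype(float)
    return frame[list(COHORT_COLUMNS)]


def _check_schema(columns) -> None:
    seen = list(columns)
    required = set(COHORT_COLUMNS)
    missing = sorted(required - set(seen))
    if missing:
        raise SchemaError("missing column(s): " + ", ".join(missing))
    dupes = sorted({c for c in seen if seen.count(c) > 1})
    if dupes:
        raise SchemaError("duplicated column(s): " + ", ".join(dupes))
    extra = sorted(set(seen) - required)
    if extra:
        raise SchemaError("unexpected column(s): " + ", ".join(extra))


def frame_to_records(frame: pd.DataFrame) -> list[SubjectRecord]:
    """Convert a cohort DataFrame to a list of :class:`SubjectRecord`."""
    return [SubjectRecord(**row) for row in frame.to_dict(orient="records")]


def records_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Convert :class:`SubjectRecord` objects back to a cohort DataFrame."""
    return pd.DataFrame(
        [dataclasses.asdict(r) for r in records], columns=list(COHORT_COLUMNS)
    )
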