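"""Synthetic patient cohort with a linear generative model of regional ΔT1.

The real study population (patients scanned for suspected movement
disorders, with pre/post-contrast T1 mapping) is not publicly available, so
this module generates a tabular stand-in cohort that reproduces its
demographic structure: 447 subjects, 307 scanned during the day and 140 at
night, six diagnosis classes with period-specific frequencies, and a
truncated-normal age distribution (mean 63.0 y, SD 13.3 y).

Regional ΔT1 (post- minus pre-contrast T1, ms; more negative = stronger
gadolinium enhancement) is generated from an additive linear model

    ΔT1_r = mu_r(period) + beta_r(period) * (age - reference_age)
            + sex_offset + diagnosis_offset + N(0, subject_sd_r)

with per-region day/night intercepts and age slopes.  The day/night offset
is carried by period-specific intercepts, not a multiplier, and the age
effect is additive with period (no generative interaction) — the analysis
stage then tests for an interaction it knows to be absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

# Day/night windows, minutes since midnight: day = 06:00-17:59.
DAY_START = 360
DAY_END = 1079
MINUTES_PER_DAY = 1440

SEXES = ("male", "female")
DIAGNOSES = ("IPD", "ET", "MSA", "PSP", "VaP", "Other")

#: Analyzed regions, in report order.  These are also the ΔT1 column names.
REGIONS = (
    "cerebral_cortex",
    "cerebellar_cortex",
    "frontal_cortex",
    "parietal_cortex",
    "temporal_cortex",
    "occipital_cortex",
    "cerebral_white_matter",
    "cerebellar_white_matter",
    "bg_pvs",
    "choroid_plexus",
)

COVARIATE_COLUMNS = (
    "subject_id",
    "age",
    "sex",
    "diagnosis",
    "scan_clock",
    "scan_period",
    "contrast_delay",
)


def assign_scan_period(scan_clock: float) -> str:
    """Classify a scan clock time (minutes since midnight) as day or night.

    Daytime is 06:00-17:59 (minutes 360-1079 inclusive); everything else,
    including midnight, is nighttime.
    """
    if not 0 <= scan_clock <= MINUTES_PER_DAY - 1:
        raise ValueError(
            f"scan_clock must be in [0, {MINUTES_PER_DAY - 1}] minutes, got {scan_clock!r}"
        )
    return "day" if DAY_START <= scan_clock <= DAY_END else "night"


@dataclass(frozen=True)
class RegionParams:
    """Generative parameters for one region's ΔT1 (all in ms or ms/year)."""

    mu_day: float
    mu_night: float
    beta_age_day: float
    beta_age_night: float
    subject_sd: float

    def __post_init__(self) -> None:
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be >= 0")

    def mu(self, period: str) -> float:
        return self.mu_day if period == "day" else self.mu_night

    def beta_age(self, period: str) -> float:
        return self.beta_age_day if period == "day" else self.beta_age_night


# Default per-region intercepts (cohort medians, ms) and age slopes
# (ms/year), day and night.  Cortical subject_sd is 22 ms, which under
# normality reproduces the ~29 ms interquartile width of the reported
# cortical ΔT1 distributions; non-cortical SDs are back-derived the same
# way from each region's reported IQR (IQR / 1.349).
_DEFAULT_REGIONS: dict[str, RegionParams] = {
    "cerebral_cortex": RegionParams(-166.4, -160.9, -0.47, -0.34, 22.0),
    "cerebellar_cortex": RegionParams(-174.6, -165.0, 0.02, 0.09, 22.0),
    "frontal_cortex": RegionParams(-147.5, -144.0, -0.34, -0.04, 22.0),
    "parietal_cortex": RegionParams(-169.0, -163.3, -0.39, -0.44, 22.0),
    "temporal_cortex": RegionParams(-170.2, -166.7, -0.55, -0.37, 22.0),
    "occipital_cortex": RegionParams(-229.3, -223.1, -0.94, -1.09, 22.0),
    "cerebral_white_matter": RegionParams(-39.3, -38.4, -0.15, -0.16, 9.0),
    "cerebellar_white_matter": RegionParams(-50.4, -50.3, -0.16, -0.11, 11.0),
    "bg_pvs": RegionParams(-87.2, -88.5, -0.51, -0.29, 20.0),
    "choroid_plexus": RegionParams(-869.7, -869.2, -0.90, -1.66, 108.0),
}

# Diagnosis counts by period, used as sampling proportions.
_DIAGNOSIS_COUNTS = {
    "day": {"IPD": 84, "ET": 64, "MSA": 39, "PSP": 10, "VaP": 7, "Other": 103},
    "night": {"IPD": 64, "ET": 17, "MSA": 13, "PSP": 3, "VaP": 3, "Other": 40},
}
_SEX_COUNTS = {
    "day": {"male": 140, "female": 167},
    "night": {"male": 59, "female": 81},
}


def _normalize(counts: dict[str, float], keys: tuple[str, ...]) -> np.ndarray:
    v = np.array([counts[k] for k in keys], dtype=float)
    total = v.sum()
    if total <= 0:
        raise ValueError("proportions must have a positive sum")
    return v / total


@dataclass(frozen=True)
class GenerativeParams:
    """All knobs of the cohort generator.

    ``sex_offsets`` and ``diagnosis_offsets`` default to zero (no effect
    sizes are reported for them); they exist so that covariate adjustment in
    the analysis stage can be exercised with nonzero values.
    ``contrast_delay`` is acquisition metadata (log-normal, median 5.9 min),
    not a model covariate.
    """

    regions: dict[str, RegionParams] = field(
        default_factory=lambda: dict(_DEFAULT_REGIONS)
    )
    reference_age: float = 63.0
    age_mean: float = 63.0
    age_sd: float = 13.3
    age_bounds: tuple[float, float] = (18.0, 95.0)
    sex_offsets: dict[str, float] = field(
        default_factory=lambda: {s: 0.0 for s in SEXES}
    )
    diagnosis_offsets: dict[str, float] = field(
        default_factory=lambda: {d: 0.0 for d in DIAGNOSES}
    )
    sex_proportions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {p: dict(c) for p, c in _SEX_COUNTS.items()}
    )
    diagnosis_proportions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {p: dict(c) for p, c in _DIAGNOSIS_COUNTS.items()}
    )
    delay_median: float = 5.9
    delay_log_sigma: float = 0.1239  # matches the reported 5.5-6.5 IQR width

    def with_regions(self, **overrides: RegionParams) -> "GenerativeParams":
        regions = dict(self.regions)
        regions.update(overrides)
        return replace(self, regions=regions)


#: Study-size default: 307 daytime and 140 nighttime subjects.
DEFAULT_N_DAY = 307
DEFAULT_N_NIGHT = 140


def _sample_ages(rng: np.random.Generator, n: int, params: GenerativeParams) -> np.ndarray:
    lo, hi = params.age_bounds
    a = (lo - params.age_mean) / params.age_sd
    b = (hi - params.age_mean) / params.age_sd
    return stats.truncnorm.rvs(
        a, b, loc=params.age_mean, scale=params.age_sd, size=n, random_state=rng
    )


def _sample_period_block(
    rng: np.random.Generator, period: str, n: int, params: GenerativeParams
) -> pd.DataFrame:
    ages = _sample_ages(rng, n, params)
    sex = rng.choice(
        SEXES, size=n, p=_normalize(params.sex_proportions[period], SEXES)
    )
    diagnosis = rng.choice(
        DIAGNOSES, size=n, p=_normalize(params.diagnosis_proportions[period], DIAGNOSES)
    )
    # Clock times uniform within the 720-minute period window; the night
    # window wraps midnight (18:00-05:59).
    offset = rng.integers(0, 720, size=n)
    if period == "day":
        clock = DAY_START + offset
    else:
        clock = (DAY_END + 1 + offset) % MINUTES_PER_DAY
    delay = np.exp(
        np.log(params.delay_median) + params.delay_log_sigma * rng.standard_normal(n)
    )
    return pd.DataFrame(
        {
            "age": ages,
            "sex": sex,
            "diagnosis": diagnosis,
            "scan_clock": clock.astype(int),
            "scan_period": period,
            "contrast_delay": delay,
        }
    )


def sample_cohort(
    params: GenerativeParams | None = None,
    n_day: int = DEFAULT_N_DAY,
    n_night: int = DEFAULT_N_NIGHT,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw subject covariates (no ΔT1 columns yet).

    Returns one row per subject with a stable ``subject_id``, demographic
    covariates, the scan clock time, its derived day/night period, and the
    post-contrast acquisition delay.  Identical seeds yield identical
    tables.
    """
    if params is None:
        params = GenerativeParams()
    if n_day < 0 or n_night < 0:
        raise ValueError("cohort sizes must be non-negative")
    rng = np.random.default_rng(seed)
    blocks = [
        _sample_period_block(rng, "day", n_day, params),
        _sample_period_block(rng, "night", n_night, params),
    ]
    table = pd.concat(blocks, ignore_index=True)
    table.insert(0, "subject_id", [f"sub-{i:04d}" for i in range(len(table))])
    # scan_period must agree with the clock-time rule by construction
    for clock, period in zip(table["scan_clock"], table["scan_period"]):
        assert assign_scan_period(clock) == period
    return table


def simulate_regional_delta_t1(
    cohort: pd.DataFrame,
    params: GenerativeParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fill one ΔT1 column (ms) per region from the linear generative model.

    With ``subject_sd = 0`` the values are the deterministic linear
    predictor.  Unknown region names in ``params.regions`` are rejected.
    """
    if params is None:
        params = GenerativeParams()
    unknown = set(params.regions) - set(REGIONS)
    if unknown:
        raise ValueError(f"unknown region name(s): {sorted(unknown)}")
    missing = {"age", "sex", "diagnosis", "scan_period"} - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort is missing covariate column(s): {sorted(missing)}")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    n = len(out)
    age_centered = out["age"].to_numpy() - params.reference_age
    is_day = (out["scan_period"] == "day").to_numpy()
    sex_off = out["sex"].map(params.sex_offsets).to_numpy(dtype=float)
    diag_off = out["diagnosis"].map(params.diagnosis_offsets).to_numpy(dtype=float)
    for region in REGIONS:
        if region not in params.regions:
            continue
        rp = params.regions[region]
        mu = np.where(is_day, rp.mu_day, rp.mu_night)
        beta = np.where(is_day, rp.beta_age_day, rp.beta_age_night)
        noise = rp.subject_sd * rng.standard_normal(n) if rp.subject_sd > 0 else 0.0
        out[region] = mu + beta * age_centered + sex_off + diag_off + noise
    return out


def generate_cohort(
    params: GenerativeParams | None = None,
    n_day: int = DEFAULT_N_DAY,
    n_night: int = DEFAULT_N_NIGHT,
    seed: int = 0,
) -> pd.DataFrame:
    """Covariates plus simulated regional ΔT1 in one call (the default cohort)."""
    covariates = sample_cohort(params, n_day, n_night, seed=seed)
    # distinct stream for the outcome noise so covariates and outcomes can
    # be regenerated independently
    return simulate_regional_delta_t1(covariates, params, seed=seed + 1_000_003)
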