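"""Statistical battery for the day/night ΔT1 analysis.

Implements the study's models on a cohort table:

* ANCOVA of regional ΔT1 on scan period (day vs night) adjusting for age,
  sex, and clinical diagnosis — reported as the Wald p of the period
  coefficient in the linear model;
* age slopes (β, ms per year) fitted separately within the daytime and
  nighttime strata, adjusting for sex and diagnosis;
* the age × scan-period interaction term;
* baseline-comparison tests: Mann-Whitney U, chi-square (Yates-corrected
  for 2×2), and pairwise Fisher's exact tests with Bonferroni adjustment.

Categorical covariates are treatment-coded (diagnosis reference level
``Other``, sex reference ``male``, period reference ``night``, so the
period coefficient is the adjusted day-night difference).  Covariates that
are degenerate in a given cohort (a single observed level, or zero
variance) are dropped from the design; in particular, with no covariate
variation the ANCOVA reduces exactly to the pooled two-sample t-test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg, stats

from .cohort import DIAGNOSES, REGIONS

# ------------------------------------------------------------- linear model


@dataclass
class ModelFit:
    """Least-squares fit: coefficients with Wald t statistics."""

    names: list[str]
    estimates: np.ndarray
    standard_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    df_resid: float
    residual_variance: float

    def coefficient(self, name: str) -> dict:
        i = self.names.index(name)
        return {
            "estimate": float(self.estimates[i]),
            "se": float(self.standard_errors[i]),
            "t": float(self.t_values[i]),
            "p": float(self.p_values[i]),
        }


def fit_linear_model(design: pd.DataFrame, response) -> ModelFit:
    """Ordinary least squares with per-coefficient Wald t-tests.

    ``design`` must include any intercept column explicitly.  Rank-deficient
    designs are rejected with the offending columns named (identified by
    QR with column pivoting).
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    names = list(design.columns)
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
        bad = [names[piv[i]] for i in range(min(n, k)) if diag[i] <= tol]
        bad += [names[p] for p in piv[min(n, k):]]
        raise ValueError(f"rank-deficient design; offending column(s): {bad}")
    if n <= rank:
        raise ValueError("need more observations than design rank")
    res = sm.OLS(y, X).fit()
    return ModelFit(
        names=names,
        estimates=np.asarray(res.params),
        standard_errors=np.asarray(res.bse),
        t_values=np.asarray(res.tvalues),
        p_values=np.asarray(res.pvalues),
        df_resid=float(res.df_resid),
        residual_variance=float(res.scale),
    )


def _add_categorical(
    frame: pd.DataFrame, design: dict, column: str, reference: str, levels
) -> None:
    present = [lv for lv in levels if (frame[column] == lv).any()]
    if len(present) < 2:  # degenerate covariate: drop
        return
    if reference not in present:
        reference = present[0]
    for lv in present:
        if lv == reference:
            continue
        design[f"{column}[{lv}]"] = (frame[column] == lv).astype(float)


def build_design(
    cohort: pd.DataFrame,
    period: bool = False,
    age: bool = True,
    interaction: bool = False,
    diagnosis_reference: str = "Other",
) -> pd.DataFrame:
    """Treatment-coded design matrix for the ΔT1 models.

    Degenerate covariates (single level / zero variance) are dropped.
    """
    design: dict[str, np.ndarray] = {"intercept": np.ones(len(cohort))}
    if period:
        if cohort["scan_period"].nunique() < 2:
            raise ValueError("both day and night subjects are required")
        design["period[day]"] = (cohort["scan_period"] == "day").astype(float)
    if age and cohort["age"].nunique() > 1:
        design["age"] = cohort["age"].astype(float)
    if interaction:
        if not (period and "age" in design):
            raise ValueError("interaction requires both age and period terms")
        design["age:period[day]"] = design["age"] * design["period[day]"]
    _add_categorical(cohort, design, "sex", "male", ("male", "female"))
    _add_categorical(cohort, design, "diagnosis", diagnosis_reference, DIAGNOSES)
    return pd.DataFrame(design, index=cohort.index)


def _check_region(cohort: pd.DataFrame, region: str) -> None:
    if region not in cohort.columns:
        raise ValueError(f"cohort has no ΔT1 column for region {region!r}")


def ancova_group_fit(cohort: pd.DataFrame, region: str) -> ModelFit:
    """Full ANCOVA fit: ΔT1 ~ period + age + sex + diagnosis."""
    _check_region(cohort, region)
    design = build_design(cohort, period=True)
    return fit_linear_model(design, cohort[region])


def ancova_group_pvalue(cohort: pd.DataFrame, region: str) -> float:
    """Adjusted p-value for the day/night difference in a region."""
    return ancova_group_fit(cohort, region).coefficient("period[day]")["p"]


def age_slope_by_period(
    cohort: pd.DataFrame, region: str, period: str
) -> tuple[float, float]:
    """Stratified age slope: (β in ms/year, p) within one scan period,
    adjusting for sex and diagnosis.  Strata below 10 subjects are
    rejected."""
    _check_region(cohort, region)
    stratum = cohort[cohort["scan_period"] == period]
    if len(stratum) < 10:
        raise ValueError(
            f"stratum {period!r} has only {len(stratum)} subjects (minimum 10)"
        )
    design = build_design(stratum, period=False)
    if "age" not in design.columns:
        raise ValueError("age has zero variance in this stratum")
    fit = fit_linear_model(design, stratum[region])
    coef = fit.coefficient("age")
    return coef["estimate"], coef["p"]


def interaction_pvalue(cohort: pd.DataFrame, region: str) -> float:
    """Wald p for the age × scan-period term in the full model."""
    _check_region(cohort, region)
    design = build_design(cohort, period=True, interaction=True)
    fit = fit_linear_model(design, cohort[region])
    return fit.coefficient("age:period[day]")["p"]


def regional_stats_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-region results: adjusted day/night p, stratified age
    slopes, and the interaction p (mirrors the study's result tables)."""
    rows = []
    for region in REGIONS:
        if region not in cohort.columns:
            continue
        beta_day, p_day = age_slope_by_period(cohort, region, "day")
        beta_night, p_night = age_slope_by_period(cohort, region, "night")
        rows.append(
            {
                "region": region,
                "ancova_period_p": ancova_group_pvalue(cohort, region),
                "beta_age_day": beta_day,
                "beta_age_day_p": p_day,
                "beta_age_night": beta_night,
                "beta_age_night_p": p_night,
                "interaction_p": interaction_pvalue(cohort, region),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------- rank / count tests


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null enumeration when both samples have n ≤ 8 and no cross-sample
    ties; otherwise the normal approximation with tie correction and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def chi_square_pvalue(table, yates: bool = True) -> float:
    """Pearson chi-square p-value for an r×c contingency table.

    Yates continuity correction is applied only to 2×2 tables (and only
    when ``yates`` is true).  Tables with a zero row or column margin are
    rejected.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or np.any(obs < 0):
        raise ValueError("table must be a 2-D array of non-negative counts")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    correction = bool(yates) and obs.shape == (2, 2)
    res = stats.chi2_contingency(obs, correction=correction)
    return float(res.pvalue)


def fisher_exact_pvalue(table_2x2) -> float:
    """Two-sided Fisher exact p (point-probability method)."""
    obs = np.asarray(table_2x2)
    if obs.shape != (2, 2):
        raise ValueError("Fisher's exact test requires a 2x2 table")
    return float(stats.fisher_exact(obs, alternative="two-sided")[1])


def pairwise_fisher_bonferroni(
    table, row_labels: list[str] | None = None
) -> pd.DataFrame:
    """Pairwise Fisher's exact tests between category rows of an r×2 table.

    Each pair of rows forms a 2×2 sub-table; the two-sided Fisher p is
    Bonferroni-adjusted by the number of row pairs (capped at 1).
    """
    obs = np.asarray(table, dtype=int)
    if obs.ndim != 2 or obs.shape[1] != 2 or obs.shape[0] < 2:
        raise ValueError("need an r×2 table with r >= 2")
    if row_labels is None:
        row_labels = [str(i) for i in range(obs.shape[0])]
    pairs = list(itertools.combinations(range(obs.shape[0]), 2))
    rows = []
    for i, j in pairs:
        p_raw = fisher_exact_pvalue(obs[[i, j], :])
        rows.append(
            {
                "row_a": row_labels[i],
                "row_b": row_labels[j],
                "p_raw": p_raw,
                "p_adjusted": min(1.0, p_raw * len(pairs)),
            }
        )
    return pd.DataFrame(rows)
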