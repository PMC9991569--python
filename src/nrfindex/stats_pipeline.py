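"""Validation statistics: index-vs-MAR regression, quartiles, logistic models.

The validation workflow has three parts.  First, every NRF variant is
regressed against the mean adequacy ratio (with covariates) by ordinary
least squares and the variant with the highest adjusted R^2 is selected.
Second, the selected score is cut into cohort quartiles (Q1-Q4) and
descriptive tables are compared across quartiles with the Kruskal-Wallis
rank test.  Third, logistic regression estimates the odds of overweight or
central obesity in Q2-Q4 relative to Q1, crude (model 1) and with two
nested covariate sets (models 2 and 3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .errors import (
    CollinearityError,
    ConvergenceError,
    DegenerateDistributionError,
    DomainError,
)
from .nrf_scoring import NutrientProfileConfig, score_cohort, variant_label
from .reference_values import ReferenceValueTable

__all__ = [
    "QUARTILE_LABELS",
    "RegressionFit",
    "ValidationResult",
    "AssociationResult",
    "quartile_assign",
    "fit_mar_regression",
    "compare_index_family",
    "kruskal_wallis",
    "fit_quartile_logistic",
    "build_model_covariates",
    "describe_by",
]

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")

#: Covariates of the MAR-validation regression.
VALIDATION_COVARIATES = (
    "age", "sex", "bmi", "smoking", "life_pressure",
    "grip_normal", "sedentary_h", "family_number",
)

#: Nested covariate sets of the quartile logistic models.
MODEL2_COVARIATES = ("age", "sex", "education_band")
MODEL3_COVARIATES = MODEL2_COVARIATES + ("income_band", "activity_band", "nap_frequency")

_CATEGORICAL_COVARIATES = {"sex", "education_band", "income_band", "activity_band"}


@dataclass(frozen=True)
class RegressionFit:
    adjusted_r2: float
    r2: float
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    n: int


@dataclass(frozen=True)
class ValidationResult:
    table: pd.DataFrame  # variant, algorithm, reference_amount, n, adjusted_r2
    best_variant: str

    @property
    def best_adjusted_r2(self) -> float:
        return float(self.table["adjusted_r2"].max())


@dataclass(frozen=True)
class AssociationResult:
    outcome: str
    model: int
    table: pd.DataFrame  # index Q1..Q4: odds_ratio, ci_low, ci_high, n, cases
    n: int


def quartile_assign(scores) -> pd.Series:
    """Label each value Q1-Q4 by the sample 25th/50th/75th percentiles.

    Percentiles use linear interpolation between closest ranks; a value equal
    to a cut point goes to the lower quartile.
    """
    s = pd.Series(scores, dtype=float)
    if s.isna().any():
        raise DomainError("scores contain missing values")
    if s.nunique() < 4:
        raise DegenerateDistributionError(
            f"need at least 4 distinct score values, got {s.nunique()}"
        )
    q25, q50, q75 = np.percentile(s.to_numpy(), [25, 50, 75])
    x = s.to_numpy()
    labels = np.select(
        [x <= q25, x <= q50, x <= q75],
        ["Q1", "Q2", "Q3"],
        default="Q4",
    )
    return pd.Series(labels, index=s.index, name="quartile")


def _design(covariates: pd.DataFrame | None, index) -> pd.DataFrame:
    """Reference-coded design columns for the covariate block."""
    if covariates is None or covariates.shape[1] == 0:
        return pd.DataFrame(index=index)
    blocks = []
    for col in covariates.columns:
        series = covariates[col]
        if col in _CATEGORICAL_COVARIATES or series.dtype == object:
            dummies = pd.get_dummies(series, prefix=col, drop_first=True, dtype=float)
            blocks.append(dummies)
        else:
            blocks.append(series.astype(float).to_frame(col))
    return pd.concat(blocks, axis=1)


def fit_mar_regression(
    mar,
    score,
    covariates: pd.DataFrame | None = None,
) -> RegressionFit:
    """OLS of MAR on an NRF score plus covariates; reports adjusted R^2.

    adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1) with p predictors
    excluding the intercept.
    """
    y = pd.Series(mar, dtype=float)
    x = pd.Series(score, dtype=float, name="score")
    X = pd.concat([x.to_frame(), _design(covariates, x.index)], axis=1)
    if X.shape[0] <= X.shape[1] + 1:
        raise DomainError("need n > number of predictors + 1")
    rank = np.linalg.matrix_rank(X.to_numpy(float))
    if rank < X.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.to_numpy(), 0.0)
        worst = corr.stack().idxmax()
        raise CollinearityError(f"singular design matrix; near-duplicate columns {worst}")
    model = sm.OLS(y.to_numpy(float), sm.add_constant(X.astype(float)))
    res = model.fit()
    return RegressionFit(
        adjusted_r2=float(res.rsquared_adj),
        r2=float(res.rsquared),
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        n=int(res.nobs),
    )


def compare_index_family(
    intakes: pd.DataFrame,
    participants: pd.DataFrame,
    mar,
    variants: list[NutrientProfileConfig],
    dv_table: ReferenceValueTable,
    covariates: pd.DataFrame | None = None,
) -> ValidationResult:
    """Fit one MAR regression per NRF variant and pick the adjusted-R^2 argmax.

    All fits use identical rows; ties are broken by listed order (the first
    variant attaining the maximum wins).
    """
    if len(variants) < 2:
        raise DomainError("need at least 2 variants to compare")
    rows = []
    scores = {}
    for cfg in variants:
        label = variant_label(cfg)
        s = score_cohort(intakes, participants, cfg, dv_table)
        fit = fit_mar_regression(pd.Series(mar, index=intakes.index), s, covariates)
        scores[label] = s
        rows.append(
            {
                "variant": label,
                "name": cfg.name,
                "algorithm": cfg.algorithm,
                "reference_amount": cfg.reference_amount,
                "n_encourage": cfg.n,
                "adjusted_r2": fit.adjusted_r2,
                "score_coefficient": float(fit.params["score"]),
                "score_pvalue": float(fit.pvalues["score"]),
                "n": fit.n,
            }
        )
    table = pd.DataFrame(rows)
    best = table.loc[table["adjusted_r2"].idxmax(), "variant"]
    return ValidationResult(table=table, best_variant=str(best))


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis rank test (tie-corrected H, chi-square p on k-1 df)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise DomainError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise DomainError("empty group")
    if sum(len(g) for g in groups) < 3:
        raise DomainError("need total n >= 3")
    try:
        h, p = scipy.stats.kruskal(*groups)
    except ValueError:  # all values identical: no variation, H = 0 by convention
        return 0.0, 1.0
    return float(h), float(p)


def fit_quartile_logistic(
    outcome,
    quartiles,
    covariates: pd.DataFrame | None = None,
    outcome_name: str = "outcome",
    model: int = 1,
) -> AssociationResult:
    """Logistic odds ratios for Q2-Q4 against Q1 with Wald 95% CIs.

    Q1 is the reference (OR = 1 by construction).  OR = exp(beta) and
    CI = exp(beta +- 1.96 SE) on the logit scale.
    """
    y = pd.Series(outcome).astype(float)
    q = pd.Series(quartiles, index=y.index).astype(str)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise DomainError("outcome must be binary 0/1")
    if y.nunique() < 2:
        raise DomainError("both outcome classes must be present")
    if y[q == "Q1"].nunique() < 2:
        raise DomainError("both outcome classes must be present in Q1")

    dummies = pd.get_dummies(pd.Categorical(q, categories=QUARTILE_LABELS), dtype=float)
    X = pd.concat([dummies[["Q2", "Q3", "Q4"]].set_axis(y.index), _design(covariates, y.index)], axis=1)
    cell_counts = pd.crosstab(q, y)
    empty_cells = (cell_counts == 0).any(axis=1)
    if empty_cells.any():
        import warnings

        warnings.warn(
            f"empty quartile-outcome cells in {list(cell_counts.index[empty_cells])}; "
            "odds ratios for those quartiles will have very wide intervals"
        )
    try:
        res = sm.Logit(y.to_numpy(), sm.add_constant(X.astype(float))).fit(disp=0)
    except Exception as exc:  # perfect separation raises PerfectSeparationError
        raise ConvergenceError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise ConvergenceError("logistic fit did not converge (possible separation)")

    rows = {"Q1": {"odds_ratio": 1.0, "ci_low": np.nan, "ci_high": np.nan}}
    for lab in ("Q2", "Q3", "Q4"):
        beta = float(res.params[lab])
        se = float(res.bse[lab])
        rows[lab] = {
            "odds_ratio": float(np.exp(beta)),
            "ci_low": float(np.exp(beta - 1.96 * se)),
            "ci_high": float(np.exp(beta + 1.96 * se)),
        }
    table = pd.DataFrame(rows).T
    table["n"] = q.value_counts().reindex(QUARTILE_LABELS).to_numpy()
    table["cases"] = y.groupby(q.to_numpy()).sum().reindex(QUARTILE_LABELS).to_numpy()
    return AssociationResult(outcome=outcome_name, model=model, table=table, n=len(y))


def build_model_covariates(participants: pd.DataFrame, model: int) -> pd.DataFrame | None:
    """Covariate block of logistic model 1 (crude), 2, or 3."""
    if model == 1:
        return None
    if model == 2:
        return participants[list(MODEL2_COVARIATES)]
    if model == 3:
        return participants[list(MODEL3_COVARIATES)]
    raise DomainError(f"unknown model {model}; expected 1, 2 or 3")


def describe_by(
    cohort: pd.DataFrame,
    by: str,
    variables: list[str],
) -> pd.DataFrame:
    """Median (P25, P75) of each variable per stratum, with Kruskal-Wallis p.

    Mirrors the descriptive tables of a quartile validation study: one row
    per variable, one column block per stratum of ``by``.
    """
    strata = sorted(cohort[by].dropna().unique(), key=str)
    rows = []
    for var in variables:
        row: dict[str, object] = {"variable": var}
        groups = []
        for stratum in strata:
            vals = cohort.loc[cohort[by] == stratum, var].dropna().to_numpy(float)
            groups.append(vals)
            med, p25, p75 = np.percentile(vals, [50, 25, 75]) if len(vals) else (np.nan,) * 3
            row[f"{stratum}"] = f"{med:.2f} ({p25:.2f}, {p75:.2f})"
        if len(groups) >= 2 and all(len(g) for g in groups):
            _, p = kruskal_wallis(groups)
            row["kw_pvalue"] = p
        else:
            row["kw_pvalue"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")
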