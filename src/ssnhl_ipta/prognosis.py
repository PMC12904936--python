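"""Prognostic regression models for hearing recovery.

The analyses are specified here as model contracts — outcome, covariate set
with reference categories, and fitting subset — while the numerical fitting
delegates to statsmodels (OLS with Wald 95% CIs; maximum-likelihood logistic
regression reported as odds ratios).

Model families:

* multivariable linear models of absolute recovery in dB (iPTA or PTA4);
* multivariable logistic models of the categorical outcomes, where full
  recovery is compared against incomplete recovery on the whole cohort and
  partial recovery against no recovery with the fully recovered excluded;
* crude and adjusted regressions of recovery on disease duration until
  assessment, separately in the corticosteroid-treated and untreated arms;
* sensitivity re-fits of the primary linear model on rule-defined subsets.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "ModelSpec",
    "RegressionResult",
    "CollinearityError",
    "default_linear_spec",
    "full_recovery_spec",
    "partial_vs_none_spec",
    "fit_linear_prognostic",
    "fit_logistic_prognostic",
    "duration_subgroup_regressions",
    "sensitivity_analysis",
    "SENSITIVITY_RULES",
]

# Forest-plot covariate set of the primary multivariable models: age group
# (reference: middle-aged adults), sex, degree of HL (reference: no/mild),
# frequency-range-specific HL, dizziness, tinnitus, hypertension, diabetes,
# any corticosteroid treatment (reference: none), and disease duration until
# assessment in days.
DEFAULT_COVARIATES: tuple[str, ...] = (
    "C(age_group, Treatment('middle_aged'))",
    "female",
    "C(degree, Treatment('no_mild'))",
    "range_specific",
    "dizziness",
    "tinnitus",
    "hypertension",
    "diabetes",
    "treated",
    "duration_days",
)

ADJUSTMENT_COVARIATES: tuple[str, ...] = (
    "C(age_group, Treatment('middle_aged'))",
    "C(degree, Treatment('no_mild'))",
    "hypertension",
    "diabetes",
    "tinnitus",
    "dizziness",
)


class CollinearityError(ValueError):
    """The design matrix is rank deficient; names the offending terms."""


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one regression: outcome, covariates, subset rule."""

    outcome: str
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    subset: Optional[str] = None          # pandas query string
    family: str = "linear"                # "linear" | "logistic"
    name: str = ""

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.covariates) if self.covariates else "1"
        return f"{self.outcome} ~ {rhs}"


@dataclass
class RegressionResult:
    """Coefficient table plus fit diagnostics.

    ``table`` has one row per term: term, estimate (B in dB per unit, or OR),
    ci_low, ci_high, p.  For logistic fits the estimate column is the odds
    ratio and ``log_table`` keeps the log-odds scale.
    """

    spec: ModelSpec
    table: pd.DataFrame
    n: int
    converged: bool = True
    separation_flag: bool = False
    r_squared: Optional[float] = None
    dropped_terms: tuple[str, ...] = ()
    n_excluded: int = 0

    def coefficient(self, term_substring: str) -> pd.Series:
        """First coefficient row whose term name contains ``term_substring``."""
        hits = self.table[self.table["term"].str.contains(term_substring, regex=False)]
        if hits.empty:
            raise KeyError(f"no term matching {term_substring!r}; "
                           f"available: {list(self.table['term'])}")
        return hits.iloc[0]

    def to_forest_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.insert(0, "model", self.spec.name or self.spec.family)
        out.insert(1, "outcome", self.spec.outcome)
        return out


_TREATMENT_RE = re.compile(r"C\((\w+),\s*Treatment\('([^']+)'\)\)")


def _fix_references(data: pd.DataFrame, covariates: Sequence[str]) -> tuple[str, ...]:
    """If a Treatment reference level is absent from the fitting subset,
    fall back to the subset's most common level as reference."""
    fixed = []
    for term in covariates:
        m = _TREATMENT_RE.fullmatch(term)
        if m:
            col, ref = m.groups()
            if col in data.columns and ref not in set(data[col].dropna().unique()):
                new_ref = data[col].mode().iloc[0]
                term = f"C({col}, Treatment('{new_ref}'))"
        fixed.append(term)
    return tuple(fixed)


def _prepare(df: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, tuple[str, ...], int]:
    """Subset, complete-case filter, and drop covariates without variation."""
    data = df.query(spec.subset) if spec.subset else df
    n_subset_excluded = len(df) - len(data)
    cols = set()
    for term in (spec.outcome, *spec.covariates):
        for col in df.columns:
            if col in term:
                cols.add(col)
    data = data.dropna(subset=[c for c in cols if c in data.columns])
    kept, dropped = [], []
    for term in spec.covariates:
        refs = [c for c in data.columns if c in term]
        if refs and all(data[c].nunique(dropna=True) < 2 for c in refs):
            dropped.append(term)
        else:
            kept.append(term)
    if dropped:
        warnings.warn(
            f"covariates without variation dropped from {spec.name or spec.outcome}: "
            f"{dropped}", stacklevel=3,
        )
    return data.copy(), _fix_references(data, kept), n_subset_excluded


def _check_rank(model) -> None:
    X = np.asarray(model.exog, dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        from scipy.linalg import qr

        _, r, piv = qr(X, mode="economic", pivoting=True)
        tol = abs(r[0, 0]) * max(X.shape) * np.finfo(float).eps
        bad = [model.exog_names[piv[i]] for i in range(rank, X.shape[1])]
        raise CollinearityError(f"design matrix is rank deficient; collinear terms: {bad}")


def fit_linear_prognostic(df: pd.DataFrame, spec: ModelSpec) -> RegressionResult:
    """Multivariable OLS of absolute recovery (dB) with Wald 95% CIs."""
    data, covariates, n_subset_excluded = _prepare(df, spec)
    use = ModelSpec(spec.outcome, covariates, None, "linear", spec.name)
    model = smf.ols(use.formula, data=data)
    if model.exog.shape[0] <= model.exog.shape[1]:
        raise ValueError(
            f"n = {model.exog.shape[0]} rows for {model.exog.shape[1]} parameters"
        )
    _check_rank(model)
    fit = model.fit()
    ci = fit.conf_int(alpha=0.05)
    table = pd.DataFrame(
        {
            "term": fit.params.index,
            "estimate": fit.params.to_numpy(),
            "ci_low": ci[0].to_numpy(),
            "ci_high": ci[1].to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    )
    return RegressionResult(
        spec=spec,
        table=table,
        n=int(fit.nobs),
        r_squared=float(fit.rsquared),
        dropped_terms=tuple(t for t in spec.covariates if t not in covariates),
        n_excluded=n_subset_excluded,
    )


def fit_logistic_prognostic(df: pd.DataFrame, spec: ModelSpec) -> RegressionResult:
    """Multivariable logistic regression reported as odds ratios.

    Complete separation (or non-convergence) is flagged on the result rather
    than silently reported.
    """
    data, covariates, n_subset_excluded = _prepare(df, spec)
    use = ModelSpec(spec.outcome, covariates, None, "logistic", spec.name)
    model = smf.logit(use.formula, data=data)
    _check_rank(model)
    separation = False
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(disp=0, maxiter=100)
        except Exception:
            separation = True
            fit = model.fit(disp=0, method="bfgs", maxiter=500)
    converged = bool(fit.mle_retvals.get("converged", True))
    if not converged or not np.all(np.isfinite(fit.bse)):
        separation = True
    ci = fit.conf_int(alpha=0.05)
    log_table = pd.DataFrame(
        {
            "term": fit.params.index,
            "estimate": fit.params.to_numpy(),
            "ci_low": ci[0].to_numpy(),
            "ci_high": ci[1].to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    )
    or_table = log_table.copy()
    or_table[["estimate", "ci_low", "ci_high"]] = np.exp(
        log_table[["estimate", "ci_low", "ci_high"]]
    )
    result = RegressionResult(
        spec=spec,
        table=or_table,
        n=int(fit.nobs),
        converged=converged,
        separation_flag=separation,
        r_squared=float(fit.prsquared),
        dropped_terms=tuple(t for t in spec.covariates if t not in covariates),
        n_excluded=n_subset_excluded,
    )
    result.log_table = log_table  # log-odds scale kept alongside
    return result


def default_linear_spec(measure: str = "ipta") -> ModelSpec:
    return ModelSpec(
        outcome=f"recovery_{measure}",
        covariates=DEFAULT_COVARIATES,
        family="linear",
        name=f"linear_{measure}",
    )


def full_recovery_spec(measure: str = "ipta",
                       covariates: Sequence[str] = DEFAULT_COVARIATES) -> ModelSpec:
    """Full recovery vs incomplete recovery (whole cohort)."""
    return ModelSpec(
        outcome=f"full_{measure}",
        covariates=tuple(covariates),
        family="logistic",
        name=f"full_vs_incomplete_{measure}",
    )


def partial_vs_none_spec(measure: str = "ipta",
                         covariates: Sequence[str] = DEFAULT_COVARIATES) -> ModelSpec:
    """Partial vs no recovery; the fully recovered are excluded from the fit."""
    return ModelSpec(
        outcome=f"partial_{measure}",
        covariates=tuple(covariates),
        subset=f"category_{measure} != 'full'",
        family="logistic",
        name=f"partial_vs_none_{measure}",
    )


def duration_subgroup_regressions(
    df: pd.DataFrame,
    outcome: str = "recovery_ipta",
    duration_col: str = "duration_days",
) -> dict[str, dict[str, RegressionResult]]:
    """Crude and adjusted recovery-on-duration regressions per treatment arm.

    The crude model is a simple linear regression of recovery on disease
    duration until assessment; the adjusted model additionally includes age
    group, degree of HL, hypertension, diabetes, tinnitus and dizziness (the
    variables unevenly distributed between arms).
    """
    out: dict[str, dict[str, RegressionResult]] = {}
    for arm, mask in (("treated", "treated == 1"), ("untreated", "treated == 0")):
        if df.query(mask).empty:
            raise ValueError(f"empty treatment arm: {arm}")
        crude = fit_linear_prognostic(
            df,
            ModelSpec(outcome, (duration_col,), subset=mask, name=f"crude_{arm}"),
        )
        adjusted = fit_linear_prognostic(
            df,
            ModelSpec(
                outcome,
                (duration_col, *ADJUSTMENT_COVARIATES),
                subset=mask,
                name=f"adjusted_{arm}",
            ),
        )
        out[arm] = {"crude": crude, "adjusted": adjusted}
    return out


SENSITIVITY_RULES: dict[str, str] = {
    # keep rows NOT matching the exclusion condition
    "exclude_pre_audiogram_treated": "pretreated_before_audiogram == 0",
    "exclude_nonstandard_treatment": "nonstandard_treatment == 0",
    "exclude_identified_etiology": "identified_etiology == 0",
}


def sensitivity_analysis(
    df: pd.DataFrame,
    rule: str,
    spec: Optional[ModelSpec] = None,
) -> RegressionResult:
    """Re-fit the primary linear model excluding a rule-defined subgroup."""
    if rule not in SENSITIVITY_RULES:
        raise KeyError(f"unknown sensitivity rule: {rule!r}; "
                       f"options: {sorted(SENSITIVITY_RULES)}")
    spec = spec or default_linear_spec("ipta")
    keep = SENSITIVITY_RULES[rule]
    subset = f"({spec.subset}) and ({keep})" if spec.subset else keep
    reduced = ModelSpec(spec.outcome, spec.covariates, subset, spec.family,
                        name=f"{spec.name}_{rule}")
    if df.query(subset).empty:
        raise ValueError(f"sensitivity rule {rule!r} empties the cohort")
    return fit_linear_prognostic(df, reduced)
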