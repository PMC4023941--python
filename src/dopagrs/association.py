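"""Covariate-adjusted linear association between scores and symptom scales.

The primary model is ordinary least squares of the continuous depressive-symptom
score on the genetic risk score plus covariates (continuous covariates entered
as-is, categorical covariates dummy-coded with k-1 indicators against the most
frequent level). Inference is t-based: two-sided p-values and 95% confidence
intervals from the t distribution at the residual degrees of freedom. Skewed
phenotypes are screened descriptively (moment skewness/kurtosis), never
transformed. Single-variant scans control the family-wise error rate by
Bonferroni over the number of variants scanned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import CohortTable
from .panel import ScorePanel
from .scoring import SCORE_COLUMN, compute_grs

GRS_TERM = "grs"


class AssociationError(ValueError):
    pass


@dataclass
class DesignMatrix:
    """Response vector and predictor matrix (intercept included) for one fit."""

    y: pd.Series
    X: pd.DataFrame

    def __post_init__(self) -> None:
        if self.y.isna().any() or self.X.isna().any().any():
            raise AssociationError("design matrix contains missing values")
        if len(self.y) != len(self.X):
            raise AssociationError("response and predictors have different lengths")

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass
class ModelFit:
    """OLS fit summary: per-term beta, SE, t, two-sided p and 95% CI, plus fit stats."""

    params: pd.DataFrame  # index=term; columns beta, se, t, p, ci_low, ci_high
    r_squared: float
    n: int
    df_resid: int

    def term(self, name: str) -> pd.Series:
        if name not in self.params.index:
            raise AssociationError(f"no term {name!r} in fit (terms: {list(self.params.index)})")
        return self.params.loc[name]


@dataclass
class DescriptiveStats:
    mean: float
    sd: float
    skewness: float
    kurtosis: float
    min: float
    max: float
    n: int
    excess_kurtosis: bool = True
    defined: bool = True


@dataclass
class MultiplicityReport:
    """Bonferroni accounting for a family of m tests at family-wise alpha."""

    alpha: float
    m: int
    significant: list[str] = field(default_factory=list)

    @property
    def threshold(self) -> float:
        return self.alpha / self.m


def bonferroni_threshold(alpha: float, m: int) -> float:
    if m < 1:
        raise AssociationError("number of tests must be >= 1")
    return alpha / m


def encode_covariates(
    cohort: CohortTable,
    covariate_spec,
    reference_levels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Dummy-code the named covariates into numeric design columns.

    Numeric covariates pass through; categorical ones become k-1 indicator
    columns named ``name[level]`` against a reference level (the most frequent
    level unless pinned via ``reference_levels``). A constant column, or a
    level pinned as reference that is absent from the data, is an error.
    """
    if cohort.covariates is None:
        raise AssociationError("cohort has no covariates")
    reference_levels = reference_levels or {}
    cols: dict[str, pd.Series] = {}
    for name in covariate_spec:
        if name not in cohort.covariates.columns:
            raise AssociationError(f"covariate {name!r} not present in cohort")
        series = cohort.covariates[name]
        if pd.api.types.is_numeric_dtype(series):
            if series.nunique() <= 1:
                raise AssociationError(f"covariate {name!r} is constant")
            cols[name] = series.astype(float)
        else:
            levels = series.value_counts()  # sorted by frequency, ties by order
            if len(levels) <= 1:
                raise AssociationError(f"covariate {name!r} is constant")
            ref = reference_levels.get(name, levels.index[0])
            if ref not in levels.index:
                raise AssociationError(
                    f"reference level {ref!r} for {name!r} not observed in the data"
                )
            for level in sorted(lv for lv in levels.index if lv != ref):
                cols[f"{name}[{level}]"] = (series == level).astype(float)
    return pd.DataFrame(cols, index=cohort.subjects)


def ols_fit(design: DesignMatrix) -> ModelFit:
    """Ordinary least squares with t-based inference.

    SEs come from sigma-hat^2 (X'X)^-1; p-values are two-sided from the t
    distribution at the residual df and the 95% CI is beta +/- t_{0.975,df} SE.
    A rank-deficient design is rejected, naming the collinear columns.
    """
    X = design.X
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        suspect = _collinear_columns(X)
        raise AssociationError(f"design matrix is rank deficient; collinear columns: {suspect}")
    if design.n <= X.shape[1]:
        raise AssociationError("more parameters than observations")
    res = sm.OLS(design.y.to_numpy(), X.to_numpy()).fit()
    ci = res.conf_int(alpha=0.05)
    params = pd.DataFrame(
        {
            "beta": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
        },
        index=X.columns,
    )
    return ModelFit(
        params=params,
        r_squared=float(res.rsquared),
        n=design.n,
        df_resid=int(res.df_resid),
    )


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    # greedy scan: columns whose addition does not raise the rank
    bad, kept = [], []
    for col in X.columns:
        trial = X[kept + [col]].to_numpy()
        if np.linalg.matrix_rank(trial) == len(kept) + 1:
            kept.append(col)
        else:
            bad.append(col)
    return bad


def _design_with_predictor(
    cohort: CohortTable, predictor: pd.Series, covariate_spec
) -> DesignMatrix:
    if cohort.phenotype is None:
        raise AssociationError("cohort has no phenotype")
    parts = {"const": pd.Series(1.0, index=cohort.subjects), predictor.name: predictor}
    X = pd.DataFrame(parts)
    if covariate_spec:
        X = pd.concat([X, encode_covariates(cohort, covariate_spec)], axis=1)
    return DesignMatrix(y=cohort.phenotype.astype(float), X=X)


def grs_association(
    cohort: CohortTable,
    panel: ScorePanel,
    covariate_spec=(),
    mode: str = "hardcall",
) -> ModelFit:
    """Fit phenotype ~ GRS + covariates; the ``grs`` row is the headline estimate."""
    scores = compute_grs(cohort, panel, mode=mode)
    predictor = scores[SCORE_COLUMN].rename(GRS_TERM)
    return ols_fit(_design_with_predictor(cohort, predictor, covariate_spec))


def single_variant_scan(
    cohort: CohortTable,
    panel: ScorePanel,
    covariate_spec=(),
    mode: str = "hardcall",
    alpha: float = 0.05,
) -> tuple[dict[str, ModelFit], MultiplicityReport]:
    """One adjusted fit per variant (points-coded predictor), Bonferroni-controlled."""
    points = compute_grs(cohort, panel, mode=mode)
    fits: dict[str, ModelFit] = {}
    report = MultiplicityReport(alpha=alpha, m=len(panel))
    for rule in panel:
        predictor = points[rule.variant_id].astype(float).rename(rule.variant_id)
        fit = ols_fit(_design_with_predictor(cohort, predictor, covariate_spec))
        fits[rule.variant_id] = fit
        if fit.term(rule.variant_id)["p"] < report.threshold:
            report.significant.append(rule.variant_id)
    return fits, report


def descriptive_stats(values, excess_kurtosis: bool = True) -> DescriptiveStats:
    """Moment-based summary used to screen phenotypes for gross non-normality.

    Skewness is the bias-adjusted sample coefficient (G1); kurtosis defaults to
    bias-adjusted *excess* kurtosis (G2, normal baseline 0) with
    ``excess_kurtosis=False`` selecting the Pearson convention (baseline 3).
    A constant vector has undefined shape moments and is flagged.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise AssociationError("descriptive statistics require at least two values")
    sd = float(np.std(arr, ddof=1))
    if sd == 0.0:
        return DescriptiveStats(
            mean=float(arr.mean()), sd=0.0, skewness=math.nan, kurtosis=math.nan,
            min=float(arr.min()), max=float(arr.max()), n=arr.size,
            excess_kurtosis=excess_kurtosis, defined=False,
        )
    skew = float(stats.skew(arr, bias=False))
    kurt = float(stats.kurtosis(arr, fisher=True, bias=False))
    if not excess_kurtosis:
        kurt += 3.0
    return DescriptiveStats(
        mean=float(arr.mean()), sd=sd, skewness=skew, kurtosis=kurt,
        min=float(arr.min()), max=float(arr.max()), n=arr.size,
        excess_kurtosis=excess_kurtosis,
    )


def predicted_difference(fit: ModelFit, predictor_name: str, delta: float) -> float:
    """|beta| x delta: the expected phenotype difference across a predictor span.

    With a slope of -0.80 per score point, the difference between the lowest
    and highest possible 5-variant scores (delta = 10) is 8 scale points.
    """
    beta = fit.term(predictor_name)["beta"]
    return abs(beta) * delta


def score_stratified_means(cohort: CohortTable, scores: pd.DataFrame) -> pd.DataFrame:
    """Mean phenotype with SE per integer score level (figure-style summary).

    SE = sd / sqrt(n); a level with a single subject reports SE as NaN.
    """
    if cohort.phenotype is None:
        raise AssociationError("cohort has no phenotype")
    s = scores[SCORE_COLUMN]
    if not np.allclose(s, np.round(s)):
        raise AssociationError("stratified means require integer-valued scores")
    df = pd.DataFrame({"score": s.round().astype(int), "y": cohort.phenotype.astype(float)})
    if df.empty:
        raise AssociationError("no subjects to stratify")
    grouped = df.groupby("score")["y"]
    out = pd.DataFrame({
        "n": grouped.size(),
        "mean": grouped.mean(),
        "se": grouped.std(ddof=1) / np.sqrt(grouped.size()),
    }).reset_index()
    return out
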