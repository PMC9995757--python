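"""Fall-frequency modeling: correlation screening and multivariable OLS.

The outcome is prospective fall frequency (falls per week from diaries).
Candidate biomarkers are first screened by Pearson correlation with the
outcome (pairwise-complete over missing values); a fixed five-term
linear model is then fitted by ordinary least squares:

    fall_freq ~ 1 + Nfall_Freq_h + Tot_Num_Abs + Sit_Freq_h + updrs + alpha_8

The results object carries per-term estimates, standard errors,
t-statistics and two-sided p-values (Student t on the residual degrees
of freedom), plus the ANOVA decomposition (Total/Model/Residual sums of
squares, mean squares, the model F statistic and its p-value).

Follows the statsmodels idiom: build a model from data, ``fit()``
returns a results object with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .io_core import ValidationError

__all__ = [
    "DEFAULT_TERMS",
    "CollinearityError",
    "CorrelationReport",
    "correlation_screen",
    "FallFrequencyModel",
    "FallFrequencyResults",
    "fit_ols",
    "term_t_statistics",
    "anova_summary",
]

# The five regressors of the fixed fall-frequency model (plus intercept).
DEFAULT_TERMS = ["Nfall_Freq_h", "Tot_Num_Abs", "Sit_Freq_h", "updrs", "alpha_8"]


class CollinearityError(ValueError):
    """The design matrix is rank deficient."""


@dataclass
class CorrelationReport:
    """Pairwise Pearson correlations and the |r|-ranking against the outcome."""

    matrix: pd.DataFrame  # symmetric, diagonal 1, NaN for constant features
    outcome: str
    ranking: pd.Series  # top-k features ordered by |r| with the outcome

    def top_features(self) -> list[str]:
        return list(self.ranking.index)


def correlation_screen(
    features: pd.DataFrame, outcome: str = "fall_freq", k: int = 10
) -> CorrelationReport:
    """Rank features by absolute Pearson correlation with the outcome.

    Correlations use pairwise-complete observations.  A constant feature
    has undefined correlations (NaN) and never enters the ranking.
    Requires at least 3 subjects with a non-missing outcome.
    """
    if outcome not in features.columns:
        raise ValidationError(f"outcome column {outcome!r} not in table")
    if features[outcome].notna().sum() < 3:
        raise ValidationError("need >= 3 subjects with non-missing outcome")
    matrix = features.corr(method="pearson", min_periods=2)
    r = matrix[outcome].drop(index=outcome).dropna()
    ranking = r.reindex(r.abs().sort_values(ascending=False).index)[:k]
    return CorrelationReport(matrix=matrix, outcome=outcome, ranking=ranking)


@dataclass
class FallFrequencyResults:
    """OLS results: per-term inference plus the ANOVA decomposition."""

    params: pd.Series  # estimates, intercept first
    bse: pd.Series  # standard errors
    tvalues: pd.Series
    pvalues: pd.Series
    ss_total: float
    ss_model: float
    ss_resid: float
    df_model: int
    df_resid: int
    nobs: int

    @property
    def fvalue(self) -> float:
        ms_m = self.ss_model / self.df_model
        ms_r = self.ss_resid / self.df_resid
        return ms_m / ms_r if ms_r > 0 else float("nan")

    @property
    def f_pvalue(self) -> float:
        f = self.fvalue
        if np.isnan(f):
            return float("nan")
        return float(sps.f.sf(f, self.df_model, self.df_resid))

    @property
    def rsquared(self) -> float:
        return 1.0 - self.ss_resid / self.ss_total if self.ss_total > 0 else float("nan")

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Estimate": self.params,
                "Standard error": self.bse,
                "t-stat": self.tvalues,
                "p-value": self.pvalues,
            }
        )

    def anova(self) -> pd.DataFrame:
        """Total/Model/Residual rows: SumSq, MeanSq, F, p-value."""
        ms_m = self.ss_model / self.df_model
        ms_r = self.ss_resid / self.df_resid if self.df_resid > 0 else float("nan")
        df_t = self.df_model + self.df_resid
        return pd.DataFrame(
            {
                "SumSq": [self.ss_total, self.ss_model, self.ss_resid],
                "MeanSq": [self.ss_total / df_t if df_t else float("nan"), ms_m, ms_r],
                "F": [float("nan"), self.fvalue, float("nan")],
                "p-value": [float("nan"), self.f_pvalue, float("nan")],
            },
            index=["Total", "Model", "Residual"],
        )

    def summary(self) -> str:
        lines = [
            "Fall-frequency linear model (OLS)",
            f"n = {self.nobs}, df_model = {self.df_model}, "
            f"df_resid = {self.df_resid}, R^2 = {self.rsquared:.4f}",
            "",
            self.coef_table().to_string(float_format=lambda v: f"{v:.6g}"),
            "",
            self.anova().to_string(float_format=lambda v: f"{v:.6g}", na_rep=""),
        ]
        return "\n".join(lines)


class FallFrequencyModel:
    """Multivariable OLS of fall frequency on home-monitoring biomarkers."""

    def __init__(self, y: np.ndarray, X: np.ndarray, term_names: list[str]):
        """``X`` must already contain the intercept column (first)."""
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        n, p1 = X.shape
        if len(term_names) != p1:
            raise ValidationError("term_names must match design-matrix columns")
        if n <= p1:
            raise ValidationError(
                f"need more observations ({n}) than parameters ({p1})"
            )
        rank = np.linalg.matrix_rank(X)
        if rank < p1:
            # identify offending columns via the QR diagonal
            _, rr = np.linalg.qr(X)
            diag = np.abs(np.diag(rr))
            tol = diag.max() * max(X.shape) * np.finfo(float).eps
            bad = [term_names[j] for j in range(p1) if diag[j] < tol]
            raise CollinearityError(
                f"design matrix rank {rank} < {p1}; "
                f"offending columns: {bad or '(linearly dependent set)'}"
            )
        self.y = y
        self.X = X
        self.term_names = list(term_names)

    @classmethod
    def from_dataframe(
        cls,
        table: pd.DataFrame,
        terms: list[str] | None = None,
        outcome: str = "fall_freq",
    ) -> "FallFrequencyModel":
        """Build the model from a feature table, complete-case over terms."""
        terms = list(terms or DEFAULT_TERMS)
        missing = [c for c in terms + [outcome] if c not in table.columns]
        if missing:
            raise ValidationError(f"feature table lacks columns {missing}")
        sub = table[terms + [outcome]].dropna()
        y = sub[outcome].to_numpy()
        X = np.column_stack([np.ones(len(sub)), sub[terms].to_numpy()])
        return cls(y, X, ["Intercept"] + terms)

    def fit(self) -> FallFrequencyResults:
        res = sm.OLS(self.y, self.X).fit()
        names = self.term_names
        n, p1 = self.X.shape
        bse = np.asarray(res.bse, dtype=float)
        ssr = float(res.ssr)
        tss = float(res.centered_tss)
        if ssr <= 1e-12 * max(tss, 1.0):  # numerically perfect fit
            ssr = 0.0
            bse = np.zeros_like(bse)
        return FallFrequencyResults(
            params=pd.Series(res.params, index=names),
            bse=pd.Series(bse, index=names),
            tvalues=pd.Series(term_t_statistics(res.params, bse), index=names),
            pvalues=pd.Series(res.pvalues, index=names),
            ss_total=tss,
            ss_model=float(res.ess),
            ss_resid=ssr,
            df_model=int(res.df_model),
            df_resid=int(res.df_resid),
            nobs=n,
        )


def fit_ols(X: np.ndarray, y: np.ndarray, term_names: list[str] | None = None) -> FallFrequencyResults:
    """Fit OLS on a design matrix whose first column is the intercept."""
    X = np.asarray(X, dtype=float)
    if term_names is None:
        term_names = ["Intercept"] + [f"x{i}" for i in range(1, X.shape[1])]
    return FallFrequencyModel(y, X, term_names).fit()


def term_t_statistics(estimates: np.ndarray, ses: np.ndarray) -> np.ndarray:
    """Elementwise ``estimate / SE``; a zero SE yields NaN for that term."""
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if est.shape != se.shape:
        raise ValidationError("estimates and SEs must have the same length")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(se > 0, est / se, np.nan)


def anova_summary(fit: FallFrequencyResults) -> pd.DataFrame:
    """The ANOVA table of a fitted model (module-level alias)."""
    return fit.anova()
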