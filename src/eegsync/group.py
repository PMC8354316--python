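"""Group-level inference: outlier gates, normality-gated correlations with
Bonferroni control, and popularity regressions.

The analysis ladder for stimulus-level data:

1. Univariate outliers: a single pass removes values deviating more than
   3 SD from the full-sample mean.  Mahalanobis screening flags (never
   drops) multivariate outliers above a chi-square quantile.
2. Correlations: Shapiro–Wilk on each variable; Pearson only when both
   pass at α = 0.05, otherwise Kendall tau-b.  Family-wise control is
   Bonferroni (α/m; m = 8 for the group-level family, giving the 0.006
   per-test threshold after 3-decimal rounding of 0.00625).
3. Regression: OLS of streams on neural synchrony (plus optional single
   release / ratings / early streams).  Residual normality (Shapiro) and
   homoscedasticity (Breusch–Pagan) are checked; if either fails at
   α = 0.05 the outcome is natural-log transformed and the model refit.
   On the log scale a coefficient b is reported as the multiplicative
   effect exp(b + σ̂²/2) on the outcome mean per unit predictor.
4. Nested models are compared by a partial F test on residual sums of
   squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan


class AnalysisError(ValueError):
    pass


@dataclass
class OutlierReport:
    kept: np.ndarray
    kept_index: np.ndarray
    removed_index: np.ndarray
    mean: float
    sd: float
    threshold_sd: float

    def summary(self) -> str:
        return (
            f"removed {len(self.removed_index)} of "
            f"{len(self.kept) + len(self.removed_index)} values "
            f"(mean={self.mean:.3f}, sd={self.sd:.3f}, gate={self.threshold_sd} SD)"
        )


def remove_univariate_outliers(values, k: float = 3.0) -> OutlierReport:
    """Single-pass 3-SD gate: mean and SD come from the full input.

    With zero spread nothing is removed.  The pass is not iterated, so a
    second extreme value exposed only after the first removal stays in.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise AnalysisError("need a 1-D sample of at least 3 values")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        removed = np.empty(0, dtype=int)
    else:
        removed = np.flatnonzero(np.abs(x - mean) > k * sd)
    kept_idx = np.setdiff1d(np.arange(len(x)), removed)
    return OutlierReport(
        kept=x[kept_idx],
        kept_index=kept_idx,
        removed_index=removed,
        mean=mean,
        sd=sd,
        threshold_sd=k,
    )


def mahalanobis_screen(
    matrix, quantile: float = 0.975
) -> tuple[np.ndarray, np.ndarray]:
    """Flag rows whose squared Mahalanobis distance exceeds χ²_p(quantile).

    Screening only — flagged rows are reported for review, not dropped.
    Returns ``(flags, squared_distances)``.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise AnalysisError("matrix must be 2-D (observations × variables)")
    n, p = x.shape
    if n <= p:
        raise AnalysisError(f"need more observations ({n}) than variables ({p})")
    center = x.mean(axis=0)
    cov = np.cov(x, rowvar=False)
    cov = np.atleast_2d(cov)
    try:
        inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise AnalysisError(
            "singular covariance; drop collinear variables before screening"
        ) from exc
    d = x - center
    d2 = np.einsum("ij,jk,ik->i", d, inv, d)
    cut = stats.chi2.ppf(quantile, df=p)
    return d2 > cut, d2


@dataclass
class CorrelationReport:
    pair: str
    method: str               # 'pearson' | 'kendall'
    statistic: float
    p_value: float
    n: int
    bonferroni_alpha: float
    significant: bool
    shapiro_p_x: Optional[float] = None
    shapiro_p_y: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "pair": self.pair,
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n": self.n,
            "bonferroni_alpha": self.bonferroni_alpha,
            "significant": self.significant,
            "shapiro_p_x": self.shapiro_p_x,
            "shapiro_p_y": self.shapiro_p_y,
        }

    def summary(self) -> str:
        stat = "r" if self.method == "pearson" else "tau"
        return (
            f"{self.pair}: {stat}={self.statistic:.3f}, p={self.p_value:.3f} "
            f"(threshold {round(self.bonferroni_alpha, 3)}, "
            f"{'significant' if self.significant else 'n.s.'})"
        )


def bonferroni_threshold(alpha_family: float, m_tests: int) -> float:
    """Per-test significance level α/m (0.05/8 = 0.00625 → printed 0.006)."""
    if m_tests < 1:
        raise AnalysisError("m_tests must be >= 1")
    return alpha_family / m_tests


def gated_correlation(
    x,
    y,
    pair: str = "x~y",
    alpha_family: float = 0.05,
    m_tests: int = 8,
    normality_alpha: float = 0.05,
) -> CorrelationReport:
    """Shapiro-gated correlation: Pearson iff both variables look normal,
    Kendall tau-b otherwise; significance against the Bonferroni level."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AnalysisError("x and y must be paired 1-D samples")
    if len(x) < 4:
        raise AnalysisError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AnalysisError(f"{pair}: constant variable, correlation undefined")
    sw_x = stats.shapiro(x).pvalue
    sw_y = stats.shapiro(y).pvalue
    alpha = bonferroni_threshold(alpha_family, m_tests)
    if sw_x >= normality_alpha and sw_y >= normality_alpha:
        res = stats.pearsonr(x, y)
        method = "pearson"
    else:
        res = stats.kendalltau(x, y)  # tau-b: tie-corrected
        method = "kendall"
    stat, p = float(res.statistic), float(res.pvalue)
    return CorrelationReport(
        pair=pair,
        method=method,
        statistic=stat,
        p_value=p,
        n=len(x),
        bonferroni_alpha=alpha,
        significant=bool(p < alpha),
        shapiro_p_x=float(sw_x),
        shapiro_p_y=float(sw_y),
    )


@dataclass
class RegressionReport:
    outcome: str
    transform: str                       # 'none' | 'log'
    terms: tuple[str, ...]
    params: dict                         # term -> {'b', 'se', 'p'}
    adj_r2: float
    sigma2: float                        # residual variance (MSE)
    shapiro: tuple[float, float]         # (W, p) on residuals
    breusch_pagan: tuple[float, float]   # (LM stat, p)
    multipliers: dict                    # term -> interpreted effect
    n: int
    rss: float
    df_resid: float
    model_p: float
    aic: float
    row_index: tuple = ()
    untransformed_diagnostics: Optional[dict] = None

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "transform": self.transform,
            "terms": list(self.terms),
            "params": self.params,
            "adj_r2": self.adj_r2,
            "sigma2": self.sigma2,
            "shapiro": list(self.shapiro),
            "breusch_pagan": list(self.breusch_pagan),
            "multipliers": self.multipliers,
            "n": self.n,
            "model_p": self.model_p,
            "aic": self.aic,
            "untransformed_diagnostics": self.untransformed_diagnostics,
        }


def _fit_ols(y: np.ndarray, X: pd.DataFrame):
    design = sm.add_constant(X, has_constant="add")
    return sm.OLS(y, design).fit()


def _diagnostics(fit) -> tuple[tuple[float, float], tuple[float, float]]:
    resid = np.asarray(fit.resid)
    scale = float(np.std(fit.model.endog))
    # a numerically perfect fit leaves only float noise in the residuals;
    # no diagnostic can reject there
    if scale == 0 or np.max(np.abs(resid)) < 1e-10 * max(scale, 1.0):
        return (float("nan"), 1.0), (float("nan"), 1.0)
    sw = stats.shapiro(resid)
    bp = het_breuschpagan(resid, fit.model.exog)
    return (float(sw.statistic), float(sw.pvalue)), (float(bp[0]), float(bp[1]))


def fit_popularity_model(
    frame: pd.DataFrame,
    outcome: str,
    terms: Sequence[str],
    diagnostic_alpha: float = 0.05,
    force_transform: Optional[str] = None,
) -> RegressionReport:
    """OLS of an outcome on the given terms with assumption-gated log refit.

    ``frame`` is a stimulus-level table (e.g. from
    :func:`build_stimulus_frame`) with one row per stimulus.  When the
    untransformed fit fails residual normality (Shapiro) or
    homoscedasticity (Breusch–Pagan) at ``diagnostic_alpha``, the outcome
    is natural-log transformed and refit; coefficients on the log scale
    are additionally reported as multipliers exp(b + σ̂²/2).
    ``force_transform`` pins the transform (for nested comparisons).
    """
    terms = list(terms)
    data = frame[[outcome] + terms].dropna()
    if len(data) < len(terms) + 2:
        raise AnalysisError(
            f"{len(data)} rows cannot identify {len(terms)} terms + intercept"
        )
    X = data[terms].astype(float)
    if len(terms) > 1:
        rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X.to_numpy()]))
        if rank < len(terms) + 1:
            raise AnalysisError(f"perfectly collinear terms among {terms}")
    y_raw = data[outcome].to_numpy(dtype=float)

    def finish(fit, transform, untransformed_diag):
        sw, bp = _diagnostics(fit)
        sigma2 = float(fit.mse_resid)
        params, mult = {}, {}
        params["const"] = {
            "b": float(fit.params["const"]),
            "se": float(fit.bse["const"]),
            "p": float(fit.pvalues["const"]),
        }
        for term in terms:
            b = float(fit.params[term])
            params[term] = {
                "b": b,
                "se": float(fit.bse[term]),
                "p": float(fit.pvalues[term]),
            }
            mult[term] = float(np.exp(b + sigma2 / 2.0)) if transform == "log" else b
        return RegressionReport(
            outcome=outcome,
            transform=transform,
            terms=tuple(terms),
            params=params,
            adj_r2=float(fit.rsquared_adj),
            sigma2=sigma2,
            shapiro=sw,
            breusch_pagan=bp,
            multipliers=mult,
            n=int(fit.nobs),
            rss=float(fit.ssr),
            df_resid=float(fit.df_resid),
            model_p=float(fit.f_pvalue),
            aic=float(fit.aic),
            row_index=tuple(data.index),
            untransformed_diagnostics=untransformed_diag,
        )

    if force_transform == "log":
        if (y_raw <= 0).any():
            raise AnalysisError("log transform requires strictly positive outcomes")
        return finish(_fit_ols(np.log(y_raw), X), "log", None)
    if force_transform == "none":
        return finish(_fit_ols(y_raw, X), "none", None)

    fit0 = _fit_ols(y_raw, X)
    sw0, bp0 = _diagnostics(fit0)
    if sw0[1] < diagnostic_alpha or bp0[1] < diagnostic_alpha:
        if (y_raw <= 0).any():
            raise AnalysisError(
                "assumptions failed but outcome has non-positive values; "
                "cannot log transform"
            )
        diag = {"shapiro": list(sw0), "breusch_pagan": list(bp0)}
        return finish(_fit_ols(np.log(y_raw), X), "log", diag)
    return finish(fit0, "none", None)


def compare_nested(
    base: RegressionReport, extended: RegressionReport
) -> tuple[float, float]:
    """Partial F test on residual sums of squares of two nested OLS fits."""
    if base.outcome != extended.outcome or base.transform != extended.transform:
        raise AnalysisError("models must share outcome and transform")
    if base.row_index != extended.row_index:
        raise AnalysisError("models must be fit on the same rows")
    if not set(base.terms) < set(extended.terms):
        raise AnalysisError(
            f"base terms {base.terms} are not a strict subset of {extended.terms}"
        )
    df_num = base.df_resid - extended.df_resid
    if df_num <= 0:
        raise AnalysisError("extended model adds no parameters")
    num = (base.rss - extended.rss) / df_num
    den = extended.rss / extended.df_resid
    f_stat = max(num / den, 0.0)
    p = float(stats.f.sf(f_stat, df_num, extended.df_resid))
    return float(f_stat), p


def build_stimulus_frame(
    table,
    synchrony: Optional[pd.Series] = None,
    faa: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """One row per stimulus: outcomes, metadata and aggregated metrics.

    ``synchrony``/``faa`` are per-stimulus Series (e.g. from the metrics
    stage); ratings and engagement are averaged over subjects.
    """
    frame = table.meta.copy()
    frame["single"] = frame["single_flag"].astype(float)
    frame["ratings"] = table.ratings.mean(axis=0)
    if table.engagement is not None:
        frame["engagement"] = table.engagement.mean(axis=0)
    if synchrony is not None:
        frame["synchrony"] = synchrony
    if faa is not None:
        frame["faa"] = faa
    frame["early_streams"] = frame["streams_early"]
    return frame
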