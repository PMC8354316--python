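"""Individual-level inference: rank correlations with likeability, genre
binarization, and bidirectional stepwise model selection by AIC.

Likeability is the 1–5 star rating each subject gave each stimulus.
Because the scale is ordinal, Kendall tau-b is used throughout, with a
Bonferroni family of two tests (FAA, engagement), i.e. a 0.025 per-test
threshold.  The pooled individual-level model regresses ratings on
engagement, artist, single release (and optionally FAA / pop-fan flag),
selecting terms by bidirectional stepwise search that at each step takes
the single add/drop move with the largest AIC decrease.  Two outcome
families are provided: ``linear`` on the raw 1–5 score and ``logistic``
on ratings binarized at ≥ 4; separation in the logistic family falls
back to the linear family with a flag.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .containers import GENRES, StimulusTable, ValidationError
from .group import CorrelationReport, bonferroni_threshold

logger = logging.getLogger(__name__)


class SelectionError(ValueError):
    pass


def likeability_correlations(
    table: StimulusTable,
    metrics: dict[str, pd.DataFrame],
    alpha_family: float = 0.05,
    m_tests: int = 2,
) -> list[CorrelationReport]:
    """Kendall tau-b of each metric with ratings over all observations.

    ``metrics`` maps metric name to a wide (subject × stimulus) frame
    aligned with ``table.ratings``.
    """
    alpha = bonferroni_threshold(alpha_family, m_tests)
    reports = []
    for name, wide in metrics.items():
        aligned = wide.loc[table.ratings.index, table.ratings.columns]
        x = aligned.to_numpy(dtype=float).ravel()
        y = table.ratings.to_numpy(dtype=float).ravel()
        keep = ~np.isnan(x)
        x, y = x[keep], y[keep]
        if np.ptp(x) == 0:
            raise SelectionError(f"metric {name} is constant; tau undefined")
        res = stats.kendalltau(x, y)
        reports.append(
            CorrelationReport(
                pair=f"{name}~likeability",
                method="kendall",
                statistic=float(res.statistic),
                p_value=float(res.pvalue),
                n=len(x),
                bonferroni_alpha=alpha,
                significant=bool(res.pvalue < alpha),
            )
        )
    return reports


def binarize_genre(preferences, pop_label: str = "pop") -> pd.Series:
    """Per-subject boolean: is the favourite genre pop?

    ``preferences`` is either a Series of favourite-genre labels or a
    DataFrame of rank columns (``rank_1`` holds the favourite, and each
    row must be a permutation of the six genres).
    """
    if isinstance(preferences, pd.DataFrame):
        rank_cols = [c for c in preferences.columns if c.startswith("rank_")]
        if not rank_cols:
            raise ValidationError("rank frame needs rank_1..rank_k columns")
        for subj, row in preferences[rank_cols].iterrows():
            labels = [str(v).lower() for v in row]
            unknown = set(labels) - set(GENRES)
            if unknown:
                raise ValidationError(
                    f"subject {subj}: unknown genre labels {sorted(unknown)}"
                )
            if len(set(labels)) != len(labels):
                raise ValidationError(
                    f"subject {subj}: ranks must be a permutation of genres "
                    f"(duplicates in {labels})"
                )
        fav = preferences["rank_1"]
    else:
        fav = pd.Series(preferences)
        unknown = set(str(v).lower() for v in fav) - set(GENRES)
        if unknown:
            raise ValidationError(f"unknown genre labels {sorted(unknown)}")
    return fav.astype(str).str.lower().eq(pop_label).rename("pop_fan")


@dataclass
class StepwiseResult:
    terms: tuple[str, ...]
    params: dict                       # term (and 'const') -> coefficient
    pvalues: dict
    aic: float
    family: str                        # 'linear' | 'logistic'
    trace: list = field(default_factory=list)  # (action, term, aic) per step
    fell_back_to_linear: bool = False

    def to_dict(self) -> dict:
        return {
            "terms": list(self.terms),
            "params": self.params,
            "pvalues": self.pvalues,
            "aic": self.aic,
            "family": self.family,
            "trace": [list(step) for step in self.trace],
            "fell_back_to_linear": self.fell_back_to_linear,
        }


def build_observation_frame(
    table: StimulusTable,
    faa: Optional[pd.DataFrame] = None,
    pop_fan: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Pooled (subject, stimulus) frame with candidate predictors.

    Columns: rating, engagement, faa, artist (0/1 dummy for the second
    level), single, pop_fan — whichever inputs are available.
    """
    obs = table.long()
    levels = pd.unique(obs["artist"])
    if len(levels) == 2:
        obs["artist_dummy"] = (obs["artist"] == levels[1]).astype(float)
    obs["single"] = obs["single_flag"].astype(float)
    if faa is not None:
        f = (
            faa.stack()
            .rename("faa")
            .rename_axis(["subject_id", "stimulus_id"])
            .reset_index()
        )
        obs = obs.merge(f, on=["subject_id", "stimulus_id"], how="left")
    if pop_fan is not None:
        obs = obs.merge(
            pop_fan.astype(float).rename("pop_fan"),
            left_on="subject_id",
            right_index=True,
            how="left",
        )
    return obs


def _fit_family(y: np.ndarray, X: pd.DataFrame, family: str):
    design = sm.add_constant(X, has_constant="add")
    if family == "linear":
        return sm.OLS(y, design).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
        model = sm.Logit(y, design)
        return model.fit(disp=0)


def _aic(fit) -> float:
    return float(fit.aic)


def stepwise_aic(
    data: pd.DataFrame,
    outcome: str = "rating",
    candidates: Sequence[str] = ("engagement", "faa", "artist_dummy", "single", "pop_fan"),
    family: str = "linear",
    logistic_cut: float = 4.0,
) -> StepwiseResult:
    """Bidirectional stepwise selection from the intercept-only model.

    At each step every single-term addition and deletion is scored; the
    move with the largest AIC decrease is taken; the search stops when no
    move lowers AIC.  The full trace (action, term, AIC) is retained and
    the final AIC is, by construction, the minimum over all models
    visited.
    """
    candidates = [c for c in candidates if c in data.columns]
    if len(candidates) < 2:
        raise SelectionError("need at least two candidate terms present in data")
    cols = [outcome] + candidates
    work = data[cols].dropna()
    y = work[outcome].to_numpy(dtype=float)
    if family == "logistic":
        y = (y >= logistic_cut).astype(float)

    fell_back = False

    def fit_subset(subset, fam):
        X = work[list(subset)].astype(float)
        return _fit_family(y, X, fam)

    fam = family
    try:
        current_fit = fit_subset([], fam)
    except Exception:
        if fam == "logistic":
            logger.warning("logistic null fit failed; falling back to linear family")
            fam, fell_back = "linear", True
            y = work[outcome].to_numpy(dtype=float)
            current_fit = fit_subset([], fam)
        else:
            raise

    current: list[str] = []
    current_aic = _aic(current_fit)
    trace = [("start", "(intercept)", current_aic)]

    def essentially_perfect(fit) -> bool:
        # with RSS at float-noise level AIC differences are meaningless;
        # stop instead of chasing spurious additions
        return fam == "linear" and fit.ssr <= 1e-12 * max(
            float(np.var(y)) * len(y), 1.0
        )

    while not essentially_perfect(current_fit):
        moves = []
        for term in candidates:
            if term in current:
                moves.append(("drop", term, [t for t in current if t != term]))
            else:
                moves.append(("add", term, current + [term]))
        best = None
        for action, term, subset in moves:
            try:
                fit = fit_subset(subset, fam)
            except Exception as exc:
                if fam == "logistic":
                    logger.warning(
                        "logistic fit failed for %s (%s); falling back to linear",
                        subset,
                        exc,
                    )
                    res = stepwise_aic(
                        data, outcome=outcome, candidates=candidates, family="linear"
                    )
                    res.fell_back_to_linear = True
                    return res
                raise
            aic = _aic(fit)
            if best is None or aic < best[0]:
                best = (aic, action, term, subset, fit)
        if best is None or best[0] >= current_aic:
            break
        current_aic, action, term, current, current_fit = (
            best[0],
            best[1],
            best[2],
            best[3],
            best[4],
        )
        trace.append((action, term, current_aic))

    params = {k: float(v) for k, v in current_fit.params.items()}
    pvalues = {k: float(v) for k, v in current_fit.pvalues.items()}
    result = StepwiseResult(
        terms=tuple(current),
        params=params,
        pvalues=pvalues,
        aic=current_aic,
        family=fam,
        trace=trace,
        fell_back_to_linear=fell_back,
    )
    return result


def all_subsets_aic(
    data: pd.DataFrame,
    outcome: str = "rating",
    candidates: Sequence[str] = ("engagement", "faa", "artist_dummy", "single", "pop_fan"),
    family: str = "linear",
    logistic_cut: float = 4.0,
) -> tuple[tuple[str, ...], float]:
    """Exhaustive AIC minimisation over all 2^k candidate subsets.

    Exists as the exact reference the stepwise search is validated
    against; k is small (≤ 5) in this design.
    """
    candidates = [c for c in candidates if c in data.columns]
    work = data[[outcome] + candidates].dropna()
    y = work[outcome].to_numpy(dtype=float)
    if family == "logistic":
        y = (y >= logistic_cut).astype(float)
    best: tuple[tuple[str, ...], float] | None = None
    for r in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, r):
            fit = _fit_family(y, work[list(subset)].astype(float), family)
            aic = _aic(fit)
            if best is None or aic < best[1]:
                best = (subset, aic)
    assert best is not None
    return best
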