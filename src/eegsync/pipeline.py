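"""End-to-end orchestration: simulate → preprocess → PSD → metrics →
group analysis → individual analysis, with every gate decision logged
and all intermediate tables written out.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import group as grp
from . import individual as ind
from . import io as eio
from .containers import StimulusTable
from .metrics import SynchronyConfig, aggregate_faa, compute_faa, faa_frame, neural_synchrony
from .preprocess import PreprocessConfig, preprocess
from .simulate import StudyConfig, simulate_study
from .spectral import SpectralConfig, compute_band_power

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """Wraps a stage failure with the stage name for clean aborts."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc
        return wrapped
    return deco


@_stage("simulate")
def _run_simulate(cfg: dict):
    sim = dict(cfg.get("simulate", {}))
    sim["seed"] = cfg.get("seed", 0)
    study = StudyConfig(**sim)
    return study, *simulate_study(study)


@_stage("preprocess")
def _run_preprocess(recordings, cfg: dict):
    pp = PreprocessConfig(**cfg.get("preprocess", {}))
    return [preprocess(rec, pp) for rec in recordings]


@_stage("psd")
def _run_psd(recordings, cfg: dict):
    sp = SpectralConfig(**cfg.get("spectral", {}))
    return [compute_band_power(rec, sp) for rec in recordings]


@_stage("synchrony")
def _run_synchrony(band_powers, cfg: dict):
    sc_kwargs = dict(cfg.get("synchrony", {}))
    sc_kwargs["electrodes"] = tuple(sc_kwargs.get("electrodes", ("C3", "Cz", "C4")))
    sc = SynchronyConfig(**sc_kwargs)
    by_stim = defaultdict(list)
    for bp in band_powers:
        by_stim[bp.stimulus_id].append(bp)
    results = {}
    for stim, series in sorted(by_stim.items()):
        results[stim] = neural_synchrony(series, sc)
    return results


@_stage("faa")
def _run_faa(band_powers):
    return [compute_faa(bp) for bp in band_powers]


@_stage("group-analysis")
def _run_group(frame: pd.DataFrame, cfg: dict) -> dict:
    g = cfg.get("group", {})
    k_sd = g.get("outlier_sd", 3.0)
    alpha_family = g.get("alpha_family", 0.05)
    m_tests = g.get("m_tests", 8)
    normality_alpha = g.get("normality_alpha", 0.05)
    diag_alpha = g.get("diagnostic_alpha", 0.05)

    report: dict = {"outliers": {}, "correlations": [], "models": {}, "nested": {}}
    kept_rows = {}
    for outcome in ("streams_early", "streams_late"):
        rep = grp.remove_univariate_outliers(frame[outcome].to_numpy(), k=k_sd)
        kept_rows[outcome] = frame.index[rep.kept_index]
        report["outliers"][outcome] = {
            "removed_stimuli": list(frame.index[rep.removed_index]),
            "mean": rep.mean,
            "sd": rep.sd,
        }
        logger.info("outlier gate on %s: %s", outcome, rep.summary())

    predictors = [
        c for c in ("ratings", "synchrony", "faa", "engagement") if c in frame
    ]
    screen_cols = predictors + ["streams_early", "streams_late"]
    flags, d2 = grp.mahalanobis_screen(frame[screen_cols].to_numpy())
    report["mahalanobis_flagged"] = list(frame.index[flags])
    if flags.any():
        logger.info("Mahalanobis screen flagged: %s", list(frame.index[flags]))

    for outcome in ("streams_early", "streams_late"):
        sub = frame.loc[kept_rows[outcome]]
        for pred in predictors:
            rep = grp.gated_correlation(
                sub[pred],
                sub[outcome],
                pair=f"{pred}~{outcome}",
                alpha_family=alpha_family,
                m_tests=m_tests,
                normality_alpha=normality_alpha,
            )
            logger.info("correlation %s", rep.summary())
            report["correlations"].append(rep.to_dict())

    models = {}
    for outcome in ("streams_early", "streams_late"):
        sub = frame.loc[kept_rows[outcome]]
        base = grp.fit_popularity_model(
            sub, outcome, ["synchrony"], diagnostic_alpha=diag_alpha
        )
        logger.info(
            "model %s ~ synchrony: transform=%s adjR2=%.3f",
            outcome,
            base.transform,
            base.adj_r2,
        )
        models[f"{outcome}~synchrony"] = base
        ext = grp.fit_popularity_model(
            sub,
            outcome,
            ["synchrony", "single"],
            diagnostic_alpha=diag_alpha,
            force_transform=base.transform,
        )
        models[f"{outcome}~synchrony+single"] = ext
        f_stat, p = grp.compare_nested(base, ext)
        report["nested"][f"{outcome}: +single"] = {"F": f_stat, "p": p}
        logger.info("nested test %s +single: F=%.3f p=%.4f", outcome, f_stat, p)
    report["models"] = {k: m.to_dict() for k, m in models.items()}
    return report, models, kept_rows


@_stage("individual-analysis")
def _run_individual(table: StimulusTable, faa_wide: pd.DataFrame, cfg: dict) -> dict:
    icfg = cfg.get("individual", {})
    metrics = {"faa": faa_wide}
    if table.engagement is not None:
        metrics["engagement"] = table.engagement
    corrs = ind.likeability_correlations(
        table,
        metrics,
        alpha_family=icfg.get("alpha_family", 0.05),
        m_tests=icfg.get("m_tests", 2),
    )
    for rep in corrs:
        logger.info("individual correlation %s", rep.summary())
    pop_fan = None
    if table.genre_ranks is not None:
        pop_fan = ind.binarize_genre(table.genre_ranks)
    elif table.genre_favorite is not None:
        pop_fan = ind.binarize_genre(table.genre_favorite)
    obs = ind.build_observation_frame(table, faa=faa_wide, pop_fan=pop_fan)
    step = ind.stepwise_aic(
        obs,
        outcome="rating",
        family=icfg.get("family", "linear"),
        logistic_cut=icfg.get("logistic_cut", 4.0),
    )
    logger.info(
        "stepwise (%s family) selected %s, AIC=%.2f", step.family, step.terms, step.aic
    )
    return {
        "correlations": [c.to_dict() for c in corrs],
        "stepwise": step.to_dict(),
        "n_pop_fans": int(pop_fan.sum()) if pop_fan is not None else None,
    }


def _plot_models(frame, models, kept_rows, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for name, model in models.items():
        if "synchrony" not in model.terms:
            continue
        sub = frame.loc[list(model.row_index)]
        y = sub[model.outcome].to_numpy(dtype=float)
        if model.transform == "log":
            y = np.log(y)
        x = sub["synchrony"].to_numpy(dtype=float)
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(x, y, c="k", s=20)
        b = model.params["synchrony"]["b"]
        const = model.params["const"]["b"]
        # partial fit: other terms held at their sample means
        other = sum(
            model.params[t]["b"] * sub[t].astype(float).mean()
            for t in model.terms
            if t != "synchrony"
        )
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, const + other + b * xs, color="tab:blue")
        ax.set_xlabel("neural synchrony")
        label = model.outcome + (" (ln)" if model.transform == "log" else "")
        ax.set_ylabel(label)
        ax.set_title(name)
        fig.tight_layout()
        fig.savefig(outdir / f"model_{name.replace('~', '_').replace('+', '_')}.png", dpi=100)
        plt.close(fig)


def run_all(cfg: dict, write_eeg_csv: bool = False, make_plots: bool = True) -> dict:
    """Run the full pipeline; returns the report bundle.

    All tables and JSON reports are written under ``cfg['outdir']``.
    ``write_eeg_csv`` additionally dumps the (large) long-format EEG CSV.
    """
    outdir = Path(cfg.get("outdir", "eegsync_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.get("log_level", "INFO"))

    study, recordings, truth, table = _run_simulate(cfg)
    eio.write_tables(table, outdir)
    eio.write_ground_truth(truth, outdir / "ground_truth.json")
    if write_eeg_csv:
        eio.write_recordings(recordings, outdir / "eeg_long.csv")

    clean = _run_preprocess(recordings, cfg)
    band_powers = _run_psd(clean, cfg)

    synchrony = _run_synchrony(band_powers, cfg)
    synch_series = pd.Series(
        {k: v.synchrony for k, v in synchrony.items()}, name="synchrony"
    )
    pd.DataFrame(
        {
            "stimulus_id": list(synchrony),
            "synchrony": [synchrony[k].synchrony for k in synchrony],
            "n_valid_frames": [synchrony[k].n_valid_frames for k in synchrony],
            "n_skipped_pair_frames": [
                synchrony[k].n_skipped_pair_frames for k in synchrony
            ],
        }
    ).to_csv(outdir / "synchrony.csv", index=False)

    faa_results = _run_faa(band_powers)
    faa_wide = faa_frame(faa_results)
    faa_group = aggregate_faa(faa_results)
    faa_wide.to_csv(outdir / "faa.csv")

    frame = grp.build_stimulus_frame(table, synchrony=synch_series, faa=faa_group)
    frame.to_csv(outdir / "stimulus_frame.csv")

    group_report, models, kept_rows = _run_group(frame, cfg)
    individual_report = _run_individual(table, faa_wide, cfg)

    bundle = {
        "seed": cfg.get("seed", 0),
        "n_subjects": study.n_subjects,
        "n_stimuli": study.n_stimuli,
        "group": group_report,
        "individual": individual_report,
        "synchrony": {k: v.synchrony for k, v in synchrony.items()},
        "faa_group": faa_group.to_dict(),
    }
    (outdir / "report.json").write_text(json.dumps(bundle, indent=1, sort_keys=True))
    if make_plots:
        try:
            _plot_models(frame, models, kept_rows, outdir)
        except Exception as exc:  # plotting must never sink the run
            logger.warning("plotting failed: %s", exc)
    return bundle
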