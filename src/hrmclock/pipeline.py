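"""End-to-end orchestration: melt curves -> Df -> methylation -> clock -> deviations.

``run_pipeline`` executes the full chain on one cohort's melt data, writing
every intermediate table to the output directory so each stage is auditable:

    df_table.csv              per-well Df values
    standard_series.csv       per-plate standard (level, Df) pairs
    calibration.csv           fitted a / Df_max per marker x plate
    methylation.csv           per-sample methylation percentages
    correlations.csv          per-marker Pearson r vs age
    predictions_loocv.csv     held-out age predictions
    deviation_coefficients.csv / deviation_ranking.csv
    clock_model.json          the serialized clock
    summary.json              MAD, hyperparameters, resolved config
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import calibration as cal
from . import clock as ck
from . import deviation as dev
from .config import PipelineConfig
from .melt import MeltCurve, process_plate

logger = logging.getLogger("hrmclock")

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """All tables produced by one pipeline run."""

    df_table: pd.DataFrame
    standard_series: pd.DataFrame
    calibration: pd.DataFrame
    fits: dict
    methylation: pd.DataFrame | None = None
    correlations: pd.DataFrame | None = None
    predictions: pd.DataFrame | None = None
    mad_years: float | None = None
    hyperparams: dict = field(default_factory=dict)
    deviation_coefficients: pd.DataFrame | None = None
    deviation_ranking: pd.DataFrame | None = None
    clock_model: ck.ClockModel | None = None


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(
    config: PipelineConfig,
    curves: list[MeltCurve],
    sample_sheet: pd.DataFrame,
    outdir,
) -> PipelineResult:
    """Run process -> calibrate -> quantify -> correlate -> tune -> LOOCV -> deviations.

    A standards-only plate stops cleanly after calibration.  All randomness
    (tuning folds) derives from ``config.seed``, so a rerun with the same
    inputs reproduces every output file byte-for-byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.dump(outdir / "resolved_config.yaml")

    current = {"stage": "setup"}

    def stage(name: str):
        current["stage"] = name
        logger.info("stage: %s", name)

    try:
        stage("melt processing")
        df_table, standards = process_plate(
            curves, sample_sheet, config.windows_objects,
            mode=config.mode, smooth_window=config.smooth_window,
        )
        _write(df_table, outdir / "df_table.csv")
        _write(standards, outdir / "standard_series.csv")

        stage("calibration")
        fits = {}
        cal_rows = []
        for (marker, plate), _ in standards.groupby(["marker_id", "plate_id"]):
            series = cal.StandardSeries.from_dataframe(standards, marker, plate)
            fit = cal.fit_standard_curve(series)
            fits[(marker, plate)] = fit
            cal_rows.append(
                {
                    "marker_id": marker, "plate_id": plate, "a": fit.a,
                    "df_max": fit.df_max, "rss": fit.residual_sum_squares,
                    "n_points": fit.n_points,
                }
            )
        calibration_table = pd.DataFrame(cal_rows)
        _write(calibration_table, outdir / "calibration.csv")
        result = PipelineResult(df_table, standards, calibration_table, fits)
        if df_table.empty:
            logger.info("standards-only input: stopping after calibration")
            (outdir / "summary.json").write_text(
                json.dumps({"status": "standards-only: stopped after calibration"}, indent=1)
            )
            return result

        stage("quantification")
        meth = cal.quantify_samples(df_table, fits, config.replicate_policy)
        _write(meth, outdir / "methylation.csv")
        result.methylation = meth

        stage("correlation screening")
        is_sample = pd.to_numeric(sample_sheet["standard_level"], errors="coerce").isna()
        samples = (
            sample_sheet[is_sample][["sample_id", "sex", "age_years", "health"]]
            .drop_duplicates("sample_id")
            .set_index("sample_id")
        )
        wide = meth.pivot(index="sample_id", columns="marker_id", values="methylation_percent")
        wide = wide.loc[samples.index.intersection(wide.index)]
        meta = samples.loc[wide.index]
        ages = meta["age_years"].astype(float)
        correlations = ck.age_correlation(wide, ages)
        _write(correlations, outdir / "correlations.csv")
        result.correlations = correlations

        stage("hyperparameter tuning")
        folds = min(config.tune_folds, len(wide))
        cost, epsilon = ck.tune_clock(
            wide, ages, config.cost_grid, config.epsilon_grid,
            cv_folds=folds, seed=config.seed, gamma=config.gamma,
        )
        result.hyperparams = {"cost": cost, "epsilon": epsilon, "gamma": config.gamma}

        stage("clock fit + LOOCV")
        model = ck.fit_clock(
            wide, ages, cost, epsilon, gamma=config.gamma, species=config.species
        )
        ck.save_clock(model, outdir / "clock_model.json")
        result.clock_model = model
        preds = ck.loocv(
            wide, ages, cost, epsilon, gamma=config.gamma,
            sample_ids=wide.index,
            retune_in_fold=(config.loocv_variant == "tune-in-fold"),
            cost_grid=config.cost_grid, epsilon_grid=config.epsilon_grid,
            tune_folds=folds, seed=config.seed,
        )
        preds = ck.relative_age_transform(preds, model.oldest_training_age)
        _write(preds, outdir / "predictions_loocv.csv")
        result.predictions = preds
        result.mad_years = ck.mad(preds)

        stage("deviation analysis")
        devdata = preds.merge(
            meta.reset_index()[["sample_id", "sex", "health", "age_years"]], on="sample_id"
        ).rename(columns={"age_years": "age"})
        best, ranking = dev.select_model(devdata)
        _write(best.coefficients, outdir / "deviation_coefficients.csv")
        _write(ranking, outdir / "deviation_ranking.csv")
        result.deviation_coefficients = best.coefficients
        result.deviation_ranking = ranking

        summary = {
            "n_samples": int(len(wide)),
            "markers": list(wide.columns),
            "mad_years": result.mad_years,
            "hyperparameters": result.hyperparams,
            "loocv_variant": config.loocv_variant,
            "seed": config.seed,
            "best_deviation_model": list(best.covariates),
            "deviation_r_squared": best.r_squared,
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        return result
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{current['stage']}' failed: {err}") from err
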