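"""End-to-end orchestration of the morphology and ocean analyses.

`run_morphology_pipeline` sequences quality filtering -> pixel-to-meter
conversion -> platform error calibration -> per-whale posterior
summaries -> Monte Carlo ANOVA + allometry + Dixon's Q screen, writing a
population-contrast table (pairwise differences with HPDIs and
significance stars), an allometry table, and a machine-readable run
manifest.  `run_ocean_pipeline` computes per-region cumulative forcing
curves, climatological means, 50/80% accumulation windows, a monthly
chlorophyll-a climatology and the salinity-chlorophyll correlation, and
renders a three-panel-per-region summary figure.

Both entry points are plain functions over a `RunConfig`; the numbered
scripts under ``analysis/`` are thin drivers around them.
"""

from __future__ import annotations

import json
import platform as _platform
import warnings
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__, inference, ocean, photogrammetry, uncertainty


class PipelineStageError(RuntimeError):
    """An analysis stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[stage: {stage}] {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Run-wide options; defaults mirror the published analysis choices."""

    out_dir: Path = Path("results")
    seed: int = 0
    n_reps: int = 1_000_000
    hpdi_prob: float = 0.95
    bai_range: tuple[float, float] = (0.20, 0.90)
    max_images_per_whale: int = 5
    window_fractions: tuple[float, ...] = (0.5, 0.8)
    posterior_draws: int = 2000
    measurements: tuple[str, ...] = (
        "TL", "BAI", "EE_std", "JL_std", "RB_std", "Fs_std", "Fw", "Tail_std",
    )
    dixon_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        cfg.out_dir = Path(cfg.out_dir)
        return cfg


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - labeled re-raise
            raise PipelineStageError(name, exc) from exc

    return wrap


def run_morphology_pipeline(
    records: list[photogrammetry.MorphoRecord],
    calibrations: list[uncertainty.CalibrationObservation],
    config: RunConfig = RunConfig(),
) -> dict:
    """Filter, calibrate, propagate, and compare; write result bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    retained, audit = _stage("filter")(
        photogrammetry.filter_records, records, config.max_images_per_whale
    )
    audit.to_csv(out / "filter_audit.csv", index=False)

    posteriors_by_platform = _stage("calibration")(
        uncertainty.fit_error_model, calibrations, seed=config.seed
    )

    def _posteriors():
        per_image: dict[tuple[str, str], list[uncertainty.MeasurementPosterior]] = {}
        for i, rec in enumerate(retained):
            morph = photogrammetry.to_metric(rec, config.bai_range)
            plat = rec.flight.platform_id
            if plat not in posteriors_by_platform:
                raise uncertainty.MissingCalibration(f"no calibration for platform {plat!r}")
            for mp in uncertainty.posterior_predict_morphology(
                morph,
                posteriors_by_platform[plat],
                n_draws=config.posterior_draws,
                seed=config.seed + 1000 + i,
                head_tail_range=config.bai_range,
            ):
                per_image.setdefault((mp.whale_id, mp.measurement), []).append(mp)
        return [
            uncertainty.combine_image_posteriors(group) for group in per_image.values()
        ]

    whale_posteriors = _stage("posteriors")(_posteriors)
    post_df = uncertainty.posterior_table(whale_posteriors)
    post_df.to_csv(out / "whale_posteriors.csv", index=False)

    def _compare():
        results, rows = {}, []
        for k, meas in enumerate(config.measurements):
            sub = post_df[post_df["measurement"] == meas]
            if sub.empty:
                continue
            res = inference.mc_anova(
                sub,
                measurement=meas,
                config=inference.MCAnovaConfig(
                    n_reps=config.n_reps, hpdi_prob=config.hpdi_prob,
                    seed=config.seed + 2000 + k,
                ),
            )
            results[meas] = res
            for row in res.contrasts.itertuples():
                rows.append(
                    {
                        "measurement": meas,
                        "pair": row.pair,
                        "difference": row.difference,
                        "hpdi_low": row.hpdi_low,
                        "hpdi_high": row.hpdi_high,
                        "significant": "*" if row.significant else "",
                    }
                )
        return results, pd.DataFrame(rows)

    anova_results, contrast_table = _stage("mc_anova")(_compare)
    contrast_table.to_csv(out / "population_contrasts.csv", index=False)

    def _allometry():
        wide = post_df.pivot_table(
            index=["whale_id", "population"], columns="measurement",
            values="posterior_mean",
        ).reset_index()
        rows = []
        for pop, grp in wide.groupby("population"):
            for meas in ("RB", "JL", "EE", "Tail", "Fs", "Fw"):
                if meas not in grp or grp[meas].isna().any() or len(grp) < 3:
                    continue
                vals = grp[meas].to_numpy(float)
                dx = inference.dixon_q(vals, alpha=config.dixon_alpha) if 3 <= len(vals) <= 30 else None
                if dx is not None and dx.any_outlier:
                    warnings.warn(f"Dixon's Q flags an outlier in {pop}/{meas}", stacklevel=2)
                fit = inference.allometry_fit(
                    vals, grp["TL"].to_numpy(float), measurement=meas, population=pop
                )
                rows.append(
                    {
                        "population": pop,
                        "measurement": meas,
                        "slope": fit.slope,
                        "intercept": fit.intercept,
                        "slope_ci_low": fit.slope_ci[0],
                        "slope_ci_high": fit.slope_ci[1],
                        "classification": fit.classification,
                        "n": fit.n,
                        "dixon_outlier": bool(dx.any_outlier) if dx else False,
                    }
                )
        return pd.DataFrame(rows)

    allometry_table = _stage("allometry")(_allometry)
    allometry_table.to_csv(out / "allometry.csv", index=False)

    manifest = {
        "stages": ["filter", "calibration", "posteriors", "mc_anova", "allometry"],
        "seed": config.seed,
        "n_reps": config.n_reps,
        "hpdi_prob": config.hpdi_prob,
        "bai_range": list(config.bai_range),
        "n_records_in": len(records),
        "n_records_retained": len(retained),
        "n_whales": int(post_df["whale_id"].nunique()),
        "platforms": sorted(posteriors_by_platform),
        "version": __version__,
        "python": _platform.python_version(),
        "outputs": [
            "filter_audit.csv", "whale_posteriors.csv",
            "population_contrasts.csv", "allometry.csv",
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "posteriors": post_df,
        "anova": anova_results,
        "contrasts": contrast_table,
        "allometry": allometry_table,
        "manifest": manifest,
    }


def run_ocean_pipeline(
    forcing: dict[str, ocean.DailySeries],
    config: RunConfig = RunConfig(),
    chlorophyll: dict[str, pd.Series] | None = None,
    salinity_chl: tuple[pd.Series, pd.Series] | None = None,
    make_figure: bool = True,
) -> dict:
    """Seasonality characterization per region; write result bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    window_rows, curves_by_region, clim_by_region = [], {}, {}
    for region, series in forcing.items():
        curves, excluded = _stage("season_split")(ocean.season_year_split, series)
        if excluded:
            warnings.warn(f"{region}: excluded season years {excluded}", stacklevel=2)
        clim = _stage("climatology")(ocean.climatological_mean, curves)
        curves_by_region[region] = curves
        clim_by_region[region] = clim
        for frac in config.window_fractions:
            win = _stage("window")(ocean.accumulation_window, clim, frac)
            window_rows.append(
                {
                    "region": region,
                    "fraction": frac,
                    "start_day": win.start_day,
                    "end_day": win.end_day,
                    "length_days": win.length_days,
                    "n_years": len(curves),
                }
            )
        pd.DataFrame(
            {f"y{c.season_year}": c.cumulative for c in curves.values()}
            | {"climatological_mean": clim}
        ).to_csv(out / f"cumulative_{region}.csv", index_label="day")
    windows = pd.DataFrame(window_rows)
    windows.to_csv(out / "accumulation_windows.csv", index=False)

    chl_clim = {}
    if chlorophyll:
        for region, series in chlorophyll.items():
            clim = _stage("chl_climatology")(ocean.monthly_climatology, series)
            chl_clim[region] = clim
        pd.DataFrame({r: c.monthly_mean for r, c in chl_clim.items()}).to_csv(
            out / "chl_climatology.csv", index_label="month"
        )

    corr = None
    if salinity_chl is not None:
        corr = _stage("sss_chl_correlation")(
            ocean.salinity_chl_correlation, salinity_chl[0], salinity_chl[1]
        )
        (out / "sss_chl_correlation.json").write_text(
            json.dumps({"pearson_r": corr[0], "p_value": corr[1]})
        )

    if make_figure:
        _stage("figure")(
            _ocean_figure, curves_by_region, clim_by_region, windows, chl_clim,
            out / "ocean_seasonality.png",
        )

    manifest = {
        "stages": ["season_split", "climatology", "window"]
        + (["chl_climatology"] if chlorophyll else [])
        + (["sss_chl_correlation"] if salinity_chl else []),
        "regions": sorted(forcing),
        "window_fractions": list(config.window_fractions),
        "version": __version__,
        "outputs": sorted(p.name for p in out.glob("*") if p.is_file()),
    }
    (out / "ocean_manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "windows": windows,
        "climatologies": clim_by_region,
        "chl_climatology": chl_clim,
        "sss_chl_correlation": corr,
        "manifest": manifest,
    }


def _ocean_figure(curves_by_region, clim_by_region, windows, chl_clim, path):
    regions = sorted(clim_by_region)
    ncols = 2 if chl_clim else 1
    fig, axes = plt.subplots(
        len(regions), ncols, figsize=(5 * ncols, 2.6 * len(regions)),
        squeeze=False,
    )
    for i, region in enumerate(regions):
        ax = axes[i][0]
        for c in curves_by_region[region].values():
            ax.plot(np.arange(1, 366), c.cumulative, color="0.7", lw=0.6, ls=":")
        ax.plot(np.arange(1, 366), clim_by_region[region], color="k", lw=1.5)
        sub = windows[windows["region"] == region]
        shades = {0.5: "0.45", 0.8: "0.8", 0.9: "0.85"}
        for row in sub.itertuples():
            ax.axvspan(row.start_day, row.end_day,
                       color=shades.get(row.fraction, "0.8"), alpha=0.4)
        ax.set_ylabel(region)
        ax.set_xlim(1, 365)
        if chl_clim and region in chl_clim:
            ax2 = axes[i][1]
            clim = chl_clim[region]
            ax2.plot(clim.per_year.index, clim.per_year.to_numpy(), color="0.7", lw=0.6, ls=":")
            ax2.plot(clim.per_year.index, clim.monthly_mean, color="k", lw=1.5)
            ax2.set_xlim(1, 12)
    axes[-1][0].set_xlabel("day of season year")
    if ncols == 2:
        axes[-1][1].set_xlabel("month")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
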