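"""Pipeline orchestration, report formatting and the plain-text fit artifact.

`run_pipeline` ties the stages together -- simulate (or read) profiles,
monthly reduction, the prewhitened cross-correlation grid, the seasonal
persistence analysis, the indicator regressions with LOOCV, and an
optional forecast -- writing delimited tables, fixed-field report tables
(4 significant digits), plain-text fit artifacts and a line-oriented run
log into one output directory.  Identical configuration and seed produce
byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import indicator as ind
from .profiles import (CANONICAL_LEVELS, DensityLevel, DepthLayer, ProfileSeries,
                       isopycnal_series, monthly_mean, read_profiles)
from .prewhiten import xcorr_matrix
from .regression import LoocvResult, RegressionFit
from .season import build_season_records, decline_fraction, fit_season_regression
from .simulate import SimulationConfig, simulate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings of one reproducible pipeline run.

    Defaults mirror the reference configuration: indicator at 33 m,
    oxygen layers 50-70 and 70-95 m, density levels 1009/1011/1013 kg/m3,
    alpha 0.05, AR order cap 5, squared-error LOOCV metric and a 68%
    mean-response forecast interval.
    """

    input_upstream: str | None = None
    input_downstream: str | None = None
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    year_start: int | None = None
    year_end: int | None = None
    indicator_depth: float = 33.0
    layers: tuple = ((50.0, 70.0), (70.0, 95.0))
    density_levels: tuple = (1009.0, 1011.0, 1013.0)
    alpha: float = 0.05
    ar_max_order: int = 5
    min_oxygen_depth: float = 50.0
    loocv_metric: str = "mse"
    uncertainty_level: float = 0.68
    forecast_salinity: float | None = None
    outdir: str = "inflowcast_run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and not np.isfinite(v)):
        return "--"
    if isinstance(v, float):
        return f"{v:.4g}"
    return str(v)


def _fmt_p(p: float) -> str:
    if not np.isfinite(p):
        return "--"
    return "<0.0001" if p < 1e-4 else f"{p:.4g}"


def format_fit_table(fit: RegressionFit, cv: LoocvResult | None = None) -> str:
    """Fixed-field report table for one regression (4 significant digits),
    with an optional cross-validation block."""
    lines = [
        f"Response: {fit.response or '(unnamed)'}",
        "Rsqr\tAdj Rsqr\tStd. error residuals\tF\tp\td.f.",
        "\t".join([_fmt(fit.r2), _fmt(fit.adj_r2), _fmt(fit.resid_se),
                   _fmt(fit.fstat), _fmt_p(fit.f_p), str(fit.df_resid)]),
        "Parameter\tCoefficient\tStd. Error\tt\tp",
        "\t".join(["y_0", _fmt(fit.intercept), _fmt(fit.se_intercept),
                   _fmt(fit.t_intercept), _fmt_p(fit.p_intercept)]),
        "\t".join(["slope", _fmt(fit.slope), _fmt(fit.se_slope),
                   _fmt(fit.t_slope), _fmt_p(fit.p_slope)]),
    ]
    if cv is not None:
        lines += [
            f"Cross validation results (error metric: {cv.metric})",
            "Mean Rsqr\tStd. deviation\tMean training error\t95% conf. int."
            "\tMean test error\t95% conf. int.",
            "\t".join([_fmt(cv.mean_r2), _fmt(cv.r2_sd), _fmt(cv.mean_train_error),
                       _fmt(cv.train_error_interval), _fmt(cv.mean_test_error),
                       _fmt(cv.test_error_interval)]),
        ]
    if fit.excluded:
        lines.append("Excluded years: "
                     + "; ".join(f"{y} ({reason})" for y, reason in fit.excluded))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# fit artifact (plain-text key-value record)
# ---------------------------------------------------------------------------

_ARTIFACT_SCALARS = ("response", "intercept", "slope", "se_intercept", "se_slope",
                     "t_intercept", "t_slope", "p_intercept", "p_slope", "r2",
                     "adj_r2", "resid_se", "fstat", "f_p", "df_resid", "n")


def save_fit_artifact(fit: RegressionFit, path) -> None:
    """Serialize a fit (full precision, including training data) as an
    auditable ``key: value`` text record."""
    lines = []
    for k in _ARTIFACT_SCALARS:
        lines.append(f"{k}: {getattr(fit, k)!r}")
    if fit.x is not None:
        lines.append("x: " + ",".join(repr(float(v)) for v in fit.x))
        lines.append("y: " + ",".join(repr(float(v)) for v in fit.y))
    Path(path).write_text("\n".join(lines) + "\n")


def load_fit_artifact(path) -> RegressionFit:
    raw = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        k, _, v = line.partition(":")
        raw[k.strip()] = v.strip()
    kwargs = {}
    for k in _ARTIFACT_SCALARS:
        if k not in raw:
            continue
        if k == "response":
            kwargs[k] = raw[k].strip("'\"")
        elif k in ("df_resid", "n"):
            kwargs[k] = int(raw[k])
        else:
            kwargs[k] = float(raw[k])
    for k in ("x", "y"):
        if k in raw:
            kwargs[k] = np.array([float(v) for v in raw[k].split(",")])
    return RegressionFit(**kwargs)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _obtain_profiles(config: RunConfig) -> tuple[ProfileSeries, ProfileSeries]:
    if config.input_upstream or config.input_downstream:
        if not (config.input_upstream and config.input_downstream):
            raise FileNotFoundError("both input_upstream and input_downstream are needed")
        for p in (config.input_upstream, config.input_downstream):
            if not Path(p).exists():
                raise FileNotFoundError(f"input path does not exist: {p}")
        return (read_profiles(config.input_upstream, region="upstream"),
                read_profiles(config.input_downstream, region="downstream"))
    sim = SimulationConfig(**{"seed": config.seed, **config.simulation})
    return simulate(sim)


def _restrict_years(ps: ProfileSeries, y0: int | None, y1: int | None) -> ProfileSeries:
    if y0 is None and y1 is None:
        return ps
    years = ps.times.year
    sel = np.ones(years.size, dtype=bool)
    if y0 is not None:
        sel &= years >= y0
    if y1 is not None:
        sel &= years <= y1
    return ProfileSeries(ps.data.isel(time=np.flatnonzero(sel)), region=ps.region)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a bundle of results and paths.

    On any stage failure the partially written outputs are removed and the
    error is re-raised naming the failed stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log_lines: list[str] = [f"# inflowcast run ({datetime.datetime.now().isoformat()})"]
    for f in dataclasses.fields(config):
        log_lines.append(f"setting {f.name} = {getattr(config, f.name)!r}")

    def _write(name: str, text: str) -> Path:
        p = outdir / name
        p.write_text(text)
        written.append(p)
        return p

    stage = "input"
    try:
        up, down = _obtain_profiles(config)
        up = _restrict_years(up, config.year_start, config.year_end)
        down = _restrict_years(down, config.year_start, config.year_end)

        stage = "reduce"
        up_m, down_m = monthly_mean(up), monthly_mean(down)
        for name, ps in (("upstream", up_m), ("downstream", down_m)):
            n_masked = int(sum(np.isnan(ps.data[v].values).sum() for v in ps.variables()))
            log_lines.append(f"reduce {name}: {ps.times.size} months x "
                             f"{ps.depths.size} depths, {n_masked} masked cells")

        stage = "xcorr"
        grid = xcorr_matrix(up_m, down_m, salinity_depth=config.indicator_depth,
                            min_oxygen_depth=config.min_oxygen_depth,
                            alpha=config.alpha, max_order=config.ar_max_order)
        _write("xcorr.tsv", grid.to_frame().to_csv(sep="\t", index=False))

        stage = "season"
        age = {lv.target: lv.age_class for lv in CANONICAL_LEVELS}
        levels = [DensityLevel(float(t), age.get(float(t), "")) for t in config.density_levels]
        iso = {lv.target: isopycnal_series(down_m, lv, "oxygen") for lv in levels}
        records = build_season_records(iso)
        _write("season_records.tsv", records.to_csv(sep="\t", index=False))
        frac, n_dec, n_valid = decline_fraction(records)
        log_lines.append(f"season: August below April in {n_dec}/{n_valid} cases "
                         f"({100 * frac:.1f}%)")
        season_text = [f"April->August declines: {n_dec}/{n_valid} ({100 * frac:.1f}%)\n"]
        for lv in levels:
            try:
                sfit = fit_season_regression(records, lv.target)
                season_text.append(f"== Density level {lv.target:g} kg/m3 "
                                   f"({lv.age_class}) ==\n" + format_fit_table(sfit))
                for y, reason in sfit.excluded:
                    log_lines.append(f"season exclusion level={lv.target:g} year={y}: {reason}")
            except ValueError as e:
                season_text.append(f"== Density level {lv.target:g} kg/m3: not fitted "
                                   f"({e}) ==\n")
                log_lines.append(f"season level={lv.target:g} not fitted: {e}")
        _write("season_fits.txt", "\n".join(season_text))

        stage = "fit"
        layers = tuple(DepthLayer(a, b) for a, b in config.layers)
        dataset = ind.build_indicator_dataset(
            up_m, down_m, salinity_depth=config.indicator_depth,
            layers=layers, levels=tuple(levels))
        _write("indicator_dataset.tsv", dataset.to_csv(sep="\t", index=False))
        responses = [c for c in dataset.columns if c.startswith(("oxy_", "surv_"))]
        fit_text = []
        fits: dict[str, RegressionFit] = {}
        for resp in responses:
            try:
                fit, cv = ind.fit_indicator(dataset, resp)
                fits[resp] = fit
                fit_text.append(f"== {resp} ==\n" + format_fit_table(fit, cv))
                save_fit_artifact(fit, outdir / f"fit_{resp}.txt")
                written.append(outdir / f"fit_{resp}.txt")
                n_masked = int(dataset[resp].isna().sum())
                if n_masked:
                    log_lines.append(f"fit {resp}: {n_masked} masked years dropped pairwise")
            except ValueError as e:
                fit_text.append(f"== {resp}: not fitted ({e}) ==\n")
                log_lines.append(f"fit {resp} failed: {e}")
        _write("indicator_fits.txt", "\n".join(fit_text))

        stage = "forecast"
        forecasts = {}
        if config.forecast_salinity is not None:
            fc_lines = []
            for resp, fit in fits.items():
                kind = "survival" if resp.startswith("surv_") else "oxygen"
                fc = ind.forecast(fit, config.forecast_salinity, response_kind=kind,
                                  level=config.uncertainty_level)
                forecasts[resp] = fc
                unit = "ml/l" if kind == "oxygen" else "probability"
                hw = f" +/- {fc.half_width:.4g} ({fc.interval_level:.0%} mean-response)" \
                    if fc.half_width is not None else ""
                fc_lines.append(f"{resp}: {fc.point:.4g} {unit}{hw}")
                if fc.extrapolation_warning:
                    fc_lines.append(f"  warning: {fc.extrapolation_warning}")
                    log_lines.append(f"forecast {resp}: {fc.extrapolation_warning}")
            _write("forecast.txt",
                   f"Salinity input: {config.forecast_salinity} psu (Jan-Mar maximum)\n"
                   + "\n".join(fc_lines) + "\n")
    except Exception as e:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage '{stage}' failed: {e}") from e

    log_path = outdir / "run.log"
    log_path.write_text("\n".join(log_lines) + "\n")
    return {"outdir": outdir, "tables": written, "xcorr": grid,
            "season_records": records, "decline_fraction": frac,
            "indicator_dataset": dataset, "fits": fits, "forecasts": forecasts,
            "log": log_path}
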