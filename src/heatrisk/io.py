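"""Tabular readers/writers, run configuration and the end-to-end pipeline.

All tables are plain CSV with ISO-8601 dates and temperatures in °C.  Column
names in source files vary between data providers, so every reader accepts a
column-mapping dict (canonical name -> actual header) instead of hard-coding
headers.  Per-million risks are carried at full floating precision and
rounded only at presentation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dose_response as dr
from . import projection as proj
from . import simulate as sim
from . import wbgt as wb

__all__ = [
    "AGE_GROUPS",
    "PipelineError",
    "RunConfig",
    "read_cases",
    "read_population",
    "read_scenario_climate",
    "write_band_summary",
    "read_band_summary",
    "write_fit_report",
    "read_fit_report",
    "run_pipeline",
]

log = logging.getLogger("heatrisk")

AGE_GROUPS = ("0-17", "18-64", "65+")

# dash variants seen in published tables
_DASHES = {"–": "-", "—": "-", "−": "-"}


def _normalise_age(label: str) -> str:
    s = str(label).strip()
    for d, r in _DASHES.items():
        s = s.replace(d, r)
    return s


def _apply_map(df: pd.DataFrame, column_map: dict | None) -> pd.DataFrame:
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    return df


def _parse_dates(raw: pd.Series) -> pd.Series:
    parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
    if parsed.isna().any():
        row = int(np.flatnonzero(parsed.isna().to_numpy())[0])
        raise ValueError(
            f"malformed date {raw.iloc[row]!r} at row {row + 2}"  # +header, 1-based
        )
    return parsed


def read_cases(
    path,
    population_path=None,
    column_map: dict | None = None,
    population_column_map: dict | None = None,
) -> pd.DataFrame:
    """Read the daily case table (date, age_group, count [, wbgt_c, population]).

    Validates dates, age-group labels and integer counts, rejecting bad rows
    by row number; joins a yearly population table when counts come without
    a population column.  Logs row counts per year x group.
    """
    df = _apply_map(pd.read_csv(path), column_map)
    required = {"date", "age_group", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"case table missing columns {sorted(missing)}")

    df["date"] = _parse_dates(df["date"])
    df["age_group"] = df["age_group"].map(_normalise_age)
    bad = ~df["age_group"].isin(AGE_GROUPS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"unknown age group {df['age_group'].iloc[row]!r} at row {row + 2}"
        )
    counts = pd.to_numeric(df["count"], errors="coerce")
    noninteger = counts.isna() | (counts < 0) | (counts != counts.round())
    if noninteger.any():
        row = int(np.flatnonzero(noninteger.to_numpy())[0])
        raise ValueError(f"non-integer count {df['count'].iloc[row]!r} at row {row + 2}")
    df["count"] = counts.astype(int)
    dup = df.duplicated(subset=["date", "age_group"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValueError(f"duplicate date x age_group at row {row + 2}")

    if "population" not in df.columns:
        if population_path is None:
            raise ValueError(
                "case table has no population column and no population file given"
            )
        pop = read_population(population_path, column_map=population_column_map)
        df["year"] = df["date"].dt.year
        df = df.merge(pop, on=["year", "age_group"], how="left").drop(columns="year")
        if df["population"].isna().any():
            raise ValueError("population file does not cover all case years/groups")

    per = df.groupby([df["date"].dt.year, "age_group"]).size()
    for (year, group), n in per.items():
        log.info("cases: %s %s -> %d rows", year, group, n)
    return df.reset_index(drop=True)


def read_population(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a yearly population table (year, age_group, population)."""
    df = _apply_map(pd.read_csv(path), column_map)
    missing = {"year", "age_group", "population"} - set(df.columns)
    if missing:
        raise ValueError(f"population table missing columns {sorted(missing)}")
    df = df.copy()
    df["year"] = df["year"].astype(int)
    df["age_group"] = df["age_group"].map(_normalise_age)
    df["population"] = df["population"].astype(float)
    if (df["population"] < 0).any():
        raise ValueError("population must be non-negative")
    return df


_RCPS = ("RCP2.6", "RCP4.5", "RCP8.5")


def read_scenario_climate(path, column_map: dict | None = None) -> dict:
    """Read daily scenario climate, keyed by (climate_model, scenario).

    Accepts either a precomputed ``wbgt_c`` column or the raw drivers of the
    WBGT approximation (``tasmax_c``, ``rh_pct``, ``sr_kwm2``, ``ws_ms``),
    in which case WBGT is computed on the fly.  Files without scenario /
    climate_model columns yield the single key ``(None, None)``.  Gaps in a
    year's daily coverage and unit-suspect solar radiation produce warnings,
    not errors.
    """
    df = _apply_map(pd.read_csv(path), column_map)
    if "date" not in df.columns:
        raise ValueError("climate table missing 'date' column")
    df["date"] = _parse_dates(df["date"])

    if "wbgt_c" not in df.columns:
        drivers = {"tasmax_c", "rh_pct", "sr_kwm2", "ws_ms"}
        if not drivers <= set(df.columns):
            raise ValueError(
                "climate table needs either 'wbgt_c' or all of "
                f"{sorted(drivers)}"
            )
        df["wbgt_c"] = wb.compute_wbgt(
            df["tasmax_c"], df["rh_pct"], df["sr_kwm2"], df["ws_ms"]
        )

    for col in ("climate_model", "scenario"):
        if col not in df.columns:
            df[col] = None

    if df["scenario"].notna().any():
        found = set(df["scenario"].dropna().unique())
        absent = [s for s in _RCPS if s not in found]
        if absent:
            log.warning("scenario file %s missing scenarios: %s", path, absent)

    out = {}
    for key, grp in df.groupby(["climate_model", "scenario"], dropna=False):
        key = tuple(None if pd.isna(k) else k for k in key)
        series = grp.sort_values("date").reset_index(drop=True)
        per_year = series.groupby(series["date"].dt.year).size()
        for year, n in per_year.items():
            full = 366 if pd.Timestamp(year=year, month=12, day=31).is_leap_year else 365
            if n != full:
                log.warning(
                    "climate %s year %d has %d/%d days", key, year, n, full
                )
        out[key] = series[["date", "wbgt_c"]]
    return out


def write_band_summary(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, index=False, float_format="%.6f")


def read_band_summary(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"window_start", *wb.BAND_COLUMNS, "n_days"} - set(df.columns)
    if missing:
        raise ValueError(f"band summary missing columns {sorted(missing)}")
    return df


def _params_to_dict(p: dr.ModelParams) -> dict:
    return {k: v for k, v in asdict(p).items() if v is not None}


def write_fit_report(fit: dr.FitResult, path, ci: dict | None = None) -> None:
    """Serialise a fit (params, loglik, AIC, k, vcov) as JSON."""
    doc = {
        "params": _params_to_dict(fit.params),
        "free_names": list(fit.params.free_names),
        "loglik": fit.loglik,
        "aic": fit.aic,
        "k": fit.k,
        "vcov": np.asarray(fit.vcov).tolist(),
        "n_obs": fit.n_obs,
        "age_group": fit.age_group,
    }
    if ci is not None:
        doc["ci"] = ci
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_fit_report(path) -> dr.FitResult:
    doc = json.loads(Path(path).read_text())
    params = dr.ModelParams(**doc["params"])
    return dr.FitResult(
        params=params,
        loglik=doc["loglik"],
        aic=doc["aic"],
        vcov=np.asarray(doc["vcov"], dtype=float),
        n_obs=doc["n_obs"],
        age_group=doc.get("age_group"),
    )


# ---------------------------------------------------------------------------
# run configuration and pipeline


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run.

    Defaults mirror the study conventions: 5-year windows, 5,000 bootstrap
    replicates with 2.5/97.5 percentiles, May 1 - Sep 30 risk season.
    """

    cases_path: str
    climate_path: str
    population_path: str
    out_dir: str
    models: tuple[str, ...] = dr.MODEL_KINDS
    age_groups: tuple[str, ...] = AGE_GROUPS
    grid_step: float = 0.1
    bootstrap_reps: int = 5000
    seed: int = 1
    window_years: int = 5
    window_stat: str = "mean"
    season: tuple[int, int, int, int] | None = (5, 1, 9, 30)
    baseline_window: int | None = None
    percentiles: tuple[float, float] = (2.5, 97.5)
    cases_columns: dict | None = None
    climate_columns: dict | None = None
    population_columns: dict | None = None

    def __post_init__(self):
        self.models = tuple(self.models)
        self.age_groups = tuple(self.age_groups)
        for m in self.models:
            if m not in dr.MODEL_KINDS:
                raise ValueError(f"unknown model {m!r}")
        for g in self.age_groups:
            if g not in AGE_GROUPS:
                raise ValueError(f"unknown age group {g!r}")
        if self.window_stat not in ("mean", "sum"):
            raise ValueError("window_stat must be 'mean' or 'sum'")
        if self.bootstrap_reps <= 0:
            raise ValueError("bootstrap_reps must be positive")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.season is not None:
            self.season = tuple(int(x) for x in self.season)
        for p in ("cases_path", "climate_path", "population_path"):
            if not Path(getattr(self, p)).exists():
                raise FileNotFoundError(f"{p}: {getattr(self, p)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["season"] = list(self.season) if self.season else None
        return d


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Fit -> compare -> band summaries -> project -> CI -> fold change.

    Writes fit reports, MAE tables, band summaries, a combined projection
    CSV and a machine-readable run manifest into ``config.out_dir``.
    Returns a dict of output paths.  Any stage failure raises
    :class:`PipelineError` naming the stage; outputs of completed stages
    remain on disk.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, object] = {}

    def run_stage(name, fn):
        try:
            log.info("stage %s: start", name)
            result = fn()
            log.info("stage %s: done", name)
            return result
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise PipelineError(name, exc) from exc

    def _read():
        cases = read_cases(config.cases_path, column_map=config.cases_columns)
        climate = read_scenario_climate(
            config.climate_path, column_map=config.climate_columns
        )
        pop = read_population(
            config.population_path, column_map=config.population_columns
        )
        return cases, climate, pop

    cases, climate, pop = run_stage("read", _read)

    def _fit():
        best: dict[str, dr.FitResult] = {}
        for group in config.age_groups:
            fits = []
            for model in config.models:
                fit = dr.fit_model(
                    cases,
                    model,
                    grid_step=config.grid_step,
                    age_group=group,
                    season=config.season,
                )
                fits.append(fit)
                tag = f"{group.replace('+', 'plus')}_{model}"
                fit_path = out_dir / f"fit_{tag}.json"
                write_fit_report(fit, fit_path)
                diag = dr.mae_by_wbgt(fit, cases[cases["age_group"] == group])
                mae_path = out_dir / f"mae_{tag}.csv"
                diag.table.to_csv(mae_path, index=False, float_format="%.6f")
                outputs[f"fit_{tag}"] = fit_path
                outputs[f"mae_{tag}"] = mae_path
                log.info(
                    "fit %s %s: AIC=%.1f loglik=%.1f n=%d",
                    group, model, fit.aic, fit.loglik, fit.n_obs,
                )
            best[group] = dr.compare_models(fits)
        return best

    best = run_stage("fit", _fit)

    def _bands():
        paths = []
        for (model_label, scen), series in climate.items():
            summary = wb.band_proportions(series, config.window_years)
            tag = "_".join(str(x) for x in (model_label, scen) if x is not None) or "all"
            tag = tag.replace(".", "")
            p = out_dir / f"bands_{tag}.csv"
            write_band_summary(summary, p)
            outputs[f"bands_{tag}"] = p
            paths.append(p)
        return paths

    run_stage("bands", _bands)

    def _project():
        rows = []
        group_seeds = np.random.SeedSequence(config.seed).spawn(len(config.age_groups))
        for gi, group in enumerate(config.age_groups):
            fit = best[group]
            draws = dr.bootstrap_params(fit, config.bootstrap_reps, group_seeds[gi])
            proj_group = proj.AGE_GROUP_TO_PROJECTION[group]
            pop_g = pop[pop["age_group"].isin({group, proj_group})][
                ["year", "population"]
            ]
            if pop_g.empty:
                raise ValueError(f"no population rows for group {group!r}")
            for (model_label, scen), series in climate.items():
                res = proj.projection_ci(
                    fit,
                    draws,
                    series,
                    pop_g,
                    window=config.window_years,
                    window_stat=config.window_stat,
                    percentiles=config.percentiles,
                )
                baseline = (
                    config.baseline_window
                    if config.baseline_window is not None
                    else int(res["window_start"].min())
                )
                res = proj.fold_change(res, baseline)
                res.insert(1, "age_group", proj_group)
                res.insert(2, "scenario", scen)
                res.insert(3, "climate_model", model_label)
                rows.append(res)
        combined = pd.concat(rows, ignore_index=True)
        p = out_dir / "projections.csv"
        combined.to_csv(p, index=False, float_format="%.6f")
        outputs["projections"] = p
        return combined

    run_stage("project", _project)

    def _manifest():
        import heatrisk

        manifest = {
            "config": config.to_dict(),
            "inputs": {
                name: {"path": str(getattr(config, name)), "sha256": _sha256(getattr(config, name))}
                for name in ("cases_path", "climate_path", "population_path")
            },
            "seed": config.seed,
            "versions": {
                "heatrisk": heatrisk.__version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "decisions": {
                "season": list(config.season) if config.season else "all-days",
                "window_stat": config.window_stat,
                "leap_days": "excluded from band denominators",
                "bootstrap": "parametric normal, thresholds fixed at MLE",
                "aic_k": dict(dr.N_FREE),
            },
        }
        p = out_dir / "manifest.json"
        p.write_text(json.dumps(manifest, indent=2) + "\n")
        outputs["manifest"] = p

    run_stage("manifest", _manifest)
    outputs["best_models"] = {g: best[g].params.kind for g in best}
    return outputs
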