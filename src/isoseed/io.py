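"""File formats, pipeline configuration and end-to-end orchestration.

All tables are comma-separated UTF-8 with a mandatory header row and dot
decimals.  Output files start with ``#``-prefixed provenance comments
(package version, rng seed, config hash) which every reader here skips.
Altitudes are metres above sea level; the sign convention for dispersal
distance (negative = toward the mountain foot) is fixed pipeline-wide and
repeated in every report header.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import (
    ACTINIDIA_OKUTAMA_2013,
    CalibrationLine,
    CalibrationSeedRecord,
    YearDecision,
    fit_calibration,
    year_compatibility,
)
from .classification import (
    DisperserSummary,
    direction_proportion_table,
    disperser_summary,
    format_report,
)
from .inference import (
    DispersalEstimate,
    MCMCConfig,
    SeedRecord,
    build_model,
    gelman_rubin,
    run_mcmc,
    split_gelman_rubin,
    summarize_posterior,
)
from .regressions import RegressionResult, linear_regression, log_regression
from .synthetic import SimulationConfig, TrueEvent, generate_calibration_seeds, generate_dispersal_events

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "PipelineError",
    "read_seed_csv",
    "write_seed_csv",
    "read_calibration_csv",
    "write_calibration_csv",
    "read_temperature_csv",
    "read_home_range_csv",
    "write_truth_csv",
    "write_estimates_csv",
    "read_estimates_csv",
    "write_line_json",
    "read_line_json",
    "run_pipeline",
    "simulate_to_files",
]

logger = logging.getLogger(__name__)

SEED_COLUMNS = [
    "seed_id",
    "faecal_sample_id",
    "species",
    "deposition_altitude_m",
    "delta18O_permil",
    "year",
]
CALIBRATION_COLUMNS = ["altitude_m", "delta18O_permil"]
TRUTH_COLUMNS = [
    "seed_id",
    "species",
    "mother_altitude_m",
    "deposition_altitude_m",
    "true_displacement_m",
]
ESTIMATE_COLUMNS = [
    "seed_id",
    "species",
    "post_mean_mother_alt_m",
    "post_mean_distance_m",
    "post_sd_m",
    "ci95_lower_m",
    "ci95_upper_m",
    "rhat",
    "extrapolated",
]

#: fallback home ranges (ha) when no home-range table is supplied; the
#: bear value is the published study-area mean, the rest are the derived
#: defaults of :func:`isoseed.synthetic.default_study_config`
DEFAULT_HOME_RANGES = {
    "Asian black bear": 3450.0,
    "Japanese macaque": 90.0,
    "raccoon dog": 24.0,
    "Japanese marten": 590.0,
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


# ---------------------------------------------------------------------------
# CSV / JSON primitives


def _provenance(rng_seed: int | None, config_hash: str | None) -> str:
    parts = [f"# isoseed v{__version__}"]
    if rng_seed is not None:
        parts.append(f"# rng_seed={rng_seed}")
    if config_hash is not None:
        parts.append(f"# config_hash={config_hash}")
    return "\n".join(parts) + "\n"


def _write_table(
    df: pd.DataFrame, path: Path, rng_seed: int | None = None, config_hash: str | None = None
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_provenance(rng_seed, config_hash))
        df.to_csv(fh, index=False, lineterminator="\n")


def _read_table(path: Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def _numeric(df: pd.DataFrame, path: Path, column: str, integer: bool = False) -> np.ndarray:
    """Parse one column strictly, naming the offending row and column."""
    raw = df[column]
    out = np.empty(len(raw), dtype=float)
    for i, value in enumerate(raw):
        row = i + 2  # 1-based, plus header line
        if value is None or (isinstance(value, float) and math.isnan(value)) or str(value).strip() == "":
            raise ValueError(f"{path}: row {row}, column {column!r}: missing value")
        try:
            out[i] = float(value)
        except ValueError as exc:
            raise ValueError(
                f"{path}: row {row}, column {column!r}: malformed numeric {value!r}"
            ) from exc
    if integer:
        if not np.all(out == np.floor(out)):
            bad = int(np.argmax(out != np.floor(out))) + 2
            raise ValueError(f"{path}: row {bad}, column {column!r}: expected integer")
        return out.astype(int)
    return out


def read_seed_csv(path: str | Path) -> list[SeedRecord]:
    """Dispersed-seed table → typed records, with row-level validation."""
    path = Path(path)
    df = _read_table(path, SEED_COLUMNS)
    depo = _numeric(df, path, "deposition_altitude_m")
    delta = _numeric(df, path, "delta18O_permil")
    year = _numeric(df, path, "year", integer=True)
    return [
        SeedRecord(
            seed_id=str(df["seed_id"].iloc[i]),
            faecal_sample_id=str(df["faecal_sample_id"].iloc[i]),
            species=str(df["species"].iloc[i]),
            deposition_altitude=float(depo[i]),
            delta18O=float(delta[i]),
            year=int(year[i]),
        )
        for i in range(len(df))
    ]


def write_seed_csv(
    seeds: Sequence[SeedRecord],
    path: str | Path,
    rng_seed: int | None = None,
    config_hash: str | None = None,
) -> None:
    df = pd.DataFrame(
        {
            "seed_id": [s.seed_id for s in seeds],
            "faecal_sample_id": [s.faecal_sample_id for s in seeds],
            "species": [s.species for s in seeds],
            "deposition_altitude_m": [repr(s.deposition_altitude) for s in seeds],
            "delta18O_permil": [repr(s.delta18O) for s in seeds],
            "year": [s.year for s in seeds],
        }
    )
    _write_table(df, Path(path), rng_seed, config_hash)


def read_calibration_csv(path: str | Path) -> list[CalibrationSeedRecord]:
    path = Path(path)
    df = _read_table(path, CALIBRATION_COLUMNS)
    alt = _numeric(df, path, "altitude_m")
    delta = _numeric(df, path, "delta18O_permil")
    ids = df["seed_id"] if "seed_id" in df.columns else [None] * len(df)
    return [
        CalibrationSeedRecord(altitude=float(a), delta18O=float(d), seed_id=i)
        for a, d, i in zip(alt, delta, ids)
    ]


def write_calibration_csv(
    records: Sequence[CalibrationSeedRecord],
    path: str | Path,
    rng_seed: int | None = None,
    config_hash: str | None = None,
) -> None:
    df = pd.DataFrame(
        {
            "seed_id": [r.seed_id or "" for r in records],
            "altitude_m": [repr(r.altitude) for r in records],
            "delta18O_permil": [repr(r.delta18O) for r in records],
        }
    )
    _write_table(df, Path(path), rng_seed, config_hash)


def read_temperature_csv(path: str | Path) -> dict[int, float]:
    """year → maturation-month mean temperature (°C)."""
    path = Path(path)
    df = _read_table(path, ["year", "mean_temp_c"])
    years = _numeric(df, path, "year", integer=True)
    temps = _numeric(df, path, "mean_temp_c")
    return {int(y): float(t) for y, t in zip(years, temps)}


def read_home_range_csv(path: str | Path) -> dict[str, float]:
    """species → home-range size (ha)."""
    path = Path(path)
    df = _read_table(path, ["species", "home_range_ha"])
    hr = _numeric(df, path, "home_range_ha")
    return {str(s): float(h) for s, h in zip(df["species"], hr)}


def write_truth_csv(
    truth: Sequence[TrueEvent],
    path: str | Path,
    rng_seed: int | None = None,
    config_hash: str | None = None,
) -> None:
    df = pd.DataFrame(
        {
            "seed_id": [t.seed_id for t in truth],
            "species": [t.species for t in truth],
            "mother_altitude_m": [repr(t.mother_altitude) for t in truth],
            "deposition_altitude_m": [repr(t.deposition_altitude) for t in truth],
            "true_displacement_m": [repr(t.true_displacement) for t in truth],
        }
    )
    _write_table(df, Path(path), rng_seed, config_hash)


def write_estimates_csv(
    estimates: Sequence[DispersalEstimate],
    path: str | Path,
    rng_seed: int | None = None,
    config_hash: str | None = None,
) -> None:
    df = pd.DataFrame(
        {
            "seed_id": [e.seed_id for e in estimates],
            "species": [e.species for e in estimates],
            "post_mean_mother_alt_m": [repr(e.post_mean_mother_alt) for e in estimates],
            "post_mean_distance_m": [repr(e.post_mean_distance) for e in estimates],
            "post_sd_m": [repr(e.post_sd) for e in estimates],
            "ci95_lower_m": [repr(e.ci95[0]) for e in estimates],
            "ci95_upper_m": [repr(e.ci95[1]) for e in estimates],
            "rhat": [repr(e.rhat) for e in estimates],
            "extrapolated": [str(e.extrapolated) for e in estimates],
        }
    )
    _write_table(df, Path(path), rng_seed, config_hash)


def read_estimates_csv(path: str | Path) -> list[DispersalEstimate]:
    path = Path(path)
    df = _read_table(path, ESTIMATE_COLUMNS)
    cols = {
        c: _numeric(df, path, c)
        for c in ESTIMATE_COLUMNS
        if c not in ("seed_id", "species", "extrapolated")
    }
    return [
        DispersalEstimate(
            seed_id=str(df["seed_id"].iloc[i]),
            species=str(df["species"].iloc[i]),
            post_mean_mother_alt=float(cols["post_mean_mother_alt_m"][i]),
            post_mean_distance=float(cols["post_mean_distance_m"][i]),
            post_sd=float(cols["post_sd_m"][i]),
            ci95=(float(cols["ci95_lower_m"][i]), float(cols["ci95_upper_m"][i])),
            rhat=float(cols["rhat"][i]),
            extrapolated=str(df["extrapolated"].iloc[i]).strip().lower() in ("true", "1"),
        )
        for i in range(len(df))
    ]


def write_line_json(line: CalibrationLine, path: str | Path, line_mode: str = "fixed") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"line_mode": line_mode, **dataclasses.asdict(line)}
    path.write_text(json.dumps(payload, indent=2, allow_nan=True) + "\n", encoding="utf-8")


def read_line_json(path: str | Path) -> CalibrationLine:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    payload.pop("line_mode", None)
    for key in ("support_alt", "support_delta"):
        if payload.get(key) is not None:
            payload[key] = tuple(payload[key])
    return CalibrationLine(**payload)


# ---------------------------------------------------------------------------
# Pipeline configuration


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run description (loadable from YAML or JSON).

    ``line_mode='fixed'`` uses ``line`` (default: the published 2013
    constants); ``'refit'`` estimates the line jointly from
    ``calibration_csv``.  ``apply_year_offset`` subtracts each year's
    lapse-rate altitude offset from the reported distances (off by
    default; offsets are always reported for sensitivity).
    """

    seed_csv: str
    outdir: str
    calibration_csv: str | None = None
    temperature_csv: str | None = None
    home_range_csv: str | None = None
    line_mode: str = "fixed"
    line: CalibrationLine = ACTINIDIA_OKUTAMA_2013
    calibration_year: int = 2013
    identical_threshold: float = 0.2
    exclusion_threshold: float = 0.5
    lapse_rate: float = 0.6
    apply_year_offset: bool = False
    prior_alt_bounds: tuple[float, float] = (0.0, 2500.0)
    measurement_sd: float = 0.2
    include_measurement_sd: bool = True
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.line_mode not in ("fixed", "refit"):
            raise ValueError("line_mode must be 'fixed' or 'refit'")
        if self.line_mode == "refit" and self.calibration_csv is None:
            raise ValueError("refit mode requires calibration_csv")

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        if "line" in raw and isinstance(raw["line"], dict):
            line = dict(raw["line"])
            for key in ("support_alt", "support_delta"):
                if line.get(key) is not None:
                    line[key] = tuple(line[key])
            raw["line"] = CalibrationLine(**line)
        if "mcmc" in raw and isinstance(raw["mcmc"], dict):
            mcmc = dict(raw["mcmc"])
            mcmc.setdefault("rng_seed", raw.get("rng_seed", 0))
            raw["mcmc"] = MCMCConfig(**mcmc)
        elif "mcmc" not in raw:
            raw["mcmc"] = MCMCConfig(rng_seed=raw.get("rng_seed", 0))
        if "prior_alt_bounds" in raw:
            raw["prior_alt_bounds"] = tuple(raw["prior_alt_bounds"])
        return cls(**raw)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        raw = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: expected a mapping at top level")
        return cls.from_dict(raw)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PipelineResult:
    """Bundle of everything the end-to-end run produced."""

    config: PipelineConfig
    line: CalibrationLine
    year_adjustments: dict[int, Any]
    n_seeds_input: int
    n_seeds_used: int
    estimates: list[DispersalEstimate]
    summaries: list[DisperserSummary]
    proportion_table: pd.DataFrame
    regressions: dict[str, RegressionResult]
    diagnostics: dict[str, Any]
    report_text: str


# ---------------------------------------------------------------------------
# Stages


def _stage_year_gate(
    cfg: PipelineConfig, seeds: list[SeedRecord]
) -> tuple[list[SeedRecord], dict[int, Any]]:
    if cfg.temperature_csv is None:
        logger.info("year gate: no temperature table supplied; all years retained")
        return seeds, {}
    temps = read_temperature_csv(cfg.temperature_csv)
    adjustments = year_compatibility(
        temps,
        cfg.calibration_year,
        identical_threshold=cfg.identical_threshold,
        exclusion_threshold=cfg.exclusion_threshold,
        lapse_rate=cfg.lapse_rate,
    )
    missing = sorted({s.year for s in seeds} - set(adjustments))
    if missing:
        raise PipelineError(f"year gate: no temperature record for year(s) {missing}")
    kept = [s for s in seeds if adjustments[s.year].decision != YearDecision.EXCLUDE]
    excluded = sorted(
        {s.year for s in seeds if adjustments[s.year].decision == YearDecision.EXCLUDE}
    )
    if excluded:
        logger.warning(
            "year gate: excluding %d seed(s) from year(s) %s (|ΔT| >= %.2f °C)",
            len(seeds) - len(kept),
            excluded,
            cfg.exclusion_threshold,
        )
    if not kept:
        raise PipelineError(
            f"year gate: all seeds fall in excluded year(s) {excluded}; nothing to analyse"
        )
    for year, adj in sorted(adjustments.items()):
        if adj.decision == YearDecision.ADJUST_OR_FLAG:
            logger.warning(
                "year gate: year %d flagged (ΔT=%.2f °C ≙ %.1f m); "
                "distances shift by the offset if apply_year_offset is set",
                year,
                adj.delta_T,
                adj.altitude_offset,
            )
    return kept, adjustments


def _shift_estimate(est: DispersalEstimate, offset: float) -> DispersalEstimate:
    # subtracting the offset shifts every distance draw, hence mean and CI,
    # by exactly -offset; SD and mother altitude are unchanged
    return dataclasses.replace(
        est,
        post_mean_distance=est.post_mean_distance - offset,
        ci95=(est.ci95[0] - offset, est.ci95[1] - offset),
    )


def run_pipeline(cfg: PipelineConfig, write: bool = True) -> PipelineResult:
    """Execute year gate → calibration → inference → classification →
    regressions, optionally writing the full report bundle to
    ``cfg.outdir``.  Deterministic for a fixed ``cfg.rng_seed``."""
    chash = cfg.config_hash()
    outdir = Path(cfg.outdir)

    try:
        seeds = read_seed_csv(cfg.seed_csv)
    except Exception as exc:
        raise PipelineError(f"input stage: {exc}") from exc
    if not seeds:
        raise PipelineError("input stage: seed table is empty")
    n_input = len(seeds)

    try:
        seeds, adjustments = _stage_year_gate(cfg, seeds)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"year gate: {exc}") from exc

    # calibration stage
    try:
        if cfg.line_mode == "refit":
            cal_records = read_calibration_csv(cfg.calibration_csv)
            model = build_model(
                cal_records,
                seeds,
                prior_alt_bounds=cfg.prior_alt_bounds,
                measurement_sd=cfg.measurement_sd,
                include_measurement_sd=cfg.include_measurement_sd,
            )
            line = model.line  # OLS point fit; posterior refines it
        else:
            line = cfg.line
            if cfg.calibration_csv is not None:
                cal_records = read_calibration_csv(cfg.calibration_csv)
                line = fit_calibration(cal_records)
                logger.info(
                    "calibration: fitted line from %s (slope %.5f, R²=%.2f)",
                    cfg.calibration_csv,
                    line.slope,
                    line.r_squared,
                )
            model = build_model(
                line,
                seeds,
                prior_alt_bounds=cfg.prior_alt_bounds,
                measurement_sd=cfg.measurement_sd,
                include_measurement_sd=cfg.include_measurement_sd,
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"calibration stage: {exc}") from exc

    # inference stage
    try:
        mcmc_cfg = cfg.mcmc
        draws = run_mcmc(model, mcmc_cfg)
        rhat = gelman_rubin(draws) if mcmc_cfg.n_chains >= 2 else {}
        estimates = summarize_posterior(draws, rhat=rhat)
    except Exception as exc:
        raise PipelineError(f"inference stage: {exc}") from exc

    bad = {k: v for k, v in rhat.items() if v >= mcmc_cfg.rhat_threshold}
    if bad:
        logger.warning(
            "CONVERGENCE WARNING: %d parameter(s) with R-hat >= %.3f (worst %.3f); "
            "treat the affected estimates with caution",
            len(bad),
            mcmc_cfg.rhat_threshold,
            max(bad.values()),
        )

    if cfg.apply_year_offset and adjustments:
        estimates = [
            _shift_estimate(e, adjustments[s.year].altitude_offset)
            for e, s in zip(estimates, seeds)
        ]

    # classification stage
    try:
        species_order = list(dict.fromkeys(s.species for s in seeds))
        summaries = [disperser_summary(estimates, sp) for sp in species_order]
        table = direction_proportion_table(summaries)
    except Exception as exc:
        raise PipelineError(f"classification stage: {exc}") from exc

    # regression stage
    regressions: dict[str, RegressionResult] = {}
    try:
        home_ranges = (
            read_home_range_csv(cfg.home_range_csv)
            if cfg.home_range_csv is not None
            else DEFAULT_HOME_RANGES
        )
        with_hr = [s for s in summaries if s.species in home_ranges]
        if len(with_hr) >= 3:
            regressions["home_range_log"] = log_regression(
                [home_ranges[s.species] for s in with_hr],
                [s.mean_distance for s in with_hr],
            )
        else:
            logger.info("regressions: <3 species with home ranges; log regression skipped")
        for sp in species_order:
            group = [e for e in estimates if e.species == sp]
            x = [e.post_mean_mother_alt for e in group]
            y = [e.post_mean_distance for e in group]
            if len(group) >= 3 and len(set(x)) >= 2:
                regressions[f"altitude_linear[{sp}]"] = linear_regression(x, y)
            else:
                logger.info("regressions: %s has too few seeds for a linear fit", sp)
    except Exception as exc:
        raise PipelineError(f"regression stage: {exc}") from exc

    diagnostics = {
        "rng_seed": cfg.rng_seed,
        "config_hash": chash,
        "line_mode": cfg.line_mode,
        "n_seeds_input": n_input,
        "n_seeds_used": len(seeds),
        "acceptance": draws.acceptance,
        "rhat": rhat,
        "rhat_split": split_gelman_rubin(draws)
        if mcmc_cfg.n_chains >= 2 and mcmc_cfg.retained_per_chain >= 10
        else {},
        "rhat_threshold": mcmc_cfg.rhat_threshold,
        "rhat_max": max(rhat.values()) if rhat else None,
        "retained_per_chain": draws.n_retained_per_chain,
        "total_retained": draws.total_retained,
        "n_extrapolated": sum(e.extrapolated for e in estimates),
    }

    header = [
        f"isoseed v{__version__} report (rng_seed={cfg.rng_seed}, config_hash={chash})",
        "Sign convention: negative distance = seed dispersal toward the mountain foot,",
        "positive = toward the top.",
        f"Seeds analysed: {len(seeds)}/{n_input} (after year gate); "
        f"line mode: {cfg.line_mode}; "
        f"extrapolated seeds: {diagnostics['n_extrapolated']}.",
    ]
    if bad:
        header.append(
            f"WARNING: {len(bad)} parameter(s) exceeded the R-hat threshold "
            f"{mcmc_cfg.rhat_threshold}; convergence is suspect."
        )
    report_lines = header + ["", format_report(summaries), ""]
    for name, res in regressions.items():
        report_lines.append(
            f"{name}: y = {res.slope:.2f}·{'ln(x)' if res.model == 'log_linear' else 'x'}"
            f" + {res.intercept:.2f}; r = {res.r:.2f}, t = {res.t_stat:.2f}, "
            f"P = {res.p_value:.2g}, n = {res.n}"
        )
    report_text = "\n".join(report_lines) + "\n"

    result = PipelineResult(
        config=cfg,
        line=line,
        year_adjustments=adjustments,
        n_seeds_input=n_input,
        n_seeds_used=len(seeds),
        estimates=estimates,
        summaries=summaries,
        proportion_table=table,
        regressions=regressions,
        diagnostics=diagnostics,
        report_text=report_text,
    )

    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        write_estimates_csv(estimates, outdir / "estimates.csv", cfg.rng_seed, chash)
        summary_df = pd.DataFrame(
            {
                "species": [s.species for s in summaries],
                "n_seeds": [s.n_seeds for s in summaries],
                "mean_distance_m": [repr(s.mean_distance) for s in summaries],
                "se_distance_m": [repr(s.se_distance) for s in summaries],
                "prop_downhill": [repr(s.prop_downhill) for s in summaries],
                "prop_uphill": [repr(s.prop_uphill) for s in summaries],
                "prop_neither": [repr(s.prop_neither) for s in summaries],
            }
        )
        _write_table(summary_df, outdir / "species_summary.csv", cfg.rng_seed, chash)
        _write_table(table, outdir / "direction_table.csv", cfg.rng_seed, chash)
        write_line_json(line, outdir / "calibration_line.json", cfg.line_mode)
        (outdir / "regressions.json").write_text(
            json.dumps(
                {k: dataclasses.asdict(v) for k, v in regressions.items()},
                indent=2,
                sort_keys=True,
            )
            + "\n",
            encoding="utf-8",
        )
        (outdir / "diagnostics.json").write_text(
            json.dumps(diagnostics, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        (outdir / "report.txt").write_text(report_text, encoding="utf-8")

    return result


def simulate_to_files(
    sim: SimulationConfig,
    outdir: str | Path,
    calibration_n: int = 60,
    calibration_alt_range: tuple[float, float] | None = None,
) -> dict[str, Path]:
    """Generate a full synthetic study on disk: dispersed seeds,
    calibration seeds, and the ground-truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds, truth = generate_dispersal_events(sim)
    alt_range = calibration_alt_range or sim.line.support_alt or sim.mountain_bounds
    cal = generate_calibration_seeds(
        sim.line, calibration_n, alt_range, rng_seed=sim.rng_seed + 1, allow_extrapolation=True
    )
    paths = {
        "seeds": outdir / "seeds.csv",
        "calibration": outdir / "calibration_seeds.csv",
        "truth": outdir / "truth.csv",
    }
    write_seed_csv(seeds, paths["seeds"], rng_seed=sim.rng_seed)
    write_calibration_csv(cal, paths["calibration"], rng_seed=sim.rng_seed)
    write_truth_csv(truth, paths["truth"], rng_seed=sim.rng_seed)
    return paths
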