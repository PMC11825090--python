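"""End-to-end orchestration of the four-stage point-mean pipeline.

clean -> cessation (loess) -> calibrate/fit (mixed model) -> point mean, per
species and reporting year, with all intermediate artifacts (exclusion log,
cessation estimates, coefficients, calibration traces, report rows) written to
an output directory together with a machine-readable run manifest.  Stage
outputs are pure functions of (inputs, config, seed): re-running with the same
configuration reproduces the reports byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .calibration import calibrate_max_age
from .cessation import estimate_cessation
from .cohort import apply_exclusions, build_growth_pairs, default_limits, read_records
from .point_mean import annual_report
from .synthetic import DEFAULT_SPECIES, generate_population


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    With ``records_path`` unset, a synthetic population of ``n_animals`` per
    species is generated over ``date_window`` from ``seed``.
    """

    species: list[str] = field(default_factory=lambda: ["dog"])
    years: list[int] = field(default_factory=lambda: [2023])
    records_path: str | None = None
    n_animals: int = 2000
    seed: int = 0
    date_window: tuple[str, str] = ("2023-01-01", "2023-12-31")
    max_age_at_end_months: float = 180.0
    criterion: str = "aicc"
    loess_degree: int = 1
    calibration_bounds: tuple[int, int] | None = None
    require_invoice: bool = True
    adult_cutoff_months: float = 24.0
    in_year_only: bool = True
    out_dir: str = "vetweight_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("date_window", "calibration_bounds"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all four stages and write the report bundle to ``out_dir``.

    Returns a dict with per-species cessation estimates, calibration results,
    coefficients and per-year point-mean reports.  Any stage failure raises
    :class:`PipelineError` naming the stage; logs written so far persist.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    limits = default_limits()
    bundle: dict = {"species": {}}

    try:
        if config.records_path is not None:
            records, row_errors = read_records(config.records_path)
            row_errors.to_csv(out / "row_errors.csv", index=False)
        else:
            configs = {s: DEFAULT_SPECIES[s] for s in config.species}
            records, _truth = generate_population(
                configs,
                config.n_animals,
                config.date_window,
                config.seed,
                max_age_at_end_months=config.max_age_at_end_months,
            )
    except Exception as exc:
        raise PipelineError(f"stage 'load': {exc}") from exc

    try:
        cleaned, exclusion_log = apply_exclusions(
            records, limits, require_invoice=config.require_invoice
        )
        exclusion_log.to_csv(out / "exclusion_log.csv", index=False)
    except Exception as exc:
        raise PipelineError(f"stage 'clean': {exc}") from exc

    for sp in config.species:
        sp_records = cleaned[cleaned["species"] == sp]
        if sp_records.empty:
            raise PipelineError(f"stage 'clean': no records remain for {sp}")

        try:
            cess, fit = estimate_cessation(
                sp_records,
                species=sp,
                criterion=config.criterion,
                degree=config.loess_degree,
                seed=config.seed,
            )
        except Exception as exc:
            raise PipelineError(f"stage 'cessation' ({sp}): {exc}") from exc
        _dump(
            out / f"cessation_{sp}.json",
            {
                "species": sp,
                "age_months": cess.age_months,
                "span": fit.span,
                "criterion": fit.criterion,
                "n_points": fit.n_points,
            },
        )

        try:
            hi = (config.calibration_bounds or (0, 72))[1]
            pairs = build_growth_pairs(sp_records, max_age_months=hi)
            calib, coeffs = calibrate_max_age(
                pairs, cess, bounds=config.calibration_bounds
            )
            coeffs.max_valid_age_months = limits[sp].max_juvenile_age_months
        except Exception as exc:
            raise PipelineError(f"stage 'calibrate' ({sp}): {exc}") from exc
        coeffs.to_json(out / f"coefficients_{sp}.json")
        _dump(
            out / f"calibration_{sp}.json",
            {
                "max_dev_age_months": calib.max_dev_age_months,
                "solved_cessation_months": calib.solved_cessation_months,
                "loess_target_months": calib.loess_target_months,
                "iterations": calib.iterations,
                "converged": calib.converged,
            },
        )

        reports = []
        for year in config.years:
            try:
                rep = annual_report(
                    cleaned,
                    coeffs,
                    cess,
                    year,
                    sp,
                    limits[sp].max_juvenile_age_months,
                    adult_cutoff_months=config.adult_cutoff_months,
                    in_year_only=config.in_year_only,
                )
            except Exception as exc:
                raise PipelineError(f"stage 'point_mean' ({sp}, {year}): {exc}") from exc
            reports.append(rep)
        bundle["species"][sp] = {
            "cessation": cess,
            "calibration": calib,
            "coefficients": coeffs,
            "reports": reports,
        }

    rows = [
        r.to_dict() for sp in bundle["species"].values() for r in sp["reports"]
    ]
    _dump(out / "point_means.json", rows)
    pd.json_normalize(rows).to_csv(out / "point_means.csv", index=False)
    _dump(
        out / "manifest.json",
        {
            "package": "vetweight",
            "version": __version__,
            "library_versions": _library_versions(),
            "config": _jsonable(dataclasses.asdict(config)),
            "n_input_records": int(len(records)),
            "n_retained_records": int(len(cleaned)),
            "n_excluded_records": int(len(exclusion_log)),
        },
    )
    bundle["n_input_records"] = int(len(records))
    bundle["n_retained_records"] = int(len(cleaned))
    return bundle


def _library_versions() -> dict:
    import numpy
    import scipy
    import statsmodels

    return {
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
    }


def _jsonable(obj):
    import numpy as np

    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _dump(path, payload) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(payload), fh, indent=2, sort_keys=True)
        fh.write("\n")
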