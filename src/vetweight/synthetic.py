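"""Seeded synthetic veterinary EHR bodyweight records with known ground truth.

The generator emulates the ad-hoc bodyweight record streams found in UK
primary-care veterinary databases: per-animal monotone juvenile growth rising
to a stable adult plateau at a species-specific age (~13--14 months),
right-skewed adult weight distributions, visit dates that are denser for
juveniles than adults, multiplicative measurement noise, and planted
data-entry defects (unit-error weights, missing dates of birth, implausible
ages, uninvoiced records).

Each animal's noiseless weight follows a smooth rise-then-plateau curve with
log-growth rate declining linearly to zero at the species cessation age T:

    w(a) = W * exp(-c/2 * (T - a)^2)   for a < T,   w(a) = W  for a >= T,

which is monotone, exactly constant beyond T, and continuously differentiable
at the plateau onset.  The single shape parameter c is set by the
proportional monthly gain at the age of first presentation (pets first visit
a practice at around 1.5 months, so earlier ages are never recorded).  Under
this shape the monthly proportional gain declines roughly linearly with age,
matching the pattern fitted juvenile-growth models report for primary-care
populations.  Adult weights W are log-normal, truncated to the species
plausible range.

All randomness flows from a single integer seed through ``numpy.random
.default_rng``; identical (config, seed) inputs give identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import DAYS_PER_MONTH, default_limits



_LIMITS = default_limits()


@dataclass(frozen=True)
class SpeciesConfig:
    """Study conditions for one synthetic species population.

    ``adult_weight_median_kg``/``adult_weight_log_sigma`` parameterise the
    log-normal adult weight law (location = log median, scale on the log
    scale); defaults reproduce the right-skewed medians and IQRs reported for
    UK primary-care populations.  ``cessation_age_months`` is the true age at
    which juvenile growth stops.  ``initial_monthly_gain`` is the
    proportional bodyweight gain over one month at the age of first
    presentation (``first_visit_age_months``); together with
    ``plateau_monthly_increment`` (relative weight increment over the final
    month of growth) it determines the Gompertz shape.  Visit
    rates are expected visits per month of a homogeneous Poisson process,
    higher for juveniles.  ``noise_cv`` is the coefficient of variation of
    multiplicative log-normal measurement noise.  Error rates are record
    fractions for planted data-entry defects.
    """

    species: str
    adult_weight_median_kg: float
    adult_weight_log_sigma: float
    cessation_age_months: float
    initial_monthly_gain: float = 0.385
    first_visit_age_months: float = 1.5
    visit_rate_juvenile: float = 0.8
    visit_rate_adult: float = 0.15
    noise_cv: float = 0.02
    unit_error_rate: float = 0.0
    missing_dob_rate: float = 0.0
    implausible_age_rate: float = 0.0
    missing_invoice_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.cessation_age_months <= 0:
            raise ValueError("cessation_age_months must be > 0")
        if self.adult_weight_log_sigma < 0 or self.adult_weight_median_kg <= 0:
            raise ValueError("invalid adult weight distribution parameters")
        if self.initial_monthly_gain <= 0:
            raise ValueError("initial_monthly_gain must be > 0")
        if not 0 <= self.first_visit_age_months < self.cessation_age_months:
            raise ValueError("first_visit_age_months must be in [0, cessation)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for name in (
            "unit_error_rate",
            "missing_dob_rate",
            "implausible_age_rate",
            "missing_invoice_rate",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def growth_shape(self) -> float:
        """Curvature c of the log-quadratic growth curve.

        Solved so the proportional gain over [a0, a0+1] at a0 = first
        presentation equals ``initial_monthly_gain``: the log-gain over that
        month is c * (T - a0 - 1/2), hence c is its ratio.
        """
        T = self.cessation_age_months
        a0 = self.first_visit_age_months
        if T - a0 <= 1.0:
            raise ValueError("cessation must exceed first visit age by > 1 month")
        return float(np.log1p(self.initial_monthly_gain) / (T - a0 - 0.5))


#: Default study conditions per species: adult weight laws matched to reported
#: medians/IQRs (dog 12.0 (7.1, 22.1) kg; cat 3.9 (3.0, 4.8); rabbit 2.0
#: (1.5, 2.5); guinea pig 1.0 (0.8, 1.1)); cessation ages at the smoothed
#: population estimates (13.8/12.8/13.0/12.8 months); first-presentation
#: monthly gains at the magnitudes of fitted juvenile-growth models for the
#: same populations (0.385/0.376/0.183/0.109).
DEFAULT_SPECIES: dict[str, SpeciesConfig] = {
    "dog": SpeciesConfig("dog", 12.0, 0.8414, 13.8, 0.385),
    "cat": SpeciesConfig("cat", 3.9, 0.3484, 12.8, 0.376),
    "rabbit": SpeciesConfig("rabbit", 2.0, 0.3787, 13.0, 0.183,
                            visit_rate_juvenile=0.6, visit_rate_adult=0.12),
    "guinea_pig": SpeciesConfig("guinea_pig", 1.0, 0.2361, 12.8, 0.109,
                                visit_rate_juvenile=0.6, visit_rate_adult=0.12),
}


def growth_curve_weight(age_months, adult_weight_kg, c: float, cessation: float):
    """Noiseless truth curve: log-quadratic rise, constant beyond cessation."""
    a = np.minimum(np.asarray(age_months, dtype=float), cessation)
    return adult_weight_kg * np.exp(-0.5 * c * (cessation - a) ** 2)


@dataclass
class TruthTable:
    """Ground truth for a generated population.

    ``animals`` has one row per animal: animal_id, species, dob,
    adult_weight_kg.  Together with the per-species growth parameters this
    determines each animal's noiseless weight at any age.
    """

    animals: pd.DataFrame
    configs: dict[str, SpeciesConfig]
    shapes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.shapes:
            self.shapes = {s: c.growth_shape for s, c in self.configs.items()}

    def true_weight(self, age_months) -> np.ndarray:
        """Noiseless weight of every animal at the given per-animal ages."""
        out = np.empty(len(self.animals))
        ages = np.asarray(age_months, dtype=float)
        for sp, cfg in self.configs.items():
            m = (self.animals["species"] == sp).to_numpy()
            if m.any():
                out[m] = growth_curve_weight(
                    ages[m] if ages.ndim else ages,
                    self.animals.loc[m, "adult_weight_kg"].to_numpy(),
                    self.shapes[sp],
                    cfg.cessation_age_months,
                )
        return out


def true_point_mean(
    truth: TruthTable, target_date, species: str | None = None
) -> float:
    """Arithmetic mean of noiseless true weights at ``target_date``.

    Includes every generated animal born on or before the target date; the
    oracle against which pipeline point means are judged.
    """
    df = truth.animals
    if species is not None:
        df = df[df["species"] == species]
    df = df[df["dob"] <= pd.Timestamp(target_date)]
    if df.empty:
        raise ValueError("no animals alive at target date")
    sub = TruthTable(df.reset_index(drop=True), truth.configs, truth.shapes)
    ages = (pd.Timestamp(target_date) - sub.animals["dob"]).dt.days / DAYS_PER_MONTH
    return float(np.mean(sub.true_weight(ages.to_numpy())))


def true_cessation_oracle(
    truth: TruthTable,
    species: str,
    tolerance_kg: float = 1e-4,
    grid_step: float = 0.05,
    grid_max_months: float = 30.0,
) -> float:
    """First grid age at which the noiseless population increment hits zero.

    Evaluates the population mean of the noiseless truth curves on the grid
    and returns the earliest age whose per-step increment is at or below
    ``tolerance_kg`` -- the ground-truth analogue of the smoothed-curve
    detection rule.  For light species this precedes the cessation age,
    because the tolerance is absolute.
    """
    df = truth.animals[truth.animals["species"] == species]
    if df.empty:
        raise ValueError(f"no {species} in truth table")
    cfg = truth.configs[species]
    c = truth.shapes[species]
    W = df["adult_weight_kg"].to_numpy()
    grid = np.round(np.arange(0.0, grid_max_months + grid_step / 2, grid_step), 10)
    curve = np.array(
        [
            growth_curve_weight(a, W, c, cfg.cessation_age_months).mean()
            for a in grid
        ]
    )
    hits = np.flatnonzero(np.diff(curve) <= tolerance_kg)
    if hits.size == 0:
        raise ValueError("truth curve never plateaus on the grid")
    return float(grid[hits[0]])


def generate_population(
    configs: dict[str, SpeciesConfig] | list[SpeciesConfig],
    n_animals: int,
    date_window: tuple,
    seed: int,
    max_age_at_end_months: float = 180.0,
    n_practices: int = 20,
    n_groups: int = 5,
) -> tuple[pd.DataFrame, TruthTable]:
    """Generate a synthetic bodyweight record table with ground truth.

    ``n_animals`` animals per species are created with dates of birth uniform
    over ages ``(0, max_age_at_end_months]`` at the window end, visits from a
    two-rate Poisson process (juvenile/adult), and at least one record inside
    ``date_window`` per animal.  Records carry invoice, practice and group
    identifiers.  Planted defects are applied according to the configs' error
    rates (see :func:`inject_errors`).

    Returns ``(records, truth)``; identical inputs yield identical output.
    """
    if isinstance(configs, list):
        configs = {c.species: c for c in configs}
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    start, end = (pd.Timestamp(date_window[0]), pd.Timestamp(date_window[1]))
    if end <= start:
        raise ValueError("date_window must be non-empty")

    rng = np.random.default_rng(seed)
    frames = []
    truth_frames = []
    for sp in sorted(configs):
        cfg = configs[sp]
        c = cfg.growth_shape
        T = cfg.cessation_age_months
        a0 = cfg.first_visit_age_months
        # adult weights: log-normal truncated to the species plausible range
        # (a real population holds no animals beyond those bounds)
        wmax = _LIMITS[sp].weight_max_kg if sp in _LIMITS else np.inf
        W = np.exp(
            np.log(cfg.adult_weight_median_kg)
            + cfg.adult_weight_log_sigma * rng.standard_normal(n_animals)
        )
        for _ in range(100):
            bad = W > wmax
            if not bad.any():
                break
            W[bad] = np.exp(
                np.log(cfg.adult_weight_median_kg)
                + cfg.adult_weight_log_sigma * rng.standard_normal(int(bad.sum()))
            )
        # ages at window end: every generated animal is old enough to have
        # presented at a practice at least once
        age_end = rng.uniform(a0 + 0.5, max_age_at_end_months, n_animals)
        dob_days = np.round(age_end * DAYS_PER_MONTH).astype(int)
        dob = end - pd.to_timedelta(dob_days, unit="D")
        practice = rng.integers(0, n_practices, n_animals)
        sex = rng.choice(["female", "male"], n_animals)
        aid = np.array([f"{sp[:2]}{i:06d}" for i in range(n_animals)])
        truth_frames.append(
            pd.DataFrame(
                {"animal_id": aid, "species": sp, "dob": dob, "adult_weight_kg": W}
            )
        )

        # two-rate Poisson visit process over each observable lifetime
        # (no visits before the first-presentation age a0)
        juv_span = np.maximum(np.minimum(age_end, T) - a0, 0.0)
        adult_span = np.maximum(age_end - T, 0.0)
        n_j = rng.poisson(cfg.visit_rate_juvenile * juv_span)
        n_a = rng.poisson(cfg.visit_rate_adult * adult_span)
        owner = np.concatenate([np.repeat(np.arange(n_animals), n_j),
                                np.repeat(np.arange(n_animals), n_a)])
        u = rng.uniform(size=owner.size)
        ages = np.concatenate(
            [
                a0 + u[: n_j.sum()] * np.repeat(juv_span, n_j),
                T + u[n_j.sum():] * np.repeat(adult_span, n_a),
            ]
        )
        # keep only visits inside the observation window, then force one
        # visit per animal that would otherwise have none
        age_days = np.round(ages * DAYS_PER_MONTH).astype(int)
        date_off = dob_days[owner] - age_days  # days before window end
        inside = (date_off >= 0) & (date_off <= (end - start).days)
        owner, age_days, date_off = owner[inside], age_days[inside], date_off[inside]
        have = np.bincount(owner, minlength=n_animals) > 0
        need = np.flatnonzero(~have)
        if need.size:
            a0_days = int(np.ceil(a0 * DAYS_PER_MONTH))
            span = np.minimum(dob_days[need] - a0_days, (end - start).days)
            forced = (span * rng.uniform(size=need.size)).astype(int)
            owner = np.concatenate([owner, need])
            age_days = np.concatenate([age_days, dob_days[need] - forced])
            date_off = np.concatenate([date_off, forced])
        ages = age_days / DAYS_PER_MONTH
        w = growth_curve_weight(ages, W[owner], c, T)
        if cfg.noise_cv > 0:
            sigma_n = np.sqrt(np.log1p(cfg.noise_cv**2))
            w = w * np.exp(sigma_n * rng.standard_normal(w.size) - sigma_n**2 / 2)
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": aid[owner],
                    "species": sp,
                    "sex": sex[owner],
                    "dob": dob[owner],
                    "date": end - pd.to_timedelta(date_off, unit="D"),
                    "weight_kg": w,
                    "_pr": practice[owner],
                }
            ).sort_values(["animal_id", "date"], kind="stable")
        )

    records = pd.concat(frames, ignore_index=True)
    records["invoice_id"] = [f"inv{j:08d}" for j in range(len(records))]
    records["practice_id"] = "pr" + records.pop("_pr").astype(str).str.zfill(3)
    records["group_id"] = "grp" + (
        records["practice_id"].str[2:].astype(int) % n_groups
    ).astype(str)
    records = records[
        [
            "animal_id",
            "species",
            "sex",
            "dob",
            "date",
            "weight_kg",
            "invoice_id",
            "practice_id",
            "group_id",
        ]
    ]
    truth = TruthTable(pd.concat(truth_frames, ignore_index=True), dict(configs))
    if any(
        c.unit_error_rate or c.missing_dob_rate or c.implausible_age_rate
        or c.missing_invoice_rate
        for c in configs.values()
    ):
        records, _ = inject_errors(records, configs, seed + 1)
    return records, truth


def inject_errors(
    records: pd.DataFrame,
    configs: dict[str, SpeciesConfig] | SpeciesConfig,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant data-entry defects into a record table.

    Per species and rate: unit-error records (weight multiplied or divided by
    1000), records of animals whose date of birth is blanked, records whose
    date of birth is shifted so the age falls outside the species plausibility
    range, and records stripped of their invoice id.  Returns the altered
    table and an alteration log (animal_id, date, rule, detail); with all
    rates zero the input is returned unchanged.
    """
    if isinstance(configs, SpeciesConfig):
        configs = {configs.species: configs}
    rng = np.random.default_rng(seed)
    df = records.copy().reset_index(drop=True)
    limits = default_limits()
    log = []

    for sp in sorted(configs):
        cfg = configs[sp]
        sp_idx = np.flatnonzero((df["species"] == sp).to_numpy())
        if len(sp_idx) == 0:
            continue

        def pick(rate: float) -> np.ndarray:
            n = int(round(rate * len(sp_idx)))
            return rng.choice(sp_idx, size=n, replace=False) if n else np.array([], int)

        for i in pick(cfg.unit_error_rate):
            factor = 1000.0 if rng.random() < 0.5 else 1e-3
            df.loc[i, "weight_kg"] *= factor
            log.append((df.loc[i, "animal_id"], df.loc[i, "date"], "unit_error", factor))
        for i in pick(cfg.missing_dob_rate):
            aid = df.loc[i, "animal_id"]
            df.loc[df["animal_id"] == aid, "dob"] = pd.NaT
            log.append((aid, df.loc[i, "date"], "missing_dob", ""))
        max_age_y = limits[sp].age_max_y if sp in limits else 25.0
        for i in pick(cfg.implausible_age_rate):
            shift = (max_age_y + float(rng.uniform(1.0, 5.0))) * 365.25
            df.loc[i, "dob"] = df.loc[i, "date"] - pd.Timedelta(days=int(shift))
            log.append((df.loc[i, "animal_id"], df.loc[i, "date"], "implausible_age", ""))
        for i in pick(cfg.missing_invoice_rate):
            df.loc[i, "invoice_id"] = pd.NA
            log.append((df.loc[i, "animal_id"], df.loc[i, "date"], "missing_invoice", ""))

    return df, pd.DataFrame(log, columns=["animal_id", "date", "rule", "detail"])


def write_outputs(records, truth: TruthTable, out_dir, configs=None) -> None:
    """Write records CSV, truth CSV and a JSON config echo to ``out_dir``."""
    from pathlib import Path

    from .cohort import write_records

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_records(records, out / "records.csv")
    t = truth.animals.copy()
    t["dob"] = pd.to_datetime(t["dob"]).dt.strftime("%Y-%m-%d")
    t.to_csv(out / "truth.csv", index=False)
    cfgs = configs or truth.configs
    with open(out / "config.json", "w") as fh:
        json.dump({s: asdict(c) for s, c in cfgs.items()}, fh, indent=2)


def with_error_rates(cfg: SpeciesConfig, **rates) -> SpeciesConfig:
    """Copy a config with altered error/noise rates (convenience)."""
    return replace(cfg, **rates)
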