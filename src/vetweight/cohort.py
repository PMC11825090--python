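"""Record ingestion, plausibility filtering and growth-pair construction.

Raw bodyweight records from primary-care veterinary EHRs are noisy: dates of
birth may be missing, weights may be entered in the wrong unit, and implausible
values occur at data entry.  This module reads the record CSV, applies the
exclusion rules (invoice restriction, missing date of birth, species-specific
weight/age plausibility ranges, implausible month-on-month growth jumps) and
builds the consecutive-measurement proportional-gain observations used to model
juvenile growth.

All tabular data are pandas DataFrames.  Every dropped row is accounted for in
an exclusion log so that ``len(input) == len(retained) + len(log)``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

#: Fixed day/month conversion used throughout the package (mean Gregorian month).
DAYS_PER_MONTH = 30.4375

RECORD_COLUMNS = [
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

_MANDATORY = ["animal_id", "species", "dob", "date", "weight_kg"]


class SchemaError(ValueError):
    """The input file does not carry the expected columns."""


@dataclass(frozen=True)
class SpeciesLimits:
    """Plausibility bounds for one species.

    Weights outside ``[weight_min_kg, weight_max_kg]`` or ages outside
    ``[age_min_y, age_max_y]`` (closed intervals, day precision) are treated as
    data-entry errors.  ``jump_factor`` bounds the plausible monthly-equivalent
    growth ratio between consecutive measurements (10 for dogs and cats, 3 for
    rabbits and guinea pigs).  ``max_juvenile_age_months`` is the validity
    bound of the juvenile growth model for this species.
    """

    weight_min_kg: float
    weight_max_kg: float
    age_min_y: float
    age_max_y: float
    jump_factor: float
    max_juvenile_age_months: float

    def __post_init__(self) -> None:
        if not self.weight_min_kg < self.weight_max_kg:
            raise ValueError("weight_min_kg must be < weight_max_kg")
        if not self.age_min_y < self.age_max_y:
            raise ValueError("age_min_y must be < age_max_y")
        if self.jump_factor <= 1:
            raise ValueError("jump_factor must be > 1")


def default_limits() -> dict[str, SpeciesLimits]:
    """Load the packaged per-species plausibility limits (versioned YAML)."""
    ref = importlib.resources.files("vetweight.data") / "species_limits.yaml"
    raw = yaml.safe_load(ref.read_text())
    return {name: SpeciesLimits(**vals) for name, vals in raw["species"].items()}


def load_limits(path) -> dict[str, SpeciesLimits]:
    """Load per-species limits from a YAML file with the packaged schema."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {name: SpeciesLimits(**vals) for name, vals in raw["species"].items()}


def age_in_months(dob, date) -> float:
    """Age in months between two dates, at 30.4375 days per month.

    Raises ``ValueError`` when ``date`` precedes ``dob``.
    """
    days = (pd.Timestamp(date) - pd.Timestamp(dob)).days
    if days < 0:
        raise ValueError(f"date {date} precedes dob {dob}")
    return days / DAYS_PER_MONTH


def _ages_months(dob: pd.Series, date: pd.Series) -> pd.Series:
    return (date - dob).dt.days / DAYS_PER_MONTH


def read_records(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a bodyweight record CSV.

    Returns ``(records, row_errors)``.  Rows whose date or weight fields fail
    to parse are collected into ``row_errors`` (columns: row, column, value)
    and dropped from ``records``; a missing mandatory column raises
    :class:`SchemaError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    for c in RECORD_COLUMNS:
        if c not in df.columns:
            df[c] = ""

    errors = []
    weight = pd.to_numeric(df["weight_kg"], errors="coerce")
    date = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")
    # dob may legitimately be blank (missing date of birth)
    dob = pd.to_datetime(
        df["dob"].replace("", pd.NA), format="%Y-%m-%d", errors="coerce"
    )
    bad_weight = weight.isna() | (weight <= 0)
    bad_date = date.isna()
    bad_dob = dob.isna() & (df["dob"] != "")
    for col, bad, src in [
        ("weight_kg", bad_weight, df["weight_kg"]),
        ("date", bad_date, df["date"]),
        ("dob", bad_dob, df["dob"]),
    ]:
        for i in np.flatnonzero(bad.to_numpy()):
            errors.append({"row": int(i), "column": col, "value": src.iloc[i]})

    keep = ~(bad_weight | bad_date | bad_dob)
    out = pd.DataFrame(
        {
            "animal_id": df["animal_id"],
            "species": df["species"],
            "sex": df["sex"].replace("", "unknown"),
            "dob": dob,
            "date": date,
            "weight_kg": weight,
            "invoice_id": df["invoice_id"].replace("", pd.NA),
            "practice_id": df["practice_id"],
            "group_id": df["group_id"],
        }
    )[keep].reset_index(drop=True)
    return out, pd.DataFrame(errors, columns=["row", "column", "value"])


def write_records(records: pd.DataFrame, path) -> None:
    """Write records as CSV with ISO-8601 dates (inverse of read_records)."""
    out = records.copy()
    for c in ("dob", "date"):
        out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, columns=RECORD_COLUMNS)


def _log_entries(df: pd.DataFrame, rule: str, stage: str, value) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rule_id": rule,
            "stage": stage,
            "animal_id": df["animal_id"].to_numpy(),
            "date": df["date"].to_numpy(),
            "value": np.asarray(value),
        }
    )


def apply_exclusions(
    records: pd.DataFrame,
    limits: dict[str, SpeciesLimits] | None = None,
    require_invoice: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the plausibility and completeness exclusion rules.

    Removes, in order: records without an invoice id (when ``require_invoice``),
    all records of animals lacking a date of birth, records with weight or age
    outside the species plausibility range, and the later record of any
    consecutive pair whose monthly-equivalent growth ratio
    ``(w2/w1)**(1/max(I, 1))`` exceeds the species jump factor (``I`` in
    months).  Jump comparisons always use the previous *retained* record.

    Returns ``(retained, log)`` where the log holds one row per removed record
    (columns rule_id, stage, animal_id, date, value) so that row counts are
    conserved.
    """
    if limits is None:
        limits = default_limits()
    unknown = set(records["species"].unique()) - set(limits)
    if unknown:
        raise ValueError(f"no limits defined for species: {sorted(unknown)}")

    df = records.reset_index(drop=True)
    logs = []

    if require_invoice:
        bad = df["invoice_id"].isna()
        logs.append(_log_entries(df[bad], "missing_invoice", "invoice", ""))
        df = df[~bad]

    bad = df["dob"].isna()
    logs.append(_log_entries(df[bad], "missing_dob", "completeness", ""))
    df = df[~bad]

    wmin = df["species"].map({s: l.weight_min_kg for s, l in limits.items()})
    wmax = df["species"].map({s: l.weight_max_kg for s, l in limits.items()})
    bad = (df["weight_kg"] < wmin) | (df["weight_kg"] > wmax)
    logs.append(
        _log_entries(df[bad], "weight_range", "plausibility", df.loc[bad, "weight_kg"])
    )
    df = df[~bad]

    # closed interval at day precision: age in years from exact day counts
    age_y = (df["date"] - df["dob"]).dt.days / 365.25
    amin = df["species"].map({s: l.age_min_y for s, l in limits.items()})
    amax = df["species"].map({s: l.age_max_y for s, l in limits.items()})
    bad = (age_y < amin) | (age_y > amax)
    logs.append(_log_entries(df[bad], "age_range", "plausibility", age_y[bad].round(3)))
    df = df[~bad]

    drop_idx, drop_val = _jump_violations(df, limits)
    bad = df.index.isin(drop_idx)
    logs.append(_log_entries(df.loc[drop_idx], "growth_jump", "jump", drop_val))
    df = df[~bad]

    logs = [l for l in logs if len(l)]
    cols = ["rule_id", "stage", "animal_id", "date", "value"]
    log = (
        pd.concat(logs, ignore_index=True)
        if logs
        else pd.DataFrame(columns=cols)
    )
    return df.reset_index(drop=True), log


def _jump_violations(
    df: pd.DataFrame, limits: dict[str, SpeciesLimits]
) -> tuple[list, list]:
    """Indices (and offending ratios) of records violating the jump rule."""
    jf = df["species"].map({s: l.jump_factor for s, l in limits.items()}).to_numpy()
    order = df.sort_values(["animal_id", "date"], kind="stable")
    idx = order.index.to_numpy()
    animal = order["animal_id"].to_numpy()
    days = order["date"].astype("int64").to_numpy() // 86_400_000_000_000
    w = order["weight_kg"].to_numpy()
    jfo = jf[df.index.get_indexer(order.index)]

    drop, vals = [], []
    i = 0
    n = len(order)
    while i < n:
        j = i
        last_w, last_d = w[i], days[i]
        j += 1
        while j < n and animal[j] == animal[i]:
            interval = max((days[j] - last_d) / DAYS_PER_MONTH, 1.0)
            ratio = (w[j] / last_w) ** (1.0 / interval)
            if ratio > jfo[j]:
                drop.append(idx[j])
                vals.append(round(float(ratio), 4))
            else:
                last_w, last_d = w[j], days[j]
            j += 1
        i = j
    return drop, vals


def build_growth_pairs(records: pd.DataFrame, max_age_months: float) -> pd.DataFrame:
    """Consecutive-measurement proportional-gain observations.

    For each animal, measurements sorted by date yield pairs
    ``(w1 at age A, w2 at age A + I)`` with proportional gain
    ``g = (w2 - w1)/w1``; ``A`` is the age at the *earlier* measurement.  Pairs
    are kept when ``A <= max_age_months`` and ``I > 0``; same-day duplicate
    measurements keep the last-entered record.  Animals with fewer than two
    usable records contribute nothing.

    Returns a DataFrame with columns animal_id, age_months, interval_months,
    prop_gain.
    """
    df = records.dropna(subset=["dob"]).sort_values(
        ["animal_id", "date"], kind="stable"
    )
    df = df.drop_duplicates(subset=["animal_id", "date"], keep="last")
    same = df["animal_id"].to_numpy()[1:] == df["animal_id"].to_numpy()[:-1]
    age = _ages_months(df["dob"], df["date"]).to_numpy()
    w = df["weight_kg"].to_numpy()
    a1, a2 = age[:-1][same], age[1:][same]
    w1, w2 = w[:-1][same], w[1:][same]
    ids = df["animal_id"].to_numpy()[:-1][same]
    interval = a2 - a1
    keep = (a1 <= max_age_months) & (interval > 0)
    return pd.DataFrame(
        {
            "animal_id": ids[keep],
            "age_months": a1[keep],
            "interval_months": interval[keep],
            "prop_gain": (w2[keep] - w1[keep]) / w1[keep],
            "weight_kg": w1[keep],  # weight at the earlier measurement
        }
    )
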