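"""Annual point-mean population bodyweights with juvenile adjustment.

Stages 3--4 of the pipeline.  For each animal the latest recorded bodyweight
on or before 31 December of the reporting year is selected; juvenile weights
(age at measurement below the species juvenile bound) are projected forward by
the proportional-gain model over the interval from the measurement date to the
target date or the end of juvenile growth, whichever comes first; adult
weights enter unadjusted.  The point mean is the arithmetic mean of the
resulting per-animal estimates (one value per animal), with a normal-
approximation confidence interval, alongside two comparison statistics: the
period mean of the raw latest weights (full population) and the adults-only
period mean (animals over an age cutoff, default 24 months).  Group
consistency is assessed with Kruskal-Wallis tests across practices or
veterinary groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cessation import CessationEstimate
from .cohort import DAYS_PER_MONTH
from .growth_model import GrowthCoefficients, predict_gain

#: Hard floor (kg) applied to adjusted weights.
MIN_WEIGHT_KG = 0.01


@dataclass
class PointMeanReport:
    """One species-year row of the annual point-mean report."""

    species: str
    year: int
    n_practices: int
    n_animals: int
    n_juveniles: int
    point_mean_kg: float
    ci95_kg: tuple[float, float]
    period_mean_full_kg: float
    period_mean_adults_only_kg: float | None
    kruskal_wallis: dict = field(default_factory=dict)

    @property
    def pct_juveniles(self) -> float:
        return 100.0 * self.n_juveniles / self.n_animals

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "year": self.year,
            "n_practices": self.n_practices,
            "n_animals": self.n_animals,
            "n_juveniles": self.n_juveniles,
            "pct_juveniles": round(self.pct_juveniles, 2),
            "point_mean_kg": self.point_mean_kg,
            "ci95_kg": list(self.ci95_kg),
            "period_mean_full_kg": self.period_mean_full_kg,
            "period_mean_adults_only_kg": self.period_mean_adults_only_kg,
            "kruskal_wallis": self.kruskal_wallis,
        }


def latest_weight_per_animal(
    records: pd.DataFrame,
    year: int,
    max_juvenile_age_months: float,
    in_year_only: bool = True,
) -> pd.DataFrame:
    """One snapshot per animal: the latest record on or before 31 December.

    With ``in_year_only`` (the default) an animal is included only if it has a
    record dated within the calendar year; otherwise any record on or before
    31 December qualifies.  Same-day duplicates keep the last-entered record.

    Returns a snapshot DataFrame with columns animal_id, species, dob,
    last_weight_kg, last_date, age_at_last_months, is_juvenile,
    estimated_weight_kg (initially the unadjusted weight), practice_id,
    group_id.
    """
    end = pd.Timestamp(year=year, month=12, day=31)
    df = records[records["date"] <= end]
    if in_year_only:
        df = df[df["date"] >= pd.Timestamp(year=year, month=1, day=1)]
    df = df.sort_values(["animal_id", "date"], kind="stable")
    last = df.groupby("animal_id", sort=True).tail(1)
    age = (last["date"] - last["dob"]).dt.days / DAYS_PER_MONTH
    return pd.DataFrame(
        {
            "animal_id": last["animal_id"].to_numpy(),
            "species": last["species"].to_numpy(),
            "dob": last["dob"].to_numpy(),
            "last_weight_kg": last["weight_kg"].to_numpy(),
            "last_date": last["date"].to_numpy(),
            "age_at_last_months": age.to_numpy(),
            "is_juvenile": (age < max_juvenile_age_months).to_numpy(),
            "estimated_weight_kg": last["weight_kg"].to_numpy(),
            "practice_id": last["practice_id"].to_numpy(),
            "group_id": last["group_id"].to_numpy(),
        }
    )


def adjust_juveniles(
    snapshots: pd.DataFrame,
    coeffs: GrowthCoefficients,
    cessation: CessationEstimate | float,
    target_date,
) -> pd.DataFrame:
    """Project juvenile weights forward to the target date.

    For juvenile snapshots the adjustment interval is the time (months) from
    the last measurement to the earlier of the target date and the animal's
    end of juvenile growth (dob + cessation age), clamped at zero; the
    estimated weight is ``last_weight * (1 + predicted gain(age, interval))``,
    floored at 0.01 kg.  Adults are returned unchanged.  Raises when any
    snapshot postdates the target.
    """
    target = pd.Timestamp(target_date)
    out = snapshots.copy()
    if (pd.to_datetime(out["last_date"]) > target).any():
        raise ValueError("snapshot measurement after target date")
    juv = out["is_juvenile"].to_numpy()
    if not juv.any():
        return out
    cess_months = (
        cessation.age_months if isinstance(cessation, CessationEstimate) else cessation
    )
    dob = pd.to_datetime(out.loc[juv, "dob"])
    cess_date = dob + pd.to_timedelta(
        np.round(cess_months * DAYS_PER_MONTH), unit="D"
    )
    end = cess_date.clip(upper=target)
    interval = (
        (end - pd.to_datetime(out.loc[juv, "last_date"])).dt.days.clip(lower=0)
        / DAYS_PER_MONTH
    ).to_numpy()
    gain = predict_gain(
        coeffs, out.loc[juv, "age_at_last_months"].to_numpy(), interval
    )
    gain = np.where(interval > 0, gain, 0.0)
    est = out.loc[juv, "last_weight_kg"].to_numpy() * (1.0 + gain)
    if np.any(est < MIN_WEIGHT_KG):
        warnings.warn(
            f"{int((est < MIN_WEIGHT_KG).sum())} adjusted weight(s) floored at "
            f"{MIN_WEIGHT_KG} kg",
            RuntimeWarning,
        )
        est = np.maximum(est, MIN_WEIGHT_KG)
    out.loc[juv, "estimated_weight_kg"] = est
    return out


def compute_point_mean(snapshots: pd.DataFrame) -> dict:
    """Point mean of estimated weights with a 95% normal-approximation CI."""
    if snapshots.empty:
        raise ValueError("no snapshots")
    w = snapshots["estimated_weight_kg"].to_numpy(dtype=float)
    n = len(w)
    mean = float(np.mean(w))
    se = float(np.std(w, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    nj = int(snapshots["is_juvenile"].sum())
    return {
        "point_mean_kg": mean,
        "ci95_kg": (mean - 1.96 * se, mean + 1.96 * se),
        "n_animals": n,
        "n_juveniles": nj,
        "pct_juveniles": 100.0 * nj / n,
    }


def compute_period_means(
    snapshots: pd.DataFrame, adult_cutoff_months: float = 24.0
) -> tuple[float, float | None]:
    """Period mean of raw latest weights: full population and adults only.

    Adults are animals strictly older than ``adult_cutoff_months`` at their
    last measurement; with no adults the second value is ``None``.
    """
    if snapshots.empty:
        raise ValueError("no snapshots")
    full = float(snapshots["last_weight_kg"].mean())
    adults = snapshots[snapshots["age_at_last_months"] > adult_cutoff_months]
    adults_only = float(adults["last_weight_kg"].mean()) if len(adults) else None
    return full, adults_only


def compare_groups(snapshots: pd.DataFrame, grouping: str) -> dict:
    """Kruskal-Wallis test of estimated weights across practices or groups.

    ``grouping`` is 'practice' or 'group'.  Returns {'statistic', 'p',
    'n_groups'}; identical values in every group yield H = 0, p = 1.
    """
    col = {"practice": "practice_id", "group": "group_id"}[grouping]
    samples = [g.to_numpy() for _, g in snapshots.groupby(col)["estimated_weight_kg"]]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            stat, p = stats.kruskal(*samples)
    except ValueError:  # all values identical: no rank variation
        stat, p = 0.0, 1.0
    if not (np.isfinite(stat) and np.isfinite(p)):  # scipy yields nan on ties
        stat, p = 0.0, 1.0
    return {"statistic": float(stat), "p": float(p), "n_groups": len(samples)}


def annual_report(
    records: pd.DataFrame,
    coeffs: GrowthCoefficients,
    cessation: CessationEstimate | float,
    year: int,
    species: str,
    max_juvenile_age_months: float,
    adult_cutoff_months: float = 24.0,
    in_year_only: bool = True,
) -> PointMeanReport:
    """Assemble one species-year point-mean report row (Table-style output)."""
    recs = records[records["species"] == species]
    snaps = latest_weight_per_animal(
        recs, year, max_juvenile_age_months, in_year_only=in_year_only
    )
    if snaps.empty:
        raise ValueError(f"no records for {species} in {year}")
    target = pd.Timestamp(year=year, month=12, day=31)
    snaps = adjust_juveniles(snaps, coeffs, cessation, target)
    pm = compute_point_mean(snaps)
    full, adults_only = compute_period_means(snaps, adult_cutoff_months)
    kw = {}
    for grouping in ("practice", "group"):
        col = {"practice": "practice_id", "group": "group_id"}[grouping]
        if snaps[col].nunique() >= 2:
            kw[grouping] = compare_groups(snaps, grouping)
    return PointMeanReport(
        species=species,
        year=year,
        n_practices=int(snaps["practice_id"].nunique()),
        n_animals=pm["n_animals"],
        n_juveniles=pm["n_juveniles"],
        point_mean_kg=pm["point_mean_kg"],
        ci95_kg=pm["ci95_kg"],
        period_mean_full_kg=full,
        period_mean_adults_only_kg=adults_only,
        kruskal_wallis=kw,
    )


def dddvet_per_animal(
    total_drug_mg: float,
    dddvet_mg_per_kg_day: float,
    n_animals: int,
    mean_bodyweight_kg: float,
) -> float:
    """Average treatment-days per animal implied by total drug use.

    ``total_drug_mg / (dddvet_mg_per_kg_day * mean_bodyweight_kg * n_animals)``:
    inversely proportional to the total population bodyweight at risk, which
    is why an unbiased point-mean bodyweight matters for usage surveillance.
    """
    for name, v in [
        ("total_drug_mg", total_drug_mg),
        ("dddvet_mg_per_kg_day", dddvet_mg_per_kg_day),
        ("n_animals", n_animals),
        ("mean_bodyweight_kg", mean_bodyweight_kg),
    ]:
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    return total_drug_mg / (dddvet_mg_per_kg_day * mean_bodyweight_kg * n_animals)
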