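"""Juvenile growth cessation from smoothed bodyweight-age curves.

Stage 1 of the pipeline: a loess smoother of bodyweight against age (months),
with its span selected by AICc or GCV, is evaluated on a 0.05-month grid; the
end of juvenile growth is the earliest grid age at which the predicted
per-step weight increment reaches zero.  Exact zero never occurs in
floating-point smoother output, so an increment at or below a small tolerance
(default 1e-4 kg per 0.05-month step, far below measurement noise) counts as
zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .loess import LoessSmoother, select_span

#: Age-grid resolution (months) at which the increment is examined.
GRID_STEP = 0.05

#: Per-step weight increment (kg) at or below which growth counts as ceased.
ZERO_TOLERANCE_KG = 1e-4

#: Default cap on points entering the smoother; above it a seeded uniform
#: subsample is taken.
DEFAULT_SUBSAMPLE = 4000


class NoPlateauError(ValueError):
    """The smoothed curve never stops increasing within the fitted grid."""


@dataclass
class LoessFit:
    """A span-selected loess fit of bodyweight on age, on the 0.05-month grid."""

    span: float
    degree: int
    criterion: str
    criterion_value: float
    grid_ages: np.ndarray
    grid_weights: np.ndarray
    n_points: int


@dataclass
class CessationEstimate:
    """Age (months) at the end of juvenile growth for one species."""

    age_months: float
    method: str  # "loess" or "model_solve"
    species: str | None = None
    resolution_months: float = GRID_STEP
    detail: dict = field(default_factory=dict)


def fit_loess(
    ages,
    weights,
    criterion: str = "aicc",
    degree: int = 1,
    subsample: int | None = DEFAULT_SUBSAMPLE,
    seed: int = 0,
    grid_max_months: float | None = None,
    bin_months: float | None = GRID_STEP,
    point_weights=None,
) -> LoessFit:
    """Fit a loess curve of weight (kg) on age (months), selecting the span.

    By default records are first aggregated to mean weight per 0.05-month age
    bin and the smoother is fit to the bin means: between-animal weight
    variance (large in heterogeneous species) is averaged down before
    smoothing, so the whole data set informs the curve at a cost independent
    of record count.  Set ``bin_months=None`` to smooth raw records, in which
    case inputs beyond ``subsample`` points are uniformly subsampled (seeded).

    The span minimising ``criterion`` ('aicc' or 'gcv') over [0.05, 0.95] is
    chosen by a coarse scan followed by golden-section refinement.  Fitted
    values are evaluated on the 0.05-month grid from 0 to
    ``min(max observed age, 60)`` months (overridable).
    """
    ages = np.asarray(ages, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if len(ages) < 50:
        raise ValueError("need at least 50 points for span selection")
    if np.any(ages < 0):
        raise ValueError("ages must be non-negative")
    counts = None if point_weights is None else np.asarray(point_weights, float)
    if bin_months is not None and point_weights is None:
        idx = np.floor(ages / bin_months).astype(np.int64)
        full_counts = np.bincount(idx)
        sums = np.bincount(idx, weights=weights)
        nonzero = full_counts > 0
        ages = (np.arange(len(full_counts))[nonzero] + 0.5) * bin_months
        weights = sums[nonzero] / full_counts[nonzero]
        counts = full_counts[nonzero].astype(float)
    if subsample is not None and len(ages) > subsample:
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(ages), size=subsample, replace=False)
        ages, weights = ages[pick], weights[pick]
        if counts is not None:
            counts = counts[pick]

    span, value = select_span(
        ages, weights, criterion=criterion, degree=degree, weights=counts
    )
    sm = LoessSmoother(ages, weights, span, degree, counts)
    top = grid_max_months if grid_max_months is not None else min(ages.max(), 60.0)
    grid = np.round(np.arange(0.0, top + GRID_STEP / 2, GRID_STEP), 10)
    grid = grid[grid <= ages.max()]  # boundary windows extrapolate below min age
    return LoessFit(
        span=span,
        degree=degree,
        criterion=criterion,
        criterion_value=value,
        grid_ages=grid,
        grid_weights=sm.predict(grid),
        n_points=len(ages),
    )


def detect_cessation(
    fit: LoessFit,
    tolerance_kg: float = ZERO_TOLERANCE_KG,
    species: str | None = None,
    min_grid_cover_months: float = 24.0,
    curve: str = "weight",
) -> CessationEstimate:
    """Earliest grid age at which the per-step weight increment reaches zero.

    With ``curve='weight'`` the fit is a bodyweight-vs-age curve and the scan
    finds the first grid age ``a`` with
    ``predicted(a + 0.05) - predicted(a) <= tolerance_kg``.  With
    ``curve='gain'`` the fit is already a monthly-growth curve (kg/month vs
    age) and the scan finds the first grid age whose predicted change per
    0.05-month step, ``predicted(a) * 0.05``, is at or below the tolerance.
    Raises :class:`NoPlateauError` when growth never ceases on the grid.  The
    fitted grid must cover at least ``[0, min_grid_cover_months]``.
    """
    g = fit.grid_ages
    if g[0] > GRID_STEP or g[-1] < min_grid_cover_months:
        raise ValueError(
            f"fitted grid [{g[0]}, {g[-1]}] must cover [0, {min_grid_cover_months}]"
        )
    if curve == "weight":
        step_change = np.diff(fit.grid_weights)
        grid = g[:-1]
    elif curve == "gain":
        step_change = fit.grid_weights * GRID_STEP
        grid = g
    else:
        raise ValueError("curve must be 'weight' or 'gain'")
    hits = np.flatnonzero(step_change <= tolerance_kg)
    if hits.size == 0:
        raise NoPlateauError("predicted increments positive over the whole grid")
    age = float(grid[hits[0]])
    return CessationEstimate(
        age_months=age,
        method="loess",
        species=species,
        resolution_months=GRID_STEP,
        detail={"span": fit.span, "criterion": fit.criterion, "n_points": fit.n_points},
    )


def monthly_gain_points(
    records, max_interval_months: float = 2.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-animal consecutive-pair monthly bodyweight change versus age.

    For each animal's consecutive measurements (w1 at age a, w2 at age a + I,
    0 < I <= ``max_interval_months``) the point is (a, (w2 - w1)/I): the mean
    growth rate in kg/month attributed to the age at the earlier measurement
    (the same convention the growth-pair model uses), with precision weight
    I^2 (the derivative noise of multiplicative measurement error scales as
    1/I).  Differencing within animals removes between-animal size variation,
    which otherwise swamps the growth signal near the plateau; start-age
    attribution keeps the curve exactly zero beyond the plateau onset, and
    longer intervals are excluded because they smear the growth rate across
    it.

    Returns ``(start_ages, gains_kg_per_month, weights)``.
    """
    from .cohort import build_growth_pairs

    pairs = build_growth_pairs(records, max_age_months=np.inf)
    pairs = pairs[pairs["interval_months"] <= max_interval_months]
    a = pairs["age_months"].to_numpy()
    i = pairs["interval_months"].to_numpy()
    gain_kg = pairs["prop_gain"].to_numpy() * pairs["weight_kg"].to_numpy()
    return a, gain_kg / i, i**2


def estimate_cessation(
    records,
    species: str | None = None,
    criterion: str = "aicc",
    degree: int = 1,
    seed: int = 0,
    tolerance_kg: float = ZERO_TOLERANCE_KG,
    grid_max_months: float | None = None,
) -> tuple[CessationEstimate, LoessFit]:
    """Loess estimate of growth cessation from a cleaned record table.

    Builds per-animal monthly-growth points (see :func:`monthly_gain_points`),
    smooths them against age with a span-selected loess on 0.05-month bin
    means (bin-count weighted), and returns the earliest grid age at which
    the predicted interval change in bodyweight reaches zero.
    """
    ages, gains, pw = monthly_gain_points(records)
    if len(ages) < 50:
        raise ValueError("need at least 50 growth pairs")
    # aggregate to 0.05-month bins: precision-weighted bin means, with loess
    # weights equal to each bin's effective (Kish) pair count
    idx = np.floor(ages / GRID_STEP).astype(np.int64)
    u = np.bincount(idx, weights=pw)
    u2 = np.bincount(idx, weights=pw**2)
    nz = u > 0
    mean = np.bincount(idx, weights=pw * gains)[nz] / u[nz]
    count = np.bincount(idx)[nz].astype(float)
    n_eff = u[nz] ** 2 / np.maximum(u2[nz], 1e-300)  # Kish effective size
    bin_ages = (np.flatnonzero(nz) + 0.5) * GRID_STEP

    # fit on the pair-count CDF scale: nearest-neighbour windows then carry
    # constant pair mass, giving narrow bandwidths in the dense juvenile
    # region and wide ones on the sparsely sampled plateau
    cdf = np.cumsum(count)
    cdf = (cdf - count / 2.0) / cdf[-1]
    span, value = select_span(
        cdf, mean, criterion=criterion, degree=degree, weights=n_eff
    )
    sm = LoessSmoother(cdf, mean, span, degree, n_eff)
    top = grid_max_months if grid_max_months is not None else min(ages.max(), 60.0)
    grid = np.round(np.arange(0.0, top + GRID_STEP / 2, GRID_STEP), 10)
    grid = grid[grid <= ages.max()]
    grid_cdf = np.interp(grid, bin_ages, cdf)
    fit = LoessFit(
        span=span,
        degree=degree,
        criterion=criterion,
        criterion_value=value,
        grid_ages=grid,
        grid_weights=sm.predict(grid_cdf),
        n_points=len(ages),
    )
    est = detect_cessation(fit, tolerance_kg=tolerance_kg, species=species,
                           curve="gain")
    return est, fit
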