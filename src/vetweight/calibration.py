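"""Development-window calibration and model validation statistics.

The growth model's solved cessation age depends on the maximum age of animals
admitted to the development data: including older animals pushes the solved
cessation later.  :func:`calibrate_max_age` exploits this monotonicity with a
binary search over integer maximum ages so that the model-solved cessation
matches the loess estimate obtained from observed data.

Model fit quality is quantified by calibration-in-the-large (mean observed
minus mean predicted gain), the calibration slope (coefficient of observed on
predicted gain), and bootstrap optimism (animals resampled with replacement).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cessation import CessationEstimate
from .growth_model import (
    ConvergenceError,
    GrowthCoefficients,
    NoRootError,
    backward_select,
    fit_growth_model,
    predict_gain,
    solve_cessation,
    variance_partition,
)


@dataclass
class CalibrationResult:
    """Outcome of the development-window binary search."""

    max_dev_age_months: int
    solved_cessation_months: float
    loess_target_months: float
    iterations: list = field(default_factory=list)  # (candidate age, solved cessation)
    converged: bool = True


@dataclass
class ModelValidationReport:
    """Calibration statistics of a fitted gain model on validation pairs."""

    citl: float
    slope: float
    slope_ci: tuple[float, float]
    vpc: float
    calibration_deciles: pd.DataFrame | None = None
    optimism_citl: float | None = None
    optimism_slope: float | None = None


def _search_monotone(solved, lo: int, hi: int, target: float) -> tuple[int, bool]:
    """Binary search for the integer whose (cached) monotone value is closest
    to ``target``; ties go to the smaller integer.

    Returns ``(best, monotone_ok)`` where ``monotone_ok`` reports whether the
    probed values were consistent with a nondecreasing sequence.
    """
    cache: dict[int, float] = {}

    def f(M: int) -> float:
        if M not in cache:
            cache[M] = solved(M)
        return cache[M]

    a, b = lo, hi
    while a < b:
        mid = (a + b) // 2
        if f(mid) < target:
            a = mid + 1
        else:
            b = mid
    candidates = sorted({M for M in (a - 1, a, a + 1) if lo <= M <= hi})
    best = min(candidates, key=lambda M: (abs(f(M) - target), M))
    probed = sorted(cache)
    vals = [cache[M] for M in probed]
    monotone = all(v2 >= v1 - 1e-9 for v1, v2 in zip(vals, vals[1:]))
    return best, monotone


def calibrate_max_age(
    pairs_all: pd.DataFrame,
    loess_target: CessationEstimate,
    bounds: tuple[int, int] | None = None,
    interval: float = 1.0,
    search_max: float = 60.0,
) -> tuple[CalibrationResult, GrowthCoefficients]:
    """Choose the development max age whose solved cessation matches the target.

    For each probed integer max age ``M`` the model (term set frozen to the
    backward-selection result at the upper bound) is refit on pairs with age
    <= ``M`` and its cessation solved at the given interval.  A binary search
    exploits the monotone increase of solved cessation in ``M``; the returned
    ``M`` minimises ``|solved - target|`` (ties to the smaller ``M``).  A
    detected non-monotone probe sequence triggers an exhaustive scan with a
    warning.  An ``M`` with no root counts as "solved above target".

    Default bounds are ``[ceil(target) + 1, 72]`` months.
    """
    target = loess_target.age_months
    if bounds is None:
        bounds = (int(math.ceil(target)) + 1, 72)
    lo, hi = int(bounds[0]), int(bounds[1])
    if lo > hi:
        raise ValueError("empty bounds")
    if lo < math.ceil(target):
        raise ValueError("lower bound must be >= ceil(loess target)")

    mask = tuple(
        t
        for t, on in backward_select(
            pairs_all[pairs_all["age_months"] <= hi], final_reml=False
        ).included_terms.items()
        if on
    )

    cache: dict[int, float] = {}
    iterations: list[tuple[int, float]] = []

    def solved(M: int) -> float:
        if M not in cache:
            sub = pairs_all[pairs_all["age_months"] <= M]
            try:
                fit = fit_growth_model(sub, mask)
                cache[M] = solve_cessation(fit, interval, search_max).age_months
            except (NoRootError, ConvergenceError):
                cache[M] = np.inf  # treated as solved above target
            iterations.append((M, cache[M]))
        return cache[M]

    if lo == hi:
        best = lo
        solved(best)
    else:
        best, monotone = _search_monotone(solved, lo, hi, target)
        if not monotone:
            warnings.warn(
                "solved cessation not monotone in max age; falling back to "
                "exhaustive scan",
                RuntimeWarning,
            )
            for M in range(lo, hi + 1):
                solved(M)
            best = min(range(lo, hi + 1), key=lambda M: (abs(solved(M) - target), M))

    final = fit_growth_model(
        pairs_all[pairs_all["age_months"] <= best],
        mask,
        reml=True,
        max_valid_age_months=None,
    )
    final.aic = np.nan
    result = CalibrationResult(
        max_dev_age_months=int(best),
        solved_cessation_months=cache[best],
        loess_target_months=target,
        iterations=iterations,
        converged=bool(np.isfinite(cache[best])),
    )
    return result, final


def compute_calibration(
    coeffs: GrowthCoefficients,
    validation_pairs: pd.DataFrame,
    deciles: bool = True,
) -> ModelValidationReport:
    """Calibration slope, CITL and decile plot data on validation pairs.

    Slope is the coefficient of observed gain regressed on predicted gain
    (with intercept); CITL is mean(observed) - mean(predicted).
    """
    pred = predict_gain(
        coeffs,
        validation_pairs["age_months"].to_numpy(),
        validation_pairs["interval_months"].to_numpy(),
        validate_age=False,
    )
    obs = validation_pairs["prop_gain"].to_numpy(dtype=float)
    if len(np.unique(pred)) < 2:
        raise ValueError("need at least 2 distinct predicted values")
    ols = sm.OLS(obs, sm.add_constant(pred)).fit()
    ci = ols.conf_int()[1]
    dec = None
    if deciles:
        q = pd.qcut(pred, 10, duplicates="drop")
        dec = (
            pd.DataFrame({"pred": pred, "obs": obs, "decile": q})
            .groupby("decile", observed=True)
            .agg(mean_predicted=("pred", "mean"), mean_observed=("obs", "mean"),
                 n=("obs", "size"))
            .reset_index(drop=True)
        )
    return ModelValidationReport(
        citl=float(np.mean(obs) - np.mean(pred)),
        slope=float(ols.params[1]),
        slope_ci=(float(ci[0]), float(ci[1])),
        vpc=variance_partition(coeffs),
        calibration_deciles=dec,
    )


@dataclass
class OptimismEstimate:
    """Mean bootstrap optimism of the calibration statistics."""

    optimism_slope: float
    optimism_citl: float
    reps_used: int
    reps_failed: int


def _performance(coeffs: GrowthCoefficients, pairs: pd.DataFrame) -> tuple[float, float]:
    rep = compute_calibration(coeffs, pairs, deciles=False)
    return rep.slope, rep.citl


def bootstrap_optimism(
    pairs: pd.DataFrame,
    reps: int = 500,
    frac: float = 0.01,
    seed: int = 0,
    terms: tuple[str, ...] | None = None,
) -> OptimismEstimate:
    """Bootstrap optimism of slope and CITL, resampling animals.

    Each repetition samples ``ceil(frac * n_animals)`` animals with
    replacement (resampled animals keep distinct group identities), refits the
    model with the given term set, and records apparent performance (on the
    bootstrap sample) minus performance on the original data.  Failed
    repetition fits are skipped and counted.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    rng = np.random.default_rng(seed)
    animals = pairs["animal_id"].unique()
    m = int(math.ceil(frac * len(animals)))
    grouped = dict(tuple(pairs.groupby("animal_id", sort=False)))

    opt_slope, opt_citl, failed = [], [], 0
    for _ in range(reps):
        chosen = rng.choice(animals, size=m, replace=True)
        sampled = []
        for j, a in enumerate(chosen):
            g = grouped[a].copy()
            g["animal_id"] = f"bs{j}"
            sampled.append(g)
        boot = pd.concat(sampled, ignore_index=True)
        try:
            fit = fit_growth_model(boot, terms)
            s_app, c_app = _performance(fit, boot)
            s_orig, c_orig = _performance(fit, pairs)
        except (ConvergenceError, ValueError):
            failed += 1
            continue
        opt_slope.append(s_app - s_orig)
        opt_citl.append(c_app - c_orig)
    if not opt_slope:
        raise ConvergenceError("all bootstrap repetitions failed")
    return OptimismEstimate(
        optimism_slope=float(np.mean(opt_slope)),
        optimism_citl=float(np.mean(opt_citl)),
        reps_used=len(opt_slope),
        reps_failed=failed,
    )
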