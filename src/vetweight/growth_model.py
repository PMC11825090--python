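"""Mixed-effects model of proportional juvenile bodyweight gain.

Stage 2 of the pipeline.  The outcome is the proportional gain
``g = (w2 - w1)/w1`` between consecutive measurements of one animal; the
predictors are the age ``A`` (months) at the earlier measurement and the
interval ``I`` (months) between the pair, entered as cubic polynomials with an
``A x I`` interaction:

    g = b0 + bA A + bA2 A^2 + bA3 A^3 + bI I + bI2 I^2 + bI3 I^3 + bAI A I
        + u_animal + e

with a random intercept per animal.  Backward selection drops terms by AIC
(maximum-likelihood fits for comparability) under a marginality constraint; the
final model is refit by REML.  The age at which growth ceases is the smallest
positive root of the fixed-effect polynomial at a one-month interval, found
numerically by a fine grid scan plus bisection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cessation import CessationEstimate

#: Canonical term order (fixed effects beyond the intercept).
TERMS = ("age", "age2", "age3", "interval", "interval2", "interval3", "age_x_interval")

#: Higher-order partners that must be absent before a term may be dropped.
_MARGINALITY = {
    "age": ("age2", "age3", "age_x_interval"),
    "age2": ("age3",),
    "age3": (),
    "interval": ("interval2", "interval3", "age_x_interval"),
    "interval2": ("interval3",),
    "interval3": (),
    "age_x_interval": (),
}


class ConvergenceError(RuntimeError):
    """The mixed-model fit failed or produced a singular solution."""


@dataclass
class GrowthCoefficients:
    """Fitted proportional-gain model: fixed effects, variances, bookkeeping.

    Excluded terms carry coefficient exactly 0 and ``included_terms`` False.
    ``var_animal`` is the random-intercept variance, ``var_resid`` the residual
    variance; ``aic`` is from the maximum-likelihood fit of the same term set.
    """

    intercept: float
    age: float = 0.0
    age2: float = 0.0
    age3: float = 0.0
    interval: float = 0.0
    interval2: float = 0.0
    interval3: float = 0.0
    age_x_interval: float = 0.0
    included_terms: dict = field(default_factory=lambda: {t: True for t in TERMS})
    var_animal: float = 0.0
    var_resid: float = 1.0
    aic: float = np.nan
    n_pairs: int = 0
    n_animals: int = 0
    max_valid_age_months: float | None = None
    fe_se: dict | None = None  # standard errors of included fixed effects

    def __post_init__(self) -> None:
        if self.var_animal < 0 or self.var_resid <= 0:
            raise ValueError("variances must satisfy var_animal >= 0, var_resid > 0")
        for t in TERMS:
            if not self.included_terms.get(t, False) and getattr(self, t) != 0.0:
                raise ValueError(f"excluded term {t} has non-zero coefficient")

    def to_json(self, path=None) -> str:
        payload = {
            "coefficients": {"intercept": self.intercept}
            | {t: getattr(self, t) for t in TERMS},
            "included_terms": self.included_terms,
            "var_animal": self.var_animal,
            "var_resid": self.var_resid,
            "aic": None if np.isnan(self.aic) else self.aic,
            "n_pairs": self.n_pairs,
            "n_animals": self.n_animals,
            "max_valid_age_months": self.max_valid_age_months,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "GrowthCoefficients":
        """Load coefficients from a JSON file path or string.

        Accepts hand-written files that provide only ``coefficients``; terms
        absent from the file are treated as excluded.
        """
        try:
            payload = json.loads(source)
        except (json.JSONDecodeError, TypeError):
            with open(source) as fh:
                payload = json.load(fh)
        coef = payload["coefficients"]
        included = payload.get(
            "included_terms", {t: t in coef and coef[t] != 0 for t in TERMS}
        )
        return cls(
            intercept=float(coef["intercept"]),
            **{t: float(coef.get(t, 0.0)) for t in TERMS},
            included_terms={t: bool(included.get(t, False)) for t in TERMS},
            var_animal=float(payload.get("var_animal", 0.0)),
            var_resid=float(payload.get("var_resid", 1.0)),
            aic=float(payload["aic"]) if payload.get("aic") is not None else np.nan,
            n_pairs=int(payload.get("n_pairs", 0)),
            n_animals=int(payload.get("n_animals", 0)),
            max_valid_age_months=payload.get("max_valid_age_months"),
        )


#: Internal predictor scale (months are divided by this before fitting) to
#: keep the cubic design well conditioned; coefficients are mapped back.
_SCALE = 12.0

_TERM_SCALE = {
    "age": _SCALE,
    "age2": _SCALE**2,
    "age3": _SCALE**3,
    "interval": _SCALE,
    "interval2": _SCALE**2,
    "interval3": _SCALE**3,
    "age_x_interval": _SCALE**2,
}


def _design(pairs: pd.DataFrame, terms: tuple[str, ...]) -> np.ndarray:
    A = pairs["age_months"].to_numpy(dtype=float) / _SCALE
    I = pairs["interval_months"].to_numpy(dtype=float) / _SCALE
    cols = {
        "age": A,
        "age2": A**2,
        "age3": A**3,
        "interval": I,
        "interval2": I**2,
        "interval3": I**3,
        "age_x_interval": A * I,
    }
    X = np.column_stack([np.ones(len(pairs))] + [cols[t] for t in terms])
    return X


def _profiled_lmm(
    X: np.ndarray, y: np.ndarray, groups: np.ndarray, reml: bool
) -> tuple[np.ndarray, np.ndarray, float, float, float]:
    """Exact ML/REML fit of a random-intercept linear mixed model.

    For a single random intercept the covariance is V = sigma_e^2 (I + lam J)
    per group (lam = sigma_u^2 / sigma_e^2), and GLS reduces to partial
    demeaning: subtracting theta_g = 1 - 1/sqrt(1 + lam n_g) times the group
    mean from every column.  The profile (restricted) log-likelihood is then
    a smooth 1-d function of lam, maximised numerically.

    Returns ``(beta, se, var_u, var_e, llf)``.
    """
    codes = pd.factorize(groups)[0]
    counts = np.bincount(codes).astype(float)
    n, p = X.shape

    ysum = np.bincount(codes, weights=y)

    def transform(lam: float):
        theta = 1.0 - 1.0 / np.sqrt(1.0 + lam * counts)
        w = (theta / counts)[codes]
        yt = y - w * ysum[codes]
        Xt = X - w[:, None] * np.vstack(
            [np.bincount(codes, weights=X[:, j]) for j in range(p)]
        ).T[codes]
        return yt, Xt

    def neg_ll(lam: float) -> float:
        yt, Xt = transform(lam)
        beta, rss_, _, _ = np.linalg.lstsq(Xt, yt, rcond=None)
        resid = yt - Xt @ beta
        rss = float(resid @ resid)
        logdet_v = float(np.sum(np.log1p(lam * counts)))
        if reml:
            sign, logdet_x = np.linalg.slogdet(Xt.T @ Xt)
            if sign <= 0:
                return np.inf
            df = n - p
            return 0.5 * (df * np.log(rss / df) + logdet_v + logdet_x)
        return 0.5 * (n * np.log(rss / n) + logdet_v)

    from scipy.optimize import minimize_scalar

    res = minimize_scalar(neg_ll, bounds=(0.0, 50.0), method="bounded",
                          options={"xatol": 1e-8})
    lam = float(res.x) if res.fun <= neg_ll(0.0) else 0.0

    yt, Xt = transform(lam)
    XtX = Xt.T @ Xt
    beta, _, rank, _ = np.linalg.lstsq(Xt, yt, rcond=None)
    if rank < p or not np.all(np.isfinite(beta)):
        raise ConvergenceError("singular design in mixed model fit")
    resid = yt - Xt @ beta
    rss = float(resid @ resid)
    df = (n - p) if reml else n
    var_e = rss / df
    var_u = lam * var_e
    se = np.sqrt(np.diag(var_e * np.linalg.inv(XtX)))
    logdet_v = float(np.sum(np.log1p(lam * counts)))
    if reml:
        _, logdet_x = np.linalg.slogdet(XtX)
        llf = -0.5 * (
            (n - p) * (np.log(2 * np.pi * var_e) + 1.0) + logdet_v + logdet_x
            - p * np.log(var_e)
        )
    else:
        llf = -0.5 * (n * (np.log(2 * np.pi * var_e) + 1.0) + logdet_v)
    return beta, se, var_u, var_e, float(llf)


def fit_growth_model(
    pairs: pd.DataFrame,
    terms: tuple[str, ...] | None = None,
    reml: bool = False,
    max_valid_age_months: float | None = None,
) -> GrowthCoefficients:
    """Fit the proportional-gain mixed model with the given fixed-effect terms.

    ``terms`` is an ordered subset of :data:`TERMS` (default: all).  Fitting
    is by ML (AIC-comparable) unless ``reml=True``, via the exact profiled
    random-intercept solver (:func:`_profiled_lmm`).  Raises
    :class:`ConvergenceError` on singular or failed fits.
    """
    if terms is None:
        terms = TERMS
    terms = tuple(t for t in TERMS if t in terms)
    if pairs["animal_id"].nunique() < 2:
        raise ValueError("need pairs from at least 2 animals")
    X = _design(pairs, terms)
    y = pairs["prop_gain"].to_numpy(dtype=float)
    groups = pairs["animal_id"].to_numpy()
    try:
        beta, se, var_u, var_e, llf = _profiled_lmm(X, y, groups, reml)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError(f"mixed model fit failed: {exc}") from exc

    k = len(terms) + 1 + 2  # fixed effects + intercept variance + residual
    aic = float(-2.0 * llf + 2.0 * k) if not reml else np.nan
    names = ["intercept"] + list(terms)
    betas = dict(zip(names, map(float, beta)))
    ses = dict(zip(names, map(float, se)))
    for t in terms:  # undo the internal predictor scaling
        betas[t] /= _TERM_SCALE[t]
        ses[t] /= _TERM_SCALE[t]
    return GrowthCoefficients(
        intercept=betas["intercept"],
        **{t: betas.get(t, 0.0) for t in TERMS},
        included_terms={t: t in terms for t in TERMS},
        var_animal=max(var_u, 0.0),
        var_resid=float(var_e),
        aic=aic,
        n_pairs=len(pairs),
        n_animals=int(pairs["animal_id"].nunique()),
        max_valid_age_months=max_valid_age_months,
        fe_se=ses,
    )


def backward_select(
    pairs: pd.DataFrame,
    max_valid_age_months: float | None = None,
    final_reml: bool = True,
) -> GrowthCoefficients:
    """AIC backward selection over the polynomial terms, then a REML refit.

    Starting from the full term set, repeatedly drops the term whose removal
    most reduces the ML AIC, never removing a term while a higher-order or
    interaction partner remains (marginality), until no removal reduces AIC.
    The final term set is refit by REML (its ML AIC is retained for record).
    """
    current = set(TERMS)
    fit = fit_growth_model(pairs, tuple(current))
    while True:
        droppable = [
            t for t in current if not any(p in current for p in _MARGINALITY[t])
        ]
        best_t, best_fit = None, None
        for t in droppable:
            try:
                cand = fit_growth_model(pairs, tuple(current - {t}))
            except ConvergenceError:
                continue
            if cand.aic < fit.aic and (best_fit is None or cand.aic < best_fit.aic):
                best_t, best_fit = t, cand
        if best_t is None:
            break
        current.discard(best_t)
        fit = best_fit
    if final_reml:
        final = fit_growth_model(
            pairs, tuple(current), reml=True, max_valid_age_months=max_valid_age_months
        )
        final.aic = fit.aic
        return final
    fit.max_valid_age_months = max_valid_age_months
    return fit


def predict_gain(
    coeffs: GrowthCoefficients, age, interval, validate_age: bool = True
):
    """Fixed-effect predicted proportional gain at (age, interval) in months.

    Random effects are set to zero (new-animal prediction).  Scalar or array
    inputs; raises on ages beyond the model's validity bound when
    ``validate_age`` and a bound is recorded.
    """
    A = np.asarray(age, dtype=float)
    I = np.asarray(interval, dtype=float)
    if np.any(I < 0):
        raise ValueError("interval must be >= 0")
    if np.any(A < 0):
        raise ValueError("age must be >= 0")
    if (
        validate_age
        and coeffs.max_valid_age_months is not None
        and np.any(A > coeffs.max_valid_age_months)
    ):
        raise ValueError(
            f"age beyond model validity bound {coeffs.max_valid_age_months} months"
        )
    c = coeffs
    out = (
        c.intercept
        + c.age * A
        + c.age2 * A**2
        + c.age3 * A**3
        + c.interval * I
        + c.interval2 * I**2
        + c.interval3 * I**3
        + c.age_x_interval * A * I
    )
    return float(out) if out.ndim == 0 else out


class NoRootError(ValueError):
    """The predicted gain never crosses zero within the search range."""


def solve_cessation(
    coeffs: GrowthCoefficients,
    interval: float = 1.0,
    search_max: float = 60.0,
    grid_step: float = 0.001,
    xtol: float = 1e-4,
) -> CessationEstimate:
    """Smallest age at which the predicted gain reaches zero at fixed interval.

    Scans a ``grid_step``-month grid over (0, search_max] for the first
    non-positive predicted gain, then bisects the bracketing step to ``xtol``
    months.  Raises :class:`NoRootError` when the gain stays positive.
    """
    if search_max <= 0:
        raise ValueError("search_max must be > 0")
    grid = np.arange(grid_step, search_max + grid_step / 2, grid_step)
    vals = predict_gain(coeffs, grid, interval, validate_age=False)
    nonpos = np.flatnonzero(vals <= 0.0)
    if nonpos.size == 0:
        raise NoRootError("predicted gain positive over the whole search range")
    i = int(nonpos[0])
    if i == 0:
        root = float(grid[0])
    else:
        root = float(
            brentq(
                lambda a: predict_gain(coeffs, a, interval, validate_age=False),
                grid[i - 1],
                grid[i],
                xtol=xtol,
            )
        )
    return CessationEstimate(
        age_months=root,
        method="model_solve",
        resolution_months=xtol,
        detail={"interval": interval, "search_max": search_max},
    )


def variance_partition(coeffs: GrowthCoefficients) -> float:
    """Share of outcome variance attributable to the per-animal intercept."""
    total = coeffs.var_animal + coeffs.var_resid
    if total == 0:
        raise ValueError("both variance components are zero")
    return coeffs.var_animal / total
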