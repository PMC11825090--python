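"""Mixed model of proportional gain: fitting, selection, prediction, roots."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vetweight.growth_model import (
    TERMS,
    GrowthCoefficients,
    NoRootError,
    backward_select,
    fit_growth_model,
    predict_gain,
    solve_cessation,
    variance_partition,
    _MARGINALITY,
)
from conftest import make_pairs


class TestFitGrowthModel:
    def test_parameter_recovery_within_two_se(self, reference_dog_coeffs):
        pairs = make_pairs(reference_dog_coeffs, 2000, seed=1, resid_sd=0.02)
        terms = tuple(
            t for t, on in reference_dog_coeffs.included_terms.items() if on
        )
        fit = fit_growth_model(pairs, terms)
        for name in ("intercept",) + terms:
            est = getattr(fit, name)
            true = getattr(reference_dog_coeffs, name)
            se = fit.fe_se[name]
            assert abs(est - true) <= 2.0 * se, name

    def test_constant_outcome_gives_intercept_only(self, rng):
        pairs = pd.DataFrame(
            {
                "animal_id": np.repeat([f"a{i}" for i in range(100)], 3),
                "age_months": rng.uniform(0, 13, 300),
                "interval_months": rng.uniform(0.3, 3, 300),
                "prop_gain": 0.2,
                "weight_kg": 5.0,
            }
        )
        fit = fit_growth_model(pairs)
        assert fit.intercept == pytest.approx(0.2, abs=1e-8)
        for t in TERMS:
            assert getattr(fit, t) == pytest.approx(0.0, abs=1e-7)

    def test_order_invariance(self, reference_dog_coeffs):
        pairs = make_pairs(reference_dog_coeffs, 600, seed=2)
        fit1 = fit_growth_model(pairs)
        fit2 = fit_growth_model(
            pairs.sample(frac=1.0, random_state=3).reset_index(drop=True)
        )
        for name in ("intercept",) + TERMS:
            assert getattr(fit1, name) == pytest.approx(
                getattr(fit2, name), abs=1e-8
            )

    def test_matches_statsmodels_mixedlm(self, rng):
        """Dual-route check of the profiled solver against MixedLM on data
        with a real random-intercept component."""
        import statsmodels.api as sm

        n_animals, per = 150, 4
        ids = np.repeat([f"a{i}" for i in range(n_animals)], per)
        age = rng.uniform(0, 13, ids.size)
        interval = rng.uniform(0.3, 3, ids.size)
        u = rng.normal(0, 0.05, n_animals)
        y = 0.3 - 0.02 * age + 0.05 * interval + np.repeat(u, per)
        y = y + rng.normal(0, 0.03, ids.size)
        pairs = pd.DataFrame(
            {
                "animal_id": ids,
                "age_months": age,
                "interval_months": interval,
                "prop_gain": y,
                "weight_kg": 5.0,
            }
        )
        ours = fit_growth_model(pairs, ("age", "interval"), reml=True)
        X = np.column_stack([np.ones(ids.size), age / 12.0, interval / 12.0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = sm.MixedLM(y, X, groups=ids).fit(reml=True)
        assert ours.intercept == pytest.approx(ref.fe_params[0], abs=1e-6)
        assert ours.age * 12 == pytest.approx(ref.fe_params[1], abs=1e-6)
        assert ours.interval * 12 == pytest.approx(ref.fe_params[2], abs=1e-6)
        assert ours.var_resid == pytest.approx(ref.scale, rel=1e-4)
        assert ours.var_animal == pytest.approx(
            float(np.asarray(ref.cov_re)[0, 0]), rel=1e-3, abs=1e-8
        )

    def test_too_few_animals_rejected(self):
        pairs = pd.DataFrame(
            {
                "animal_id": ["a"] * 5,
                "age_months": np.arange(5.0),
                "interval_months": np.ones(5),
                "prop_gain": np.ones(5),
                "weight_kg": 5.0,
            }
        )
        with pytest.raises(ValueError):
            fit_growth_model(pairs)


def _enumerate_marginal_masks():
    masks = []
    for included in itertools.product([False, True], repeat=len(TERMS)):
        mask = dict(zip(TERMS, included))
        if all(
            mask[t] or not any(mask[p] for p in _MARGINALITY[t]) for t in TERMS
        ):
            masks.append(tuple(t for t in TERMS if mask[t]))
    return masks


class TestBackwardSelect:
    def test_pure_noise_predictors_pruned_to_negligible_effects(self):
        """With an intercept-only generating model, AIC keeps a spurious term
        with probability ~0.16 each, so assert the statistical behaviour:
        selections are small, any survivor's effect is within the noise, and
        the full prune occurs."""
        retained, effect_ranges, any_empty = [], [], False
        for s in range(6):
            r = np.random.default_rng(s)
            pairs = pd.DataFrame(
                {
                    "animal_id": np.repeat([f"a{i}" for i in range(250)], 2),
                    "age_months": r.uniform(0, 13, 500),
                    "interval_months": r.uniform(0.3, 3, 500),
                    "prop_gain": 0.1 + r.normal(0, 0.05, 500),
                    "weight_kg": 5.0,
                }
            )
            fit = backward_select(pairs)
            k = sum(fit.included_terms.values())
            retained.append(k)
            any_empty = any_empty or k == 0
            a = np.linspace(0, 13, 40)
            i = np.linspace(0.3, 3, 40)
            preds = predict_gain(
                fit, *np.meshgrid(a, i), validate_age=False
            )
            effect_ranges.append(float(np.ptp(preds)))
        assert np.median(retained) <= 2
        assert any_empty
        assert max(effect_ranges) <= 0.05  # within one residual sd

    def test_final_mask_matches_exhaustive_enumeration(
        self, reference_dog_coeffs
    ):
        pairs = make_pairs(reference_dog_coeffs, 300, seed=4, resid_sd=0.05)
        selected = backward_select(pairs, final_reml=False)
        sel_mask = tuple(t for t, on in selected.included_terms.items() if on)
        best = min(
            _enumerate_marginal_masks(),
            key=lambda m: fit_growth_model(pairs, m).aic,
        )
        # greedy backward selection cannot beat the exhaustive optimum, and
        # must come within one AIC unit of it on this small fixture
        best_aic = fit_growth_model(pairs, best).aic
        assert selected.aic >= best_aic - 1e-9
        assert selected.aic <= best_aic + 1.0

    def test_never_accepts_aic_increase(self, reference_dog_coeffs):
        pairs = make_pairs(reference_dog_coeffs, 1000, seed=5)
        full_aic = fit_growth_model(pairs).aic
        final = backward_select(pairs, final_reml=False)
        assert final.aic <= full_aic + 1e-9

    def test_drops_cubic_interval_absent_from_truth(self, reference_dog_coeffs):
        # generating model lacks the cubic interval term; selection removes it
        # and keeps the active ones
        pairs = make_pairs(reference_dog_coeffs, 4000, seed=0, resid_sd=0.01)
        fit = backward_select(pairs)
        assert not fit.included_terms["interval3"]
        for t in ("age", "age2", "age3", "interval", "interval2",
                  "age_x_interval"):
            assert fit.included_terms[t], t


class TestPredictGain:
    def test_reference_intercept_at_origin(self, reference_dog_coeffs):
        assert predict_gain(reference_dog_coeffs, 0.0, 0.0) == 0.385

    def test_all_zero_model_predicts_zero(self):
        zero = GrowthCoefficients(
            intercept=0.0, included_terms={t: False for t in TERMS}
        )
        for a, i in [(0, 0), (3, 1), (13, 6)]:
            assert predict_gain(zero, a, i) == 0.0

    def test_matches_term_by_term_oracle(self, reference_dog_coeffs):
        c = reference_dog_coeffs
        a, i = 6.0, 1.0
        oracle = sum(
            [
                c.intercept,
                c.age * a,
                c.age2 * a**2,
                c.age3 * a**3,
                c.interval * i,
                c.interval2 * i**2,
                c.interval3 * i**3,
                c.age_x_interval * a * i,
            ]
        )
        assert predict_gain(c, a, i) == pytest.approx(oracle, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.floats(0, 14), i=st.floats(0, 12),
        s1=st.floats(-2, 2), s2=st.floats(-2, 2),
    )
    def test_linear_in_coefficients_by_superposition(self, a, i, s1, s2):
        base = {t: 0.01 * (j + 1) for j, t in enumerate(TERMS)}
        c1 = GrowthCoefficients(intercept=0.1, **base)
        c2 = GrowthCoefficients(
            intercept=0.2, **{t: -0.005 * (j + 1) for j, t in enumerate(TERMS)}
        )
        mix = GrowthCoefficients(
            intercept=s1 * 0.1 + s2 * 0.2,
            **{
                t: s1 * getattr(c1, t) + s2 * getattr(c2, t) for t in TERMS
            },
        )
        lhs = predict_gain(mix, a, i)
        rhs = s1 * predict_gain(c1, a, i) + s2 * predict_gain(c2, a, i)
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)

    def test_validity_bound_enforced(self, reference_dog_coeffs):
        with pytest.raises(ValueError):
            predict_gain(reference_dog_coeffs, 20.0, 1.0)
        # explicit override allowed for internal solvers
        predict_gain(reference_dog_coeffs, 20.0, 1.0, validate_age=False)


class TestSolveCessation:
    def test_linear_closed_form_root(self):
        # fixed-effect sum at I=1 equals 0.10 - 0.01 A -> root at 10.0
        c = GrowthCoefficients(
            intercept=0.05,
            age=-0.01,
            interval=0.05,
            included_terms={
                t: t in ("age", "interval") for t in TERMS
            },
        )
        est = solve_cessation(c, interval=1.0, search_max=60)
        assert est.age_months == pytest.approx(10.0, abs=1e-4)
        assert est.method == "model_solve"

    def test_reference_coeffs_match_grid_scan_oracle(self, reference_dog_coeffs):
        est = solve_cessation(reference_dog_coeffs, 1.0, 60.0)
        grid = np.arange(0.001, 60.0, 0.001)
        vals = predict_gain(reference_dog_coeffs, grid, 1.0, validate_age=False)
        oracle = grid[np.flatnonzero(vals <= 0)[0]]
        assert est.age_months == pytest.approx(oracle, abs=1e-3)

    def test_positive_polynomial_has_no_root(self):
        c = GrowthCoefficients(
            intercept=0.5, included_terms={t: False for t in TERMS}
        )
        with pytest.raises(NoRootError):
            solve_cessation(c, 1.0, 60.0)

    def test_invariant_to_search_max_once_bracketed(self, reference_dog_coeffs):
        r1 = solve_cessation(reference_dog_coeffs, 1.0, 20.0).age_months
        r2 = solve_cessation(reference_dog_coeffs, 1.0, 60.0).age_months
        assert r1 == pytest.approx(r2, abs=1e-6)


class TestVariancePartition:
    @pytest.mark.parametrize(
        "vu,ve,expected", [(0.0, 1.0, 0.0), (1.0, 1.0, 0.5)]
    )
    def test_simple_ratios(self, vu, ve, expected):
        c = GrowthCoefficients(
            intercept=0.0,
            included_terms={t: False for t in TERMS},
            var_animal=vu,
            var_resid=ve,
        )
        assert variance_partition(c) == expected

    def test_no_per_animal_heterogeneity_gives_negligible_vpc(
        self, reference_dog_coeffs
    ):
        """Without true per-animal heterogeneity the variance estimate sits on
        the zero boundary in most samples; the median vpc over seeds is
        negligible."""
        vpcs = []
        for s in range(5):
            pairs = make_pairs(
                reference_dog_coeffs, 20000, seed=s, resid_sd=0.02,
                n_per_animal=4,
            )
            vpcs.append(variance_partition(fit_growth_model(pairs)))
        assert np.median(vpcs) <= 1e-7


class TestSerialisation:
    def test_json_round_trip(self, reference_dog_coeffs, tmp_path):
        path = tmp_path / "coeffs.json"
        reference_dog_coeffs.to_json(path)
        back = GrowthCoefficients.from_json(path)
        for name in ("intercept",) + TERMS:
            assert getattr(back, name) == getattr(reference_dog_coeffs, name)
        assert back.included_terms == reference_dog_coeffs.included_terms

    def test_hand_written_coefficients_file(self, tmp_path):
        path = tmp_path / "hand.json"
        path.write_text(
            '{"coefficients": {"intercept": 0.385, "age": -0.053,'
            ' "interval": 0.065}}'
        )
        c = GrowthCoefficients.from_json(path)
        assert c.intercept == 0.385
        assert c.age == -0.053
        assert not c.included_terms["age3"]

    def test_excluded_term_with_nonzero_coefficient_rejected(self):
        with pytest.raises(ValueError):
            GrowthCoefficients(
                intercept=0.0,
                age=0.5,
                included_terms={t: False for t in TERMS},
            )
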