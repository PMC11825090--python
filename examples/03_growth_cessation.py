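"""Detect the end of juvenile growth and calibrate the growth model to it.

Stage 1 smooths per-animal monthly weight change against age (span-selected
loess) and reports the earliest 0.05-month grid age at which the predicted
change reaches zero.  Stage 2 fits the polynomial mixed model of proportional
gain and binary-searches the development age window so the age at which the
model's predicted gain hits zero (at a one-month interval) matches the
smoothed estimate.
"""

from vetweight import (
    DEFAULT_SPECIES,
    apply_exclusions,
    build_growth_pairs,
    calibrate_max_age,
    estimate_cessation,
    generate_population,
    variance_partition,
)

records, _ = generate_population(
    {"dog": DEFAULT_SPECIES["dog"]}, 8000, ("2022-01-01", "2023-12-31"),
    seed=3, max_age_at_end_months=36,
)
cleaned, _ = apply_exclusions(records)

cess, fit = estimate_cessation(cleaned, species="dog")
print(f"smoothed growth cessation: {cess.age_months:.2f} months "
      f"(span {fit.span:.2f}, {fit.n_points} pairs)")
print(f"generator's true cessation age: "
      f"{DEFAULT_SPECIES['dog'].cessation_age_months} months")

pairs = build_growth_pairs(cleaned, max_age_months=72)
result, coeffs = calibrate_max_age(pairs, cess, bounds=(15, 72))
print(f"\ncalibrated development window: <= {result.max_dev_age_months} months")
print(f"model-solved cessation: {result.solved_cessation_months:.2f} months "
      f"(loess target {result.loess_target_months:.2f})")
kept = [t for t, on in coeffs.included_terms.items() if on]
print(f"retained terms: intercept + {', '.join(kept)}")
print(f"variance partition coefficient: {variance_partition(coeffs):.2e}")
# A negligible VPC means animals share one growth pattern, so new animals can
# be adjusted with the fixed effects alone.
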