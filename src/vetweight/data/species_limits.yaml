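# Species plausibility limits for bodyweight records, version 1.
# Bodyweight and age ranges considered realistic for UK primary-care
# veterinary patients; records outside these ranges are excluded.
# jump_factor: maximum plausible monthly-equivalent growth ratio between
# consecutive measurements of one animal.
# max_juvenile_age_months: upper validity bound of the juvenile growth model.
version: 1
species:
  dog:
    weight_min_kg: 0.07
    weight_max_kg: 125.0
    age_min_y: 0.0
    age_max_y: 22.5
    jump_factor: 10.0
    max_juvenile_age_months: 14.0
  cat:
    weight_min_kg: 0.07
    weight_max_kg: 22.0
    age_min_y: 0.0
    age_max_y: 27.5
    jump_factor: 10.0
    max_juvenile_age_months: 13.0
  rabbit:
    weight_min_kg: 0.035
    weight_max_kg: 25.0
    age_min_y: 0.0
    age_max_y: 19.0
    jump_factor: 3.0
    max_juvenile_age_months: 13.0
  guinea_pig:
    weight_min_kg: 0.04
    weight_max_kg: 1.4
    age_min_y: 0.0
    age_max_y: 15.0
    jump_factor: 3.0
    max_juvenile_age_months: 13.0
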