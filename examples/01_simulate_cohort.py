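"""Generate a synthetic veterinary bodyweight record set with known truth.

Builds one year of ad-hoc clinic weight records for 2,000 dogs and prints the
population's true point-mean bodyweight on 31 December -- the quantity the
rest of the pipeline tries to recover from the noisy records alone.
"""

from vetweight import DEFAULT_SPECIES, generate_population, true_point_mean

records, truth = generate_population(
    {"dog": DEFAULT_SPECIES["dog"]},
    n_animals=2000,
    date_window=("2023-01-01", "2023-12-31"),
    seed=1,
)

print(f"records:            {len(records)}")
print(f"animals:            {records['animal_id'].nunique()}")
print(f"weight range (kg):  {records['weight_kg'].min():.2f}"
      f" - {records['weight_kg'].max():.2f}")
print(f"true point mean on 2023-12-31: {true_point_mean(truth, '2023-12-31'):.3f} kg")
# The true point mean is the noiseless average weight of every generated dog
# on the target date; downstream estimates are judged against it.
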