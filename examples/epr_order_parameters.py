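"""Temperature series of the 16-SASL order parameter.

Simulates noisy hyperfine splittings (10 replicates per temperature,
0.2 G scatter) realising the preset S(T) profile — a decline from 5 to 20 C
followed by a rise at 30 C — and recovers the profile.
"""

from monofilm import order_series
from monofilm.presets import S_PROFILE_PRESET
from monofilm.synthetic import generate_epr_series

records, truth = generate_epr_series(
    S_PROFILE_PRESET, a0_target=15.0, sigma=0.2, n_per_temperature=10, seed=7
)

print(f"{'T [C]':>6}{'a0 [G]':>9}{'S':>9}{'SE':>9}{'S_true':>9}")
for rec in order_series(records):
    print(
        f"{rec.temperature:>6.0f}{rec.a0:>9.2f}{rec.s:>9.4f}"
        f"{rec.se:>9.4f}{S_PROFILE_PRESET[rec.temperature]:>9.2f}"
    )
print()
print(
    "S measures acyl-chain order in the membrane core (0 = isotropic,\n"
    "1 = fully ordered); the minimum near 20 C followed by a rise at 30 C\n"
    "mirrors the temperature response of mixed-unsaturation liposomes."
)
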