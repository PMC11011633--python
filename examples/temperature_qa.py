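"""Temperature-profile QA for a simulated cold-store run.

Generates an 18-day probe set (10 fruit-core + 6 air probes, 30-minute
logging) cooling exponentially from ~25 deg C toward a 3 deg C plateau,
then summarizes it the way treatment reports do: cool-down time to 3.5 deg C
(majority rule), post-cool-down fruit-core mean/sd, and the constancy
percentage (readings within +/-0.5 deg C of target).
"""

import dataclasses

import coldtreat as ct
from coldtreat.synthetic import TemperatureProfile, gen_temperature_log

profile = TemperatureProfile(start_c=24.8, plateau_c=3.04,
                             time_constant_h=13.0, noise_sd=0.1)
logs, truth = gen_temperature_log(profile, seed=1)

summary = ct.profile_summary(logs)
for key, value in dataclasses.asdict(summary).items():
    print(f"{key:>20s}: {value:.2f}" if isinstance(value, float) else
          f"{key:>20s}: {value}")

print()
print(f"analytic 3.5 deg C crossing of the noise-free curve: "
      f"{truth['analytic_crossing_h']:.2f} h")
print("The measured cool-down agrees within one 0.5-h sampling interval;")
print("constancy near 100% means the store held the 3 +/- 0.5 deg C band.")
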