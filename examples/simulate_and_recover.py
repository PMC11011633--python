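"""Generate a synthetic extended-duration trial and recover its parameters.

Simulates the 2019-style design (third instars, durations up to 18 days,
4 replicates x 5 boxes x 2 cultivars) from known ground truth, rebuilds the
treated-number bookkeeping from the controls, fits the beta-binomial model,
and compares the recovered probit-9 lethal time against the generating
value.
"""

import coldtreat as ct
from coldtreat.synthetic import gen_cold_tolerance

data, truth = gen_cold_tolerance("y2019", seed=7)
print(f"simulated {len(data)} boxes; "
      f"{int(data['pupae_count'].sum())} pupae recovered in total")

# the pipeline's own bookkeeping reproduces the generator's E column
rebuilt = ct.estimate_treated(data.drop(columns=["treated_estimate"]))
assert (rebuilt["treated_estimate"] == data["treated_estimate"]).all()

for cultivar in ("Hayward", "Zesy002"):
    sub = data[data["cultivar"] == cultivar]
    fit = ct.fit_fixed(sub, ct.ModelSpec(link="logit"))
    lt = ct.lt_point(fit, "L3", ct.PROBIT9)
    lo, hi, case = ct.fieller_ci(fit, "L3", ct.PROBIT9)
    true_lt = truth["true_lt_probit9"][f"L3//{cultivar}"]
    print(f"{cultivar:8s} LT_99.9968 = {lt:5.2f} d  (95% CI {lo:.2f}-{hi:.2f}), "
          f"truth = {true_lt:.2f} d")

print()
print("Estimates within a few percent of truth, and truth inside the Fieller")
print("interval, is the expected behaviour at this design size.")
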