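# coldtreat

Statistics for **cold-treatment disinfestation trials**: the kind of study
that asks *"how many days at 3 °C does it take to kill every Mediterranean
fruit fly larva hiding in an export kiwifruit — and how sure are we?"*

The package implements the full statistical machinery of such a trial for
biostatisticians and phytosanitary researchers:

* **Time–mortality modelling** — the probability that an immature insect
  (egg or larval instar) dies after `t` days of cold treatment is modelled
  on a link scale,

  `g(π_s(t)) = α_s + β_s · t`,  `g ∈ {probit, logit}`,

  with one intercept and one time slope per life stage `s`, a
  **beta-binomial** observation model for box-level counts whose intraclass
  correlation follows its own submodel `ρ_s(t) = logistic(d_s + e·t)`, and
  optional Gaussian replicate intercepts integrated out by a Laplace
  approximation (adaptive Gauss–Hermite fallback).
* **Lethal times** — inverting a fit at a target mortality `p` gives
  `LT_p = (g(p) − α_s)/β_s`; the quarantine benchmark is **probit 9**,
  `p = 0.999968` (at most 32 survivors per million treated).  95% intervals
  for the ratio come from **Fieller's theorem**, with the unbounded/exclusive
  cases flagged rather than clipped.
* **Efficacy arithmetic** — extrapolating the number of insects treated in a
  large-scale trial from control counts (two-sided t on the standard error,
  plus the one-sided Wearing and IPPC-style variants), and the zero-survivor
  confidence bound `C = 1 − m^n` (Couey–Chew) that true mortality exceeded
  `m` when `n` treated insects yielded no survivors.
* **Mortality bookkeeping** — treated boxes don't reveal how many insects
  they contained; expected totals come from matching control-box means, and
  group summaries (median and range of box mortality) mirror the standard
  reporting tables.
* **Temperature QA** — ice-bath calibration offsets, cool-down time to
  3.5 °C (majority-of-probes rule), and the constancy percentage of
  post-cool-down readings within ±0.5 °C of the 3 °C target.
* **Synthetic data** — generators that emulate the 2018/2019 cold-tolerance
  designs and the 2022 large-scale trial with known ground truth, so every
  pipeline stage is testable without the unpublished box-level raw data.

The package ships the published duration-level bioassay totals
(`coldtreat.datasets`) for the 2018–2019 kiwifruit experiments on
*Ceratitis capitata* in 'Hayward' and 'Zesy002'.

## Worked example

```python
import coldtreat as ct
from coldtreat.datasets import load_bioassay_totals

fit = ct.fit_fixed(
    load_bioassay_totals(cultivar="Hayward", life_stage="L3"),
    ct.ModelSpec(link="logit"),
)
print(ct.format_lt_table(ct.lt_table(fit)).to_string(index=False))
```

```
life_stage            LT_50            LT_95            LT_99          LT_99.9968
        L3 4.72 (4.54-4.88) 7.73 (7.63-7.84) 9.42 (9.26-9.61) 15.32 (14.84-15.86)
```

Half the third instars are dead after ~4.7 days at 3 °C, 99% after ~9.4
days, and the probit-9 security level is reached after ~15.3 days
(parentheses are Fieller 95% intervals).  Fits of the aggregated totals sit
near, but not exactly on, the originally reported box-level estimates
(17.31 days for this dataset) — see `docs/methods.md` for why.

The efficacy side of the story:

```python
import coldtreat as ct
print(ct.mortality_confidence(499_604, 0, ct.PROBIT9))   # 0.9999999
print(ct.required_n(ct.PROBIT9, 0.95))                   # 93,616
```

Zero survivors among ~500,000 treated larvae gives >99.99999% confidence
that true mortality exceeded 99.9968%; 93,616 is the smallest trial that
could certify probit 9 at 95% confidence.

Longer narrative walk-throughs live in `examples/` (one script per
capability), and a thin CLI covers the same ground from a shell:

```sh
coldtreat simulate --design y2019 --seed 1 --out sim.csv
coldtreat report --input sim.csv --out-dir results --link auto
coldtreat efficacy --control-counts 10226,10598,10625 \
    --n-control-fruit 200 --n-treated-fruit 10200
```

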