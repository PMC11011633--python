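"""Synthetic bioassay, large-scale-trial and temperature data with known truth.

No box-level raw data accompany the study this package models, so every
pipeline stage is exercised against generated data whose ground truth is
known exactly.  The generators emulate the three experimental designs:

* ``y2018`` — 4 immature stages (egg, L1-L3) x 2 kiwifruit cultivars x
  treatment durations {0, 5, 6, 7, 8, 10} days x 4 replicates, 3 boxes of
  5 fruit per cell;
* ``y2019`` — third instars only, durations {0, 8, 10, 11, 13, 14, 16, 18},
  4 replicates, 5 boxes of 10 fruit per cell (810 fruit infested per
  replicate including the 10 dissection fruit);
* the 2022 large-scale trial — 3 replicates of 3,400 fruit treated 18 days,
  180 at 8 and 10 days, 200 untreated controls and 10 dissection fruit
  (3,770 fruit per replicate).

Mortality follows the same link model the fitting code estimates:
``P(dead) = link^-1(alpha_stage + beta_stage * t + cultivar shift + u_rep)``
with beta-binomial box-level noise.  Default coefficients are back-solved
from the published Hayward lethal-time table (LT_50 and LT_99.9968 per
stage); dispersion and replicate-effect defaults are synthetic choices,
documented in the methods note, sized to make overdispersion detectable.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .bioassay import betabinom_rvs, link_inverse, link_transform
from .thermal import TemperatureLog

__all__ = [
    "TrueParams",
    "Design",
    "TemperatureProfile",
    "DESIGNS",
    "gen_cold_tolerance",
    "gen_large_scale",
    "gen_temperature_log",
]


@dataclass(frozen=True)
class TrueParams:
    """Ground-truth parameters for the generators.

    ``alpha``/``beta`` are per-stage intercepts and time slopes on the link
    scale, derived from the published Hayward LT_50/LT_99.9968 pairs.  The
    second cultivar is more susceptible by ``cultivar_shift`` on the link
    scale.  ``rho_intercept``/``rho_slope`` parameterize the beta-binomial
    intraclass correlation ``rho = expit(d + e t)``; ``sigma_u`` is the sd of
    Gaussian replicate intercepts.  Egg loads per fruit are rounded truncated
    normals consistent with the printed infestation means (90 eggs/fruit in
    the tolerance years, 105 in the large-scale trial); ``pupation_rate`` is
    the egg-to-pupa survival of untreated fruit per cultivar.
    """

    link: str = "logit"
    alpha: dict = field(default_factory=lambda: {
        "egg": -3.195, "L1": -3.086, "L2": -3.289, "L3": -3.161,
    })
    beta: dict = field(default_factory=lambda: {
        "egg": 0.830, "L1": 1.348, "L2": 0.988, "L3": 0.780,
    })
    cultivar_shift: dict = field(default_factory=lambda: {
        "Hayward": 0.0, "Zesy002": 0.5,
    })
    rho_intercept: float = special.logit(0.05)
    rho_slope: float = 0.0
    sigma_u: float = 0.25
    eggs_per_fruit_mean: float = 90.0
    eggs_per_fruit_sd: float = 20.0
    pupation_rate: dict = field(default_factory=lambda: {
        "Hayward": 0.50, "Zesy002": 0.17,
    })
    # large-scale trial
    ls_eggs_per_fruit_mean: float = 105.0
    ls_pupae_per_fruit_mean: float = 51.0
    ls_pupae_per_fruit_sd: float = 5.4
    ls_live_l3_per_fruit_mean: float = 76.0
    ls_live_l3_per_fruit_sd: float = 5.0
    # survival probability of the 18-day lots; 0 emulates the trial outcome
    # (true mortality beyond the probit-9 level)
    ls_survival_18d: float = 0.0

    def mortality(self, stage: str, cultivar: str, t, u=0.0):
        eta = (self.alpha[stage] + self.beta[stage] * np.asarray(t, dtype=float)
               + self.cultivar_shift.get(cultivar, 0.0) + u)
        return link_inverse(eta, self.link)

    def rho(self, t):
        return special.expit(self.rho_intercept + self.rho_slope * np.asarray(t, dtype=float))

    def true_lt(self, stage: str, p: float, cultivar: str = "Hayward") -> float:
        q = link_transform(p, self.link)
        return (q - self.alpha[stage] - self.cultivar_shift.get(cultivar, 0.0)) / self.beta[stage]


@dataclass(frozen=True)
class Design:
    """Layout of a cold-tolerance experiment."""

    year: str
    stages: tuple[str, ...]
    cultivars: tuple[str, ...]
    durations: tuple[float, ...]
    n_replicates: int
    boxes_per_cell: int
    fruit_per_box: int
    dissection_fruit: int = 0  # extra infested fruit set aside per replicate

    @property
    def fruit_per_replicate(self) -> int:
        cells = len(self.stages) * len(self.cultivars) * len(self.durations)
        return cells * self.boxes_per_cell * self.fruit_per_box + self.dissection_fruit


DESIGNS = {
    "y2018": Design(
        year="2018",
        stages=("egg", "L1", "L2", "L3"),
        cultivars=("Hayward", "Zesy002"),
        durations=(0.0, 5.0, 6.0, 7.0, 8.0, 10.0),
        n_replicates=4,
        boxes_per_cell=3,
        fruit_per_box=5,
    ),
    "y2019": Design(
        year="2019",
        stages=("L3",),
        cultivars=("Hayward", "Zesy002"),
        durations=(0.0, 8.0, 10.0, 11.0, 13.0, 14.0, 16.0, 18.0),
        n_replicates=4,
        boxes_per_cell=5,
        fruit_per_box=10,
        dissection_fruit=10,
    ),
}


def _eggs_in_box(rng, n_fruit, mean, sd):
    eggs = np.rint(rng.normal(mean, sd, size=n_fruit))
    return int(np.maximum(eggs, 1.0).sum())


def gen_cold_tolerance(
    design: str | Design = "y2018",
    params: TrueParams | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Generate box-level observations for a cold-tolerance design.

    Returns ``(observations, truth)``.  ``observations`` matches the schema
    consumed by the fitting code; ``treated_estimate`` is bookkept the same
    way the summaries module recomputes it (mean control pupal count of the
    matching cultivar x replicate x stage group).  ``truth`` echoes the
    parameters, the per-box latent treated numbers, and the true lethal
    times.
    """
    params = params or TrueParams()
    if isinstance(design, str):
        try:
            design = DESIGNS[design]
        except KeyError:
            raise ValueError(
                f"unknown design {design!r}; expected one of {sorted(DESIGNS)} "
                "or a Design instance"
            ) from None
    rng = np.random.default_rng(seed)

    rows = []
    latent = {}
    u_true = {}
    for rep in range(1, design.n_replicates + 1):
        rep_label = f"R{rep}"
        for cv in design.cultivars:
            u = rng.normal(0.0, params.sigma_u) if params.sigma_u > 0 else 0.0
            u_true[(rep_label, cv)] = u
            for stage in design.stages:
                for t in design.durations:
                    pmort = float(params.mortality(stage, cv, t, u))
                    rho = float(params.rho(t))
                    for b in range(1, design.boxes_per_cell + 1):
                        eggs = _eggs_in_box(
                            rng, design.fruit_per_box,
                            params.eggs_per_fruit_mean, params.eggs_per_fruit_sd,
                        )
                        n_latent = int(rng.binomial(eggs, params.pupation_rate[cv]))
                        n_latent = max(n_latent, 1)
                        survivors = int(
                            betabinom_rvs(n_latent, 1.0 - pmort, rho, rng)
                        )
                        unit = f"{design.year}-{cv}-{stage}-{rep_label}-D{t:g}-B{b}"
                        rows.append(
                            dict(
                                year=design.year, cultivar=cv, life_stage=stage,
                                replicate=rep_label, duration_days=t,
                                unit_id=unit, pupae_count=survivors,
                            )
                        )
                        latent[unit] = n_latent
    df = pd.DataFrame(rows)

    # bookkeeping identical to summaries.estimate_treated
    controls = df[df["duration_days"] == 0.0]
    means = controls.groupby(["cultivar", "replicate", "life_stage"])["pupae_count"].mean()
    df["treated_estimate"] = [
        max(float(means.loc[(r.cultivar, r.replicate, r.life_stage)]), 1.0)
        for r in df.itertuples()
    ]

    truth = {
        "params": asdict(params),
        "design": asdict(design),
        "seed": seed,
        "latent_treated": latent,
        "replicate_effects": {f"{k[0]}//{k[1]}": v for k, v in u_true.items()},
        "true_lt_probit9": {
            f"{stage}//{cv}": params.true_lt(stage, 0.999968, cv)
            for stage in design.stages for cv in design.cultivars
        },
    }
    return df, truth


def gen_large_scale(params: TrueParams | None = None, seed: int = 0) -> tuple[dict, dict]:
    """Generate the large-scale trial counts (3 replicates).

    Returns ``(counts, truth)`` where ``counts`` holds per-replicate control
    totals, dissection per-fruit live-L3 counts, and treated survivor totals
    per duration with the fruit numbers of the trial design.
    """
    params = params or TrueParams()
    rng = np.random.default_rng(seed)
    n_reps = 3
    fruit = {"control": 200, "8": 180, "10": 180, "18": 3400, "dissect": 10}

    def pupae_total(n_fruit):
        per = np.rint(rng.normal(params.ls_pupae_per_fruit_mean,
                                 params.ls_pupae_per_fruit_sd, size=n_fruit))
        return int(np.maximum(per, 0.0).sum())

    control_counts = []
    dissections = []
    treated = {"8": [], "10": [], "18": []}
    latent = {"8": [], "10": [], "18": []}
    for _ in range(n_reps):
        control_counts.append(pupae_total(fruit["control"]))
        per_l3 = np.rint(rng.normal(params.ls_live_l3_per_fruit_mean,
                                    params.ls_live_l3_per_fruit_sd,
                                    size=fruit["dissect"]))
        dissections.append(np.maximum(per_l3, 0.0).astype(int).tolist())
        for key, t in (("8", 8.0), ("10", 10.0), ("18", 18.0)):
            n_latent = pupae_total(fruit[key])
            latent[key].append(n_latent)
            if key == "18":
                p_surv = params.ls_survival_18d
            else:
                p_surv = 1.0 - float(params.mortality("L3", "Hayward", t))
            treated[key].append(int(rng.binomial(n_latent, p_surv)) if p_surv > 0 else 0)

    counts = {
        "fruit_per_replicate": fruit,
        "total_fruit_per_replicate": sum(fruit.values()),
        "control_counts": control_counts,
        "dissection_live_l3": dissections,
        "treated_survivors": treated,
    }
    truth = {
        "params": asdict(params),
        "seed": seed,
        "latent_treated": latent,
    }
    return counts, truth


@dataclass(frozen=True)
class TemperatureProfile:
    """Exponential-decay cooling toward a plateau with Gaussian noise."""

    start_c: float = 25.0
    plateau_c: float = 3.0
    time_constant_h: float = 13.2
    noise_sd: float = 0.1
    n_fruit_probes: int = 10
    n_air_probes: int = 6
    interval_min: float = 30.0
    duration_h: float = 432.0
    air_time_constant_h: float | None = None  # defaults to a third of the fruit value

    def crossing_time(self, threshold: float = 3.5) -> float:
        """Closed-form time at which the noise-free fruit curve crosses
        ``threshold``: tau * ln((start - plateau)/(threshold - plateau))."""
        if self.start_c <= threshold:
            return 0.0
        if self.plateau_c >= threshold:
            return math.inf
        return self.time_constant_h * math.log(
            (self.start_c - self.plateau_c) / (threshold - self.plateau_c)
        )


def gen_temperature_log(
    profile: TemperatureProfile | None = None, seed: int = 0
) -> tuple[list[TemperatureLog], dict]:
    """Generate a probe set for one treatment run.

    Fruit cores follow the profile's exponential decay; air probes share the
    plateau but cool faster.  Truth records the analytic 3.5 deg C crossing
    time of the noise-free fruit curve.
    """
    profile = profile or TemperatureProfile()
    rng = np.random.default_rng(seed)
    hours = np.arange(0.0, profile.duration_h + 1e-9, profile.interval_min / 60.0)

    def decay(tau):
        return profile.plateau_c + (profile.start_c - profile.plateau_c) * np.exp(-hours / tau)

    logs = []
    fruit_curve = decay(profile.time_constant_h)
    for i in range(profile.n_fruit_probes):
        noise = rng.normal(0.0, profile.noise_sd, size=hours.shape) if profile.noise_sd > 0 else 0.0
        logs.append(TemperatureLog(
            probe_id=f"F{i + 1:02d}", kind="fruit",
            hours=hours, readings=fruit_curve + noise,
        ))
    tau_air = profile.air_time_constant_h or profile.time_constant_h / 3.0
    air_curve = decay(tau_air)
    for i in range(profile.n_air_probes):
        noise = rng.normal(0.0, profile.noise_sd, size=hours.shape) if profile.noise_sd > 0 else 0.0
        logs.append(TemperatureLog(
            probe_id=f"A{i + 1:02d}", kind="air",
            hours=hours, readings=air_curve + noise,
        ))
    truth = {
        "profile": asdict(profile),
        "seed": seed,
        "analytic_crossing_h": profile.crossing_time(3.5),
        "sampling_interval_h": profile.interval_min / 60.0,
    }
    return logs, truth
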