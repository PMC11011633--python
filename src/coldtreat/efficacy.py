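"""Large-scale-trial efficacy arithmetic.

Three pieces of plumbing around a quarantine trial with ``n`` treated insects
and ``s`` survivors:

* extrapolating the number treated from control counts (scaled confidence
  intervals, in three printed variants),
* the confidence that true mortality meets a target, given the outcome
  (the zero-survivor special case is the classic ``C = 1 - m^n``), and
* the minimum number that must be treated for a target confidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ExtrapolationInputs",
    "TreatedInterval",
    "EfficacyResult",
    "treated_interval",
    "per_fruit_interval",
    "mortality_confidence",
    "required_n",
    "efficacy_report",
]

_METHODS = ("two_sided_t", "one_sided_t_wearing", "ippc_sd")


@dataclass(frozen=True)
class ExtrapolationInputs:
    """Per-replicate control counts plus the scaling of the trial.

    ``n_control_fruit`` is the number of fruit behind each control count and
    ``n_treated_fruit`` the number of treated fruit the estimate is scaled to.
    """

    control_counts: tuple[float, ...]
    n_control_fruit: int
    n_treated_fruit: int
    method: str = "two_sided_t"

    def __post_init__(self):
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        if len(self.control_counts) < 2:
            raise ValueError("need at least 2 control replicates for a t interval")
        if any(c <= 0 for c in self.control_counts):
            raise ValueError("control counts must be positive")
        if self.n_control_fruit <= 0 or self.n_treated_fruit <= 0:
            raise ValueError("fruit counts must be positive")


@dataclass(frozen=True)
class TreatedInterval:
    """Scaled interval for the number of insects treated."""

    low: float
    high: float
    method: str
    scale: float

    @property
    def rounded(self) -> tuple[int, int]:
        # round half away from zero, matching how printed counts are compared
        r = lambda x: int(math.floor(x + 0.5)) if math.isfinite(x) else x
        return (r(self.low), r(self.high))


@dataclass(frozen=True)
class EfficacyResult:
    """Confidence that true mortality >= target given the trial outcome."""

    n_treated: int
    survivors: int
    target_mortality: float
    confidence: float


def treated_interval(inputs: ExtrapolationInputs, level: float = 0.95) -> TreatedInterval:
    """Interval for the number treated, scaled up from control counts.

    * ``two_sided_t`` — (mean +/- t_{(1+level)/2, r-1} * s/sqrt(r)) * scale,
      the study's own calculation;
    * ``one_sided_t_wearing`` — lower limit of the one-sided t interval on
      the standard error, scaled (upper limit unbounded);
    * ``ippc_sd`` — one-sided normal limit using the standard *deviation* in
      place of the standard error (an approximation to the IPPC convention).
    """
    c = np.asarray(inputs.control_counts, dtype=float)
    r = len(c)
    mean = float(np.mean(c))
    sd = float(np.std(c, ddof=1))
    se = sd / math.sqrt(r)
    scale = inputs.n_treated_fruit / inputs.n_control_fruit

    if inputs.method == "two_sided_t":
        tq = stats.t.ppf(0.5 + level / 2.0, r - 1)
        lo, hi = (mean - tq * se) * scale, (mean + tq * se) * scale
    elif inputs.method == "one_sided_t_wearing":
        tq = stats.t.ppf(level, r - 1)
        lo, hi = (mean - tq * se) * scale, math.inf
    else:  # ippc_sd
        zq = stats.norm.ppf(level)
        lo, hi = (mean - zq * sd) * scale, math.inf
    return TreatedInterval(low=lo, high=hi, method=inputs.method, scale=scale)


def per_fruit_interval(
    mean: float, se: float, n: int, method: str = "t", level: float = 0.95
) -> tuple[float, float]:
    """Two-sided interval for a per-fruit mean from its standard error."""
    if se < 0:
        raise ValueError("standard error must be non-negative")
    if method == "t":
        if n < 2:
            raise ValueError("t interval needs n >= 2")
        q = stats.t.ppf(0.5 + level / 2.0, n - 1)
    elif method == "normal":
        q = stats.norm.ppf(0.5 + level / 2.0)
    else:
        raise ValueError("method must be 't' or 'normal'")
    return (mean - q * se, mean + q * se)


def mortality_confidence(n: int, survivors: int, m: float) -> float:
    """Confidence that true mortality >= ``m`` after ``survivors`` of ``n``.

    ``C = 1 - sum_{i<=s} C(n,i) (1-m)^i m^(n-i)``; for zero survivors this is
    ``1 - m^n``.  Evaluated in log space, exact for n up to the millions.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if not 0 <= survivors <= max(n, 0):
        raise ValueError("survivors must lie in [0, n]")
    if not 0.0 < m < 1.0:
        raise ValueError("target mortality must lie strictly between 0 and 1")
    if n == 0:
        return 0.0
    if survivors == 0:
        return -math.expm1(n * math.log(m))
    return float(stats.binom.sf(survivors, n, 1.0 - m))


def required_n(m: float, confidence: float) -> int:
    """Smallest ``n`` with ``mortality_confidence(n, 0, m) >= confidence``."""
    if not 0.0 < m < 1.0 or not 0.0 < confidence < 1.0:
        raise ValueError("m and confidence must lie strictly between 0 and 1")
    n = max(1, math.ceil(math.log1p(-confidence) / math.log(m)))
    # the closed form can be off by one at the boundary; pin it down exactly
    while mortality_confidence(n, 0, m) < confidence:
        n += 1
    while n > 1 and mortality_confidence(n - 1, 0, m) >= confidence:
        n -= 1
    return n


def efficacy_report(
    control_counts,
    n_control_fruit: int,
    n_treated_fruit: int,
    survivors: int = 0,
    target_mortality: float = 0.999968,
    level: float = 0.95,
    n_policy: str = "min",
    extra_n_estimates: dict[str, float] | None = None,
) -> dict:
    """Full efficacy summary: all three treated-number variants, the treated
    number chosen under ``n_policy`` ('min' is the conservative default),
    and the confidence that mortality met the target.
    """
    variants = {}
    for method in _METHODS:
        iv = treated_interval(
            ExtrapolationInputs(tuple(control_counts), n_control_fruit,
                                n_treated_fruit, method),
            level=level,
        )
        variants[method] = {
            "low": iv.low,
            "high": iv.high if math.isfinite(iv.high) else None,
            "low_rounded": iv.rounded[0],
            "high_rounded": iv.rounded[1] if math.isfinite(iv.high) else None,
        }
    candidates = {m: v["low"] for m, v in variants.items()}
    if extra_n_estimates:
        candidates.update(extra_n_estimates)
    if n_policy == "min":
        chosen_label, chosen = min(candidates.items(), key=lambda kv: kv[1])
    else:
        raise ValueError("only the conservative 'min' n policy is implemented")
    n_treated = int(math.floor(chosen))
    conf = mortality_confidence(n_treated, survivors, target_mortality)
    return {
        "treated_number_variants": variants,
        "n_policy": n_policy,
        "n_treated": n_treated,
        "n_source": chosen_label,
        "survivors": survivors,
        "target_mortality": target_mortality,
        "confidence": conf,
        "statement": (
            f"confidence {100 * conf:.4f}% that true mortality exceeds "
            f"{100 * target_mortality:.4f}% given {survivors} survivor(s) "
            f"among an estimated {n_treated} treated"
        ),
    }
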