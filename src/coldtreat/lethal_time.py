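"""Lethal-time estimation with Fieller confidence intervals.

A fitted time-mortality model predicts death probability
``p = link^-1(alpha_stage + beta_stage * t)``; inverting at a target
mortality ``p`` gives the lethal time ``LT_p = (link(p) - alpha) / beta``.
The quarantine-security benchmark is probit 9, i.e. ``p = 0.999968``
(at most 32 survivors per million treated).

The interval for the ratio of the two jointly normal coefficient estimates
uses Fieller's theorem.  When the slope is too imprecise (``g >= 1``) the
interval is unbounded or exclusive and is returned flagged as such, never
clipped to a finite pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bioassay import ModelFit, link_transform

__all__ = [
    "PROBIT9",
    "LethalTimeEstimate",
    "lt_point",
    "fieller_ci",
    "lt_table",
    "format_lt_table",
]

#: Probit-9 quarantine security: 99.9968% mortality, stored to full precision.
PROBIT9 = 0.999968


@dataclass(frozen=True)
class LethalTimeEstimate:
    """LT_p for one life stage with its Fieller confidence interval."""

    life_stage: str
    p: float
    lt_days: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    method: str = "fieller"
    bounded: bool = True
    case: str = "bounded"  # 'bounded' | 'exclusive' | 'unbounded'


def lt_point(fit: ModelFit, stage: str, p: float) -> float:
    """Treatment duration at which a fraction ``p`` of the stage dies."""
    if not fit.converged:
        raise ValueError("lt_point requires a converged fit")
    beta = fit.beta(stage)
    if beta == 0.0:
        raise ZeroDivisionError(f"slope for stage {stage!r} is zero; LT undefined")
    return (link_transform(p, fit.spec.link) - fit.alpha(stage)) / beta


def fieller_ci(fit: ModelFit, stage: str, p: float, level: float = 0.95):
    """Fieller interval for LT_p = (link(p) - alpha)/beta.

    Returns ``(low, high, case)`` where case is 'bounded', 'exclusive'
    (the interval is the *complement* of (low, high)), or 'unbounded'
    (the whole line; low/high are -inf/inf).
    """
    if fit.covariance is None or fit.covariance.size == 0:
        raise ValueError("fit has no covariance; cannot form a Fieller interval")
    q = link_transform(p, fit.spec.link)
    a = q - fit.alpha(stage)          # numerator estimate
    b = fit.beta(stage)               # denominator estimate
    V = fit.ab_covariance(stage)
    va, vb, cab = V[0, 0], V[1, 1], -V[0, 1]
    z = stats.norm.ppf(0.5 + level / 2.0)

    A = b * b - z * z * vb
    B = a * b - z * z * cab
    C = a * a - z * z * va
    disc = B * B - A * C

    if A > 0.0 and disc >= 0.0:
        r = np.sqrt(disc)
        return ((B - r) / A, (B + r) / A, "bounded")
    if disc > 0.0:
        # g >= 1: the quadratic opens downward; the confidence set is the
        # complement of a finite interval
        r = np.sqrt(disc)
        lo, hi = sorted(((B - r) / A, (B + r) / A))
        return (lo, hi, "exclusive")
    return (-np.inf, np.inf, "unbounded")


def lt_table(
    fit: ModelFit,
    stages: Sequence[str] | None = None,
    ps: Sequence[float] = (0.5, 0.95, 0.99, PROBIT9),
    level: float = 0.95,
) -> list[LethalTimeEstimate]:
    """One :class:`LethalTimeEstimate` per stage and mortality level.

    Rows are ordered by stage (canonical order of the fit) then by ``p``.
    """
    stages = tuple(stages) if stages is not None else fit.stages
    out = []
    for stage in stages:
        for p in sorted(ps):
            lt = lt_point(fit, stage, p)
            lo, hi, case = fieller_ci(fit, stage, p, level)
            out.append(
                LethalTimeEstimate(
                    life_stage=stage, p=float(p), lt_days=float(lt),
                    ci_low=float(lo), ci_high=float(hi), level=level,
                    bounded=(case == "bounded"), case=case,
                )
            )
    return out


def format_lt_table(estimates: Sequence[LethalTimeEstimate], digits: int = 2) -> pd.DataFrame:
    """Wide table: one stage per row, one 'LT_x (lo-hi)' column per level."""
    rows: dict[str, dict[str, str]] = {}
    for e in estimates:
        label = f"LT_{100 * e.p:g}"
        if e.case == "bounded":
            cell = f"{e.lt_days:.{digits}f} ({e.ci_low:.{digits}f}-{e.ci_high:.{digits}f})"
        else:
            cell = f"{e.lt_days:.{digits}f} ({e.case})"
        rows.setdefault(e.life_stage, {})[label] = cell
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "life_stage"
    return df.reset_index()
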