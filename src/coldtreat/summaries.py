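"""Mortality bookkeeping: from pupal counts to group summaries.

Treated boxes do not reveal how many insects they contained; the expected
total per box is estimated from the mean pupal yield of the control boxes in
the matching (cultivar, replicate, life stage) group.  Proportional mortality
is then ``1 - pupae/expected``, clipped to [0, 1] (a lucky box can out-yield
the control mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MortalitySummary",
    "estimate_treated",
    "mortality_from_counts",
    "summarize_groups",
    "write_summary_table",
]

_GROUP = ("cultivar", "replicate", "life_stage")


@dataclass(frozen=True)
class MortalitySummary:
    """Tables-style group summary (one cultivar x stage x duration cell)."""

    cultivar: str
    life_stage: str
    duration_days: float
    n_units: int
    pupae_total: int
    treated_total: float
    median_mortality: float      # percent
    mortality_range: tuple[float, float]  # percent


def estimate_treated(df: pd.DataFrame, by=_GROUP, control_duration: float = 0.0) -> pd.DataFrame:
    """Fill ``treated_estimate`` from matching control-box means.

    Every unit in a group gets the mean pupal count of that group's control
    (duration ``control_duration``) boxes.  Raises ``KeyError`` naming the
    group when a group has no controls.
    """
    df = df.copy()
    by = list(by)
    controls = df[df["duration_days"] == control_duration]
    if controls.empty:
        raise KeyError("no control (duration 0) units in the data")
    means = controls.groupby(by)["pupae_count"].mean()
    est = np.empty(len(df))
    for i, (_, row) in enumerate(df.iterrows()):
        key = tuple(row[c] for c in by)
        key = key[0] if len(key) == 1 else key
        if key not in means.index:
            raise KeyError(f"no control boxes for group {dict(zip(by, np.atleast_1d(key)))}")
        est[i] = means.loc[key]
    df["treated_estimate"] = np.maximum(est, 1.0)
    return df


def mortality_from_counts(pupae, expected):
    """Proportional mortality ``max(0, 1 - pupae/expected)``, clipped to [0,1]."""
    pupae = np.asarray(pupae, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if np.any(expected <= 0):
        raise ValueError("expected totals must be positive")
    out = np.clip(1.0 - pupae / expected, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def summarize_groups(
    df: pd.DataFrame, by=("cultivar", "life_stage", "duration_days")
) -> list[MortalitySummary]:
    """Per-group medians and ranges of box-level mortality.

    Boxes (not fruit) are the summary unit; percentages carry one decimal.
    Empty groups are simply absent from the output.
    """
    df = df.copy()
    if "mortality" not in df.columns:
        df["mortality"] = mortality_from_counts(
            df["pupae_count"], df["treated_estimate"]
        )
    out = []
    for keys, g in df.groupby(list(by), sort=True):
        keys = dict(zip(by, np.atleast_1d(keys)))
        pct = 100.0 * g["mortality"].to_numpy()
        out.append(
            MortalitySummary(
                cultivar=str(keys.get("cultivar", "all")),
                life_stage=str(keys.get("life_stage", "all")),
                duration_days=float(keys.get("duration_days", np.nan)),
                n_units=int(len(g)),
                pupae_total=int(g["pupae_count"].sum()),
                treated_total=float(g["treated_estimate"].sum()),
                median_mortality=round(float(np.median(pct)), 1),
                mortality_range=(round(float(pct.min()), 1), round(float(pct.max()), 1)),
            )
        )
    return out


def write_summary_table(summaries, path=None) -> pd.DataFrame:
    """Summaries as a D/N/P/E/M/R table (one row per group)."""
    df = pd.DataFrame(
        {
            "cultivar": [s.cultivar for s in summaries],
            "life_stage": [s.life_stage for s in summaries],
            "D": [s.duration_days for s in summaries],
            "N": [s.n_units for s in summaries],
            "P": [s.pupae_total for s in summaries],
            "E": [s.treated_total for s in summaries],
            "M": [s.median_mortality for s in summaries],
            "R_low": [s.mortality_range[0] for s in summaries],
            "R_high": [s.mortality_range[1] for s in summaries],
        }
    )
    if path is not None:
        df.to_csv(path, index=False)
    return df
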