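"""Temperature-log quality assurance for cold-treatment runs.

Cold stores log air and fruit-core probes on a nominal 30-minute grid.  QA
consists of: ice-bath calibration offsets, the cool-down time (elapsed hours
until the fruit cores first read below 3.5 deg C -- by default the
large-scale "majority" rule, strictly more than half the probes), the
constancy percentage (post-cool-down fruit readings within +/-0.5 deg C of
the 3 deg C target, band inclusive), and a one-row profile summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureLog",
    "CooldownResult",
    "ProfileSummary",
    "calibrate",
    "apply_calibration",
    "cooldown_time",
    "constancy",
    "profile_summary",
    "read_temperature_logs",
    "write_temperature_logs",
]


@dataclass
class TemperatureLog:
    """One probe's time series.  ``offset`` is added to raw readings."""

    probe_id: str
    kind: str                      # 'air' | 'fruit'
    hours: np.ndarray              # elapsed hours since loading, increasing
    readings: np.ndarray           # raw deg C
    offset: float = 0.0

    def __post_init__(self):
        self.hours = np.asarray(self.hours, dtype=float)
        self.readings = np.asarray(self.readings, dtype=float)
        if self.kind not in ("air", "fruit"):
            raise ValueError("probe kind must be 'air' or 'fruit'")
        if len(self.hours) != len(self.readings):
            raise ValueError("hours and readings must have equal length")
        if len(self.hours) and np.any(np.diff(self.hours) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.readings)):
            raise ValueError("readings must be finite")

    @property
    def corrected(self) -> np.ndarray:
        return self.readings + self.offset


@dataclass(frozen=True)
class CooldownResult:
    hours: float
    reached: bool
    index: int | None  # sample index of the crossing, None if never reached


@dataclass(frozen=True)
class ProfileSummary:
    """The six summary fields of a treatment temperature profile."""

    start_mean: float
    overall_mean: float
    cooldown_hours: float
    cooldown_reached: bool
    post_cooldown_mean: float
    post_cooldown_sd: float
    constancy_pct: float


def calibrate(ice_bath_readings: dict[str, np.ndarray], min_readings: int = 10) -> dict[str, float]:
    """Per-probe offsets from an ice-bath run: ``offset = 0 - mean(raw)``."""
    offsets = {}
    for probe, readings in ice_bath_readings.items():
        readings = np.asarray(readings, dtype=float)
        if readings.size == 0:
            raise ValueError(f"no ice-bath readings for probe {probe!r}")
        if readings.size < min_readings:
            raise ValueError(
                f"probe {probe!r} has {readings.size} ice-bath readings; "
                f"need at least {min_readings}"
            )
        offsets[probe] = float(0.0 - np.mean(readings))
    return offsets


def apply_calibration(logs: list[TemperatureLog], offsets: dict[str, float]) -> list[TemperatureLog]:
    """Return logs with calibration offsets attached (missing probes keep 0)."""
    return [
        TemperatureLog(
            probe_id=lg.probe_id, kind=lg.kind, hours=lg.hours,
            readings=lg.readings, offset=offsets.get(lg.probe_id, lg.offset),
        )
        for lg in logs
    ]


def _fruit_matrix(logs: list[TemperatureLog]):
    fruit = [lg for lg in logs if lg.kind == "fruit"]
    if not fruit:
        raise ValueError("no fruit probes in the log set")
    n = len(fruit[0].hours)
    for lg in fruit:
        if len(lg.hours) != n or not np.allclose(lg.hours, fruit[0].hours):
            raise ValueError("fruit probes must share a common time grid")
    mat = np.vstack([lg.corrected for lg in fruit])
    return fruit[0].hours, mat


def cooldown_time(
    logs: list[TemperatureLog], threshold: float = 3.5, rule: str = "majority"
) -> CooldownResult:
    """Elapsed hours until the fruit cores first read below ``threshold``.

    ``rule='majority'`` (large-scale trials): the first sample at which
    strictly more than half of the fruit probes read below the threshold.
    ``rule='mean'`` (cold-tolerance years): the first sample at which the
    mean fruit-core reading is below the threshold.  Resolution is the
    sampling interval; a never-reached threshold is flagged, not raised.
    """
    hours, mat = _fruit_matrix(logs)
    if rule == "majority":
        below = (mat < threshold).sum(axis=0)
        ok = below > mat.shape[0] / 2.0
    elif rule == "mean":
        ok = mat.mean(axis=0) < threshold
    else:
        raise ValueError("rule must be 'majority' or 'mean'")
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        return CooldownResult(hours=float("nan"), reached=False, index=None)
    i = int(idx[0])
    return CooldownResult(hours=float(hours[i] - hours[0]), reached=True, index=i)


def constancy(
    logs: list[TemperatureLog],
    target: float = 3.0,
    band: float = 0.5,
    after: CooldownResult | int | None = None,
    rule: str = "majority",
) -> float:
    """Percent of post-cool-down fruit readings within ``target +/- band``.

    The band is inclusive at both ends.  ``after`` may be a
    :class:`CooldownResult` or a sample index; by default the cool-down is
    computed here with the given rule.
    """
    _, mat = _fruit_matrix(logs)
    if after is None:
        after = cooldown_time(logs, rule=rule)
    if isinstance(after, CooldownResult):
        if not after.reached:
            raise ValueError("cool-down never reached; no post-cool-down window")
        start = after.index
    else:
        start = int(after)
    post = mat[:, start:]
    if post.size == 0:
        raise ValueError("no post-cool-down readings")
    within = (post >= target - band) & (post <= target + band)
    return float(100.0 * within.sum() / post.size)


def profile_summary(
    logs: list[TemperatureLog],
    threshold: float = 3.5,
    target: float = 3.0,
    band: float = 0.5,
    rule: str = "majority",
) -> ProfileSummary:
    """One summary row: start/overall means, cool-down, post-cool-down
    fruit-core mean/sd and constancy.  Fruit-core statistics use fruit
    probes only; the overall mean includes air probes.
    """
    hours, fruit = _fruit_matrix(logs)
    all_mat = np.concatenate([lg.corrected for lg in logs])
    cd = cooldown_time(logs, threshold=threshold, rule=rule)
    if cd.reached:
        post = fruit[:, cd.index:]
        post_mean = float(post.mean())
        post_sd = float(post.std(ddof=1)) if post.size > 1 else 0.0
        const = constancy(logs, target=target, band=band, after=cd)
        cd_hours = cd.hours
    else:
        post_mean = float("nan")
        post_sd = float("nan")
        const = float("nan")
        cd_hours = float("nan")
    return ProfileSummary(
        start_mean=float(fruit[:, 0].mean()),
        overall_mean=float(all_mat.mean()),
        cooldown_hours=cd_hours,
        cooldown_reached=cd.reached,
        post_cooldown_mean=post_mean,
        post_cooldown_sd=post_sd,
        constancy_pct=const,
    )


# ---------------------------------------------------------------------------
# delimited-text I/O (probe_id, kind, hours, reading_c)


def read_temperature_logs(path) -> list[TemperatureLog]:
    df = pd.read_csv(path)
    required = {"probe_id", "kind", "hours", "reading_c"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"temperature log missing columns: {sorted(missing)}")
    logs = []
    for probe, g in df.groupby("probe_id", sort=True):
        g = g.sort_values("hours")
        logs.append(
            TemperatureLog(
                probe_id=str(probe),
                kind=str(g["kind"].iloc[0]),
                hours=g["hours"].to_numpy(dtype=float),
                readings=g["reading_c"].to_numpy(dtype=float),
            )
        )
    return logs


def write_temperature_logs(logs: list[TemperatureLog], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "probe_id": lg.probe_id,
                "kind": lg.kind,
                "hours": lg.hours,
                "reading_c": lg.readings,
            }
        )
        for lg in logs
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
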