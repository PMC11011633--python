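"""Bundled published summary data.

The package ships the duration-level bioassay totals of the 2018-2019
kiwifruit cold-tolerance experiments (Mediterranean fruit fly in 'Hayward'
and 'Zesy002'), transcribed from the published summary tables: per cultivar,
life stage and treatment duration, the number of boxes, pupae retrieved (P)
and estimated number treated (E).  Box-level raw data were not published, so
these totals are the finest granularity available for refits.

Also bundled as constants: the large-scale trial pupal counts and the
printed per-fruit summary statistics used for treated-number extrapolation.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_bioassay_totals",
    "LARGE_SCALE_CONTROL_COUNTS",
    "LARGE_SCALE_TREATED_COUNTS",
    "LARGE_SCALE_FRUIT",
    "ANCILLARY_PUPAE_PER_FRUIT",
    "DISSECTION_LIVE_L3",
]

#: Per-replicate pupae recovered from the 200 untreated control fruit.
LARGE_SCALE_CONTROL_COUNTS = (10226, 10598, 10625)

#: Pupae recovered per replicate by treatment duration (days).
LARGE_SCALE_TREATED_COUNTS = {
    8: (187, 188, 188),
    10: (41, 37, 40),
    18: (0, 0, 0),
}

#: Fruit infested per replicate by role.
LARGE_SCALE_FRUIT = {"control": 200, 8: 180, 10: 180, 18: 3400, "dissect": 10}

#: Ancillary trial: mean pupae per fruit, its standard error, sample size.
ANCILLARY_PUPAE_PER_FRUIT = {"mean": 51.0, "se": 0.987, "n": 30}

#: Dissections: mean live third instars per fruit and SE, per replicate.
DISSECTION_LIVE_L3 = (
    {"mean": 77.1, "se": 1.53},
    {"mean": 74.3, "se": 1.65},
    {"mean": 77.6, "se": 1.28},
)


def load_bioassay_totals(cultivar: str | None = None, life_stage: str | None = None) -> pd.DataFrame:
    """Duration-level bioassay totals, optionally filtered.

    Columns: cultivar, life_stage, duration_days, n_boxes, pupae_count,
    treated_estimate.  Each row aggregates all boxes of one cultivar x stage
    x duration cell over both study years, so refits of these totals treat
    each row as a single beta-binomial observation.
    """
    ref = resources.files("coldtreat") / "data" / "bioassay_totals_2018_2019.csv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    if cultivar is not None:
        df = df[df["cultivar"] == cultivar]
    if life_stage is not None:
        df = df[df["life_stage"] == life_stage]
    return df.reset_index(drop=True)
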