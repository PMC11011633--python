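import numpy as np
import pandas as pd
import pytest

import coldtreat as ct
from coldtreat.bioassay import betabinom_rvs
from coldtreat.datasets import load_bioassay_totals


def simulate_boxes(
    alpha=-3.0,
    beta=0.8,
    rho=0.05,
    link="logit",
    n_boxes=50,
    box_n=100,
    durations=(0, 2, 4, 6, 8, 10),
    seed=0,
    sigma_u=0.0,
    n_replicates=4,
    stage="L3",
):
    """Single-stage box-level simulator used as the known-truth workhorse."""
    rng = np.random.default_rng(seed)
    rows = []
    reps = [f"R{i}" for i in range(n_replicates)]
    u = {r: (rng.normal(0.0, sigma_u) if sigma_u > 0 else 0.0) for r in reps}
    for i in range(n_boxes):
        # block assignment keeps replicates crossed with durations
        t = float(durations[i % len(durations)])
        rep = reps[(i // len(durations)) % n_replicates]
        p = ct.link_inverse(alpha + beta * t + u[rep], link)
        dead = int(betabinom_rvs(box_n, p, rho, rng))
        rows.append(
            dict(
                year="sim", cultivar="c", life_stage=stage, replicate=rep,
                duration_days=t, unit_id=f"B{i}",
                pupae_count=box_n - dead, treated_estimate=float(box_n),
            )
        )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def l3_totals():
    return load_bioassay_totals(life_stage="L3")


@pytest.fixture(scope="session")
def hayward_l3_totals():
    return load_bioassay_totals(cultivar="Hayward", life_stage="L3")


@pytest.fixture(scope="session")
def sim_data():
    return simulate_boxes(seed=11)


@pytest.fixture(scope="session")
def sim_fit(sim_data):
    fit = ct.fit_fixed(sim_data, ct.ModelSpec(link="logit"))
    assert fit.converged
    return fit
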