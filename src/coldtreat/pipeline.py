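"""End-to-end analysis pipeline: validate, fit, invert, summarize, report.

The pipeline is a pure function of (inputs, configuration, seed).  Given a
box-level (or duration-level) bioassay table it fits the time-mortality
model (per cultivar and combined, link chosen by AIC unless forced), writes
lethal-time tables, mortality summaries, an efficacy report when control
counts are supplied, and a temperature-profile summary when a log is
supplied.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bioassay, efficacy, lethal_time, summaries, thermal

__all__ = ["RunConfig", "Diagnostic", "validate_inputs", "run_analysis"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-loadable)."""

    input: str | None = None
    out_dir: str = "coldtreat_out"
    link: str = "auto"                       # 'probit' | 'logit' | 'auto'
    levels: tuple[float, ...] = (50.0, 95.0, 99.0, 99.9968)  # percent
    confidence_level: float = 0.95
    method: str = "two_sided_t"
    probit9: float = 0.999968
    seed: int = 0
    random: str | None = None                # random-intercept structure
    temperature_input: str | None = None
    control_counts: tuple[float, ...] | None = None
    n_control_fruit: int | None = None
    n_treated_fruit: int | None = None
    survivors: int = 0

    def __post_init__(self):
        for lv in self.levels:
            if not 0.0 < lv < 100.0:
                raise ValueError("mortality levels must lie in (0, 100) percent")
        if self.link not in ("probit", "logit", "auto"):
            raise ValueError("link must be 'probit', 'logit' or 'auto'")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("levels", "control_counts"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class Diagnostic:
    severity: str   # 'error' | 'warning'
    row: int | None
    message: str


def validate_inputs(path) -> list[Diagnostic]:
    """Schema/type/range report for a bioassay input file."""
    diags: list[Diagnostic] = []
    df = pd.read_csv(path)
    required = ("life_stage", "duration_days", "pupae_count", "treated_estimate")
    for col in required:
        if col not in df.columns:
            diags.append(Diagnostic("error", None, f"missing column {col!r}"))
    if diags:
        return diags
    for i, row in df.iterrows():
        line = int(i) + 2  # header is line 1
        if not np.isfinite(row["duration_days"]) or row["duration_days"] < 0:
            diags.append(Diagnostic("error", line, "duration_days must be >= 0"))
        if row["pupae_count"] < 0:
            diags.append(Diagnostic("error", line, "pupae_count must be >= 0"))
        if row["treated_estimate"] <= 0:
            diags.append(Diagnostic("error", line, "treated_estimate must be > 0"))
    if "unit_id" in df.columns:
        group_cols = [c for c in ("cultivar", "life_stage", "duration_days") if c in df.columns]
        dup = df.duplicated(subset=group_cols + ["unit_id"], keep=False)
        for i in df.index[dup]:
            diags.append(Diagnostic("warning", int(i) + 2, "duplicated unit_id within group"))
    return diags


def _fit_one(df, link, random):
    spec_kw = dict(random=random) if random else {}
    if link == "auto":
        fit = bioassay.select_link(df, bioassay.ModelSpec(**spec_kw))
    else:
        spec = bioassay.ModelSpec(link=link, **spec_kw)
        fit = bioassay.fit_mixed(df, spec) if random else bioassay.fit_fixed(df, spec)
    return fit


def run_analysis(config: RunConfig) -> dict:
    """Run the configured pipeline and write its report bundle.

    Returns the report dictionary; raises on malformed inputs or
    non-convergence so callers can exit non-zero.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config), "outputs": []}
    log_lines: list[str] = []
    ps = [lv / 100.0 for lv in config.levels]

    if config.input is not None:
        diags = validate_inputs(config.input)
        errors = [d for d in diags if d.severity == "error"]
        if errors:
            raise ValueError(
                "malformed input rows: "
                + "; ".join(f"line {d.row}: {d.message}" for d in errors)
            )
        for d in diags:
            log_lines.append(f"{d.severity}: line {d.row}: {d.message}")
        df = bioassay.read_observations(config.input)

        fits: dict[str, bioassay.ModelFit] = {}
        fits["combined"] = _fit_one(df, config.link, config.random)
        for cv in sorted(df["cultivar"].unique()):
            if cv != "all" and df["cultivar"].nunique() > 1:
                fits[str(cv)] = _fit_one(df[df["cultivar"] == cv], config.link, config.random)

        report["fits"] = {}
        for name, fit in fits.items():
            if not fit.converged:
                raise RuntimeError(f"model fit {name!r} did not converge")
            fit.to_json(out / f"fit_{name}.json")
            table = lethal_time.lt_table(fit, ps=ps, level=config.confidence_level)
            wide = lethal_time.format_lt_table(table)
            wide.to_csv(out / f"lt_table_{name}.csv", index=False)
            report["outputs"] += [f"fit_{name}.json", f"lt_table_{name}.csv"]
            report["fits"][name] = {
                "link": fit.spec.link,
                "aic": fit.aic,
                "loglik": fit.loglik,
                "warnings": list(fit.warnings),
                "lt": [dataclasses.asdict(e) for e in table],
            }
            log_lines.append(f"fit {name}: link={fit.spec.link} aic={fit.aic:.2f}")

        summ = summaries.summarize_groups(df)
        summaries.write_summary_table(summ, out / "mortality_summary.csv")
        report["outputs"].append("mortality_summary.csv")

    if config.control_counts is not None:
        if config.n_control_fruit is None or config.n_treated_fruit is None:
            raise ValueError("control counts need n_control_fruit and n_treated_fruit")
        rep = efficacy.efficacy_report(
            config.control_counts,
            config.n_control_fruit,
            config.n_treated_fruit,
            survivors=config.survivors,
            target_mortality=config.probit9,
            level=config.confidence_level,
        )
        with open(out / "efficacy.json", "w") as fh:
            json.dump(rep, fh, indent=1)
        report["efficacy"] = rep
        report["outputs"].append("efficacy.json")
        log_lines.append(rep["statement"])

    if config.temperature_input is not None:
        logs = thermal.read_temperature_logs(config.temperature_input)
        prof = thermal.profile_summary(logs)
        pd.DataFrame([dataclasses.asdict(prof)]).to_csv(
            out / "thermal_summary.csv", index=False
        )
        report["thermal"] = dataclasses.asdict(prof)
        report["outputs"].append("thermal_summary.csv")
        log_lines.append(f"cool-down {prof.cooldown_hours:.1f} h, constancy {prof.constancy_pct:.1f}%")

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return report
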