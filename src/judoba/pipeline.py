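"""End-to-end contest analysis pipeline.

Stages mirror the study workflow: simulate a cohort, summarise each
contest, compare the six cells robustly, test axis uniformity, build the
Poisson scenario table, and render report tables. Every stage consumes
only the run configuration or files written by an earlier stage, and all
randomness flows from the single run seed, so a rerun with the same
configuration is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .accelio import (
    OUTCOME_LABELS,
    group_table,
    read_epoch_csv,
    summaries_frame,
    summarize_trace,
    write_epoch_csv,
)
from .model import RobustFactorialANOVA
from .robust import PowerQuery, chisq_axis_uniformity, required_group_n
from .scenarios import build_scenario_table, scenario_frame
from .synthgen import ContestDesign, generate_cohort, load_cohort_config
from .types import AXES, ConfigurationError

log = logging.getLogger("judoba")

SCHEMA_VERSION = 1

#: outcomes compared across cells in the report
COMPARED_OUTCOMES = (
    "vm_cpm", "axis1_cpm", "axis2_cpm", "axis3_cpm",
    "hr_max_contest", "pct_hrmax", "bla", "rpe",
)


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    cohort_path: str | Path
    seed: int
    out_dir: str | Path
    design: ContestDesign = field(default_factory=ContestDesign)
    trim: float = 0.20
    n_sims: int = 10_000
    scenario_mode: str = "exact"
    probability_definition: str = "point"
    posthoc_method: str = "smm"
    alpha: float = 0.05

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        self.design.validate()
        if not 0 <= self.trim < 0.5:
            raise ConfigurationError("trim must lie in [0, 0.5)")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def simulate_stage(config: RunConfig) -> tuple[Path, Path]:
    """Generate the cohort; write per-athlete epoch CSVs and the manifest."""
    specs = load_cohort_config(config.cohort_path)
    config.validate()
    out = Path(config.out_dir)
    cohort = generate_cohort(specs, config.design, config.seed)  # validates first
    traces_dir = out / "traces"
    traces_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for profile, trace, physio in cohort:
        write_epoch_csv(trace, traces_dir / f"{profile.athlete_id}.csv")
        rows.append(
            {
                "athlete_id": profile.athlete_id,
                "sex": profile.sex,
                "weight_class": profile.weight_class,
                "group": profile.group,
                "age": round(physio.age, 4),
                "hr_max_contest": round(physio.hr_max_contest, 4),
                "pct_hrmax": round(physio.pct_hrmax, 4),
                "bla": round(physio.bla, 4),
                "rpe": round(physio.rpe, 4),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest_path = out / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    log.info("simulate: %d athletes, %d groups", len(rows), len(specs))
    return traces_dir, manifest_path


def summarize_stage(traces_dir: Path, manifest_path: Path, out: Path) -> Path:
    """Reduce every trace to contest outcomes; write summaries.tsv."""
    manifest = pd.read_csv(manifest_path)
    rows = []
    for _, m in manifest.iterrows():
        trace = read_epoch_csv(traces_dir / f"{m['athlete_id']}.csv")
        s = summarize_trace(trace)
        rows.append(s)
    df = summaries_frame(rows)
    # physiology comes from the manifest, not the trace files
    phys = manifest[["athlete_id", "hr_max_contest", "pct_hrmax", "bla", "rpe"]]
    df = df.drop(columns=["hr_max_contest", "pct_hrmax", "bla", "rpe"]).merge(
        phys, on="athlete_id"
    )
    path = out / "summaries.tsv"
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    log.info("summarize: %d contests", len(df))
    return path


def compare_stage(
    summaries_path: Path, manifest_path: Path, out: Path, config: RunConfig
) -> dict:
    """Robust factorial comparison of every outcome plus axis uniformity."""
    df = pd.read_csv(summaries_path, sep="\t")
    manifest = pd.read_csv(manifest_path)
    merged = df.merge(manifest[["athlete_id", "sex", "weight_class"]], on="athlete_id")

    gt = group_table(df, manifest)
    gt_path = out / "group_table.tsv"
    gt.to_csv(gt_path, sep="\t", index=False, float_format="%.6f")

    effects, contrasts = {}, {}
    for outcome in COMPARED_OUTCOMES:
        model = RobustFactorialANOVA(merged, outcome)
        res = model.fit(
            trim=config.trim, alpha=config.alpha, posthoc_method=config.posthoc_method
        )
        t = res.test
        effects[outcome] = {
            "q_sex": t.q_sex, "q_weight": t.q_weight,
            "q_interaction": t.q_interaction,
            "p_sex": t.p_sex, "p_weight": t.p_weight,
            "p_interaction": t.p_interaction,
        }
        contrasts[outcome] = [
            {
                "cell_a": c.cell_a, "cell_b": c.cell_b, "diff": c.diff,
                "p": c.p, "significant": c.significant,
                "r": c.r, "magnitude": c.magnitude,
            }
            for c in res.contrasts
        ]

    # per-group mean axis shares feed the uniformity test and scenarios
    merged["group"] = (
        merged["sex"].str[0].str.upper() + merged["weight_class"].str[0].str.upper()
    )
    share_means = merged.groupby("group", sort=True)[
        ["axis1_pct", "axis2_pct", "axis3_pct"]
    ].mean()
    uniformity = {}
    for group, row in share_means.iterrows():
        chi2, p = chisq_axis_uniformity(tuple(row))
        uniformity[group] = {"chi2": chi2, "p": p,
                             "shares": [float(v) for v in row]}
    log.info("compare: %d outcomes, %d groups", len(effects), len(uniformity))
    return {
        "group_table_path": str(gt_path),
        "group_table": gt.to_dict(orient="records"),
        "effects": effects,
        "contrasts": contrasts,
        "uniformity": uniformity,
        "axis_share_means": {
            g: dict(zip(AXES, (float(v) for v in row)))
            for g, row in share_means.iterrows()
        },
    }


def scenarios_stage(axis_share_means: dict, out: Path, config: RunConfig) -> dict:
    """Poisson scenario table from the per-group mean axis shares."""
    cells = build_scenario_table(
        axis_share_means,
        n_sims=config.n_sims,
        seed=config.seed,
        mode=config.scenario_mode,
        probability_definition=config.probability_definition,
    )
    frame = scenario_frame(cells)
    path = out / "scenario_table.tsv"
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")
    log.info("scenarios: %d cells x %d simulations", len(cells), config.n_sims)
    return {"scenario_table_path": str(path),
            "scenarios": frame.to_dict(orient="records")}


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle.

    Produces traces/, manifest.csv, summaries.tsv, group_table.tsv,
    scenario_table.tsv, rendered report tables, results.json and a run
    log with versions, the seed and content hashes of every output.
    """
    config.validate()
    specs = load_cohort_config(config.cohort_path)  # fail before writing anything
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    traces_dir, manifest_path = simulate_stage(config)
    summaries_path = summarize_stage(traces_dir, manifest_path, out)
    compare = compare_stage(summaries_path, manifest_path, out, config)
    scen = scenarios_stage(compare["axis_share_means"], out, config)

    power_n = required_group_n(PowerQuery(k_groups=len(specs), effect_f=0.40,
                                          alpha=0.05, power=0.85))
    results = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "package_version": __version__,
        "design": {
            "contest_seconds": config.design.contest_seconds,
            "epoch_seconds": config.design.epoch_seconds,
            "effort_min_s": config.design.effort_min_s,
            "effort_max_s": config.design.effort_max_s,
            "break_s": config.design.break_s,
            "break_intensity_fraction": config.design.break_intensity_fraction,
            "epoch_cv": config.design.epoch_cv,
        },
        "analysis": {
            "trim": config.trim, "alpha": config.alpha,
            "posthoc_method": config.posthoc_method,
            "scenario_mode": config.scenario_mode,
            "n_sims": config.n_sims,
            "probability_definition": config.probability_definition,
        },
        "power": {"k_groups": len(specs), "effect_f": 0.40, "alpha": 0.05,
                  "power": 0.85, "required_n_per_group": power_n},
        "group_table": compare["group_table"],
        "effects": compare["effects"],
        "contrasts": compare["contrasts"],
        "uniformity": compare["uniformity"],
        "scenarios": scen["scenarios"],
    }
    results_path = out / "results.json"
    results_path.write_text(json.dumps(results, indent=2, sort_keys=True))

    render_tables(results, out)

    outputs = sorted(
        p for p in out.rglob("*")
        if p.is_file() and p.name != "run_log.json"
    )
    run_log = {
        "package_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "cohort_config": str(config.cohort_path),
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))
    log.info("report bundle written to %s", out)
    return results


# ---------------------------------------------------------------------------
# table rendering

def _fmt(value: float, decimals: int = 1) -> str:
    return f"{value:,.{decimals}f}"


def format_mean_sd(mean: float, sd: float, pct: tuple[float, float] | None = None,
                   decimals: int = 1) -> str:
    """Render ``mean ± sd`` (with an axis-share parenthetical if given),
    e.g. ``4,588.2 ± 1,028.1 (29.3 ± 4.3)``."""
    base = f"{_fmt(mean, decimals)} ± {_fmt(sd, decimals)}"
    if pct is not None:
        base += f" ({_fmt(pct[0], decimals)} ± {_fmt(pct[1], decimals)})"
    return base


_CELL_RE = re.compile(
    r"^\s*([\d,.\-]+)\s*±\s*([\d,.\-]+)"
    r"(?:\s*\(\s*([\d,.\-]+)\s*±\s*([\d,.\-]+)\s*\))?\s*$"
)


def parse_mean_sd(cell: str) -> tuple[float, ...]:
    """Inverse of :func:`format_mean_sd` (to formatting precision)."""
    m = _CELL_RE.match(cell)
    if not m:
        raise ValueError(f"unparseable cell {cell!r}")
    vals = [float(g.replace(",", "")) for g in m.groups() if g is not None]
    return tuple(vals)


#: outcome -> axis-share column paired into its parenthetical
_AXIS_PCT_FOR = {"axis1_cpm": "axis1_pct", "axis2_cpm": "axis2_pct",
                 "axis3_cpm": "axis3_pct"}


def render_tables(results: dict, out: Path) -> dict[str, pd.DataFrame]:
    """Render the report tables (formatted strings) and write them as TSV.

    The outcome table carries one ``mean ± sd`` cell per group (axis rows
    get their percentage share in parentheses), the three factorial
    p-values, and a significance flag column for p < 0.05.
    """
    out.mkdir(parents=True, exist_ok=True)
    gt = pd.DataFrame(results.get("group_table", []))
    effects = results.get("effects", {})
    alpha = results.get("analysis", {}).get("alpha", 0.05)

    rows = []
    if not gt.empty:
        groups = sorted(gt["cell"].unique())
        stats_by = {(r["outcome"], r["cell"]): r for r in gt.to_dict(orient="records")}
        for outcome in COMPARED_OUTCOMES:
            if outcome not in set(gt["outcome"]):
                continue
            row: dict = {"outcome": OUTCOME_LABELS.get(outcome, outcome)}
            for g in groups:
                rec = stats_by.get((outcome, g))
                if rec is None or rec["n"] == 0:
                    row[g] = ""
                    continue
                pct_col = _AXIS_PCT_FOR.get(outcome)
                pct = None
                if pct_col and (pct_col, g) in stats_by:
                    prec = stats_by[(pct_col, g)]
                    pct = (prec["mean"], prec["sd"])
                row[g] = format_mean_sd(rec["mean"], rec["sd"], pct)
            eff = effects.get(outcome, {})
            for key, col in (("p_sex", "p_sex"), ("p_weight", "p_weight"),
                             ("p_interaction", "p_interaction")):
                p = eff.get(key)
                row[col] = "" if p is None else f"{p:.3f}"
            sig = [k for k in ("p_sex", "p_weight", "p_interaction")
                   if eff.get(k) is not None and eff[k] < alpha]
            row["significant_effects"] = ",".join(s.removeprefix("p_") for s in sig)
            rows.append(row)
    outcome_table = pd.DataFrame(rows)
    outcome_table.to_csv(out / "report_outcomes.tsv", sep="\t", index=False)

    scen = pd.DataFrame(results.get("scenarios", []))
    scen_rows = []
    if not scen.empty:
        for axis in AXES:
            sub = scen[scen["axis"] == axis]
            for kind, vcol, pcol in (("Upper", "upper_value", "upper_prob"),
                                     ("Median", "median_value", "median_prob"),
                                     ("Lower", "lower_value", "lower_prob")):
                row = {"axis": axis, "scenario": kind}
                for _, c in sub.iterrows():
                    row[c["group"]] = f"{int(c[vcol])}% ({100 * c[pcol]:.1f}%)"
                scen_rows.append(row)
    scenario_table = pd.DataFrame(scen_rows)
    scenario_table.to_csv(out / "report_scenarios.tsv", sep="\t", index=False)
    return {"outcomes": outcome_table, "scenarios": scenario_table}
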