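"""Epoch CSV input/output and accelerometric outcome reduction.

The epoch CSV dialect is one file per athlete with header
``t_start_s,axis1,axis2,axis3`` (any column order), integer counts, one
row per 3-second epoch. Traces reduce to the contest outcomes the
analysis compares: vector-magnitude counts per minute (vm_cpm), per-axis
cpm, and per-axis percentage shares.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import AXES, ContestSummary, ContestTrace, PhysiologyRecord, TraceFormatError

__all__ = [
    "group_table",
    "read_epoch_csv",
    "summarize_trace",
    "vector_magnitude",
    "write_epoch_csv",
]

EPOCH_CSV_COLUMNS = ("t_start_s", "axis1", "axis2", "axis3")

#: outcome column -> printable name, in reporting order
OUTCOME_LABELS = {
    "vm_cpm": "BA (a.u./cpm)",
    "axis1_cpm": "BA vertical axis (a.u./cpm)",
    "axis2_cpm": "BA mediolateral axis (a.u./cpm)",
    "axis3_cpm": "BA anteroposterior axis (a.u./cpm)",
    "axis1_pct": "Vertical axis share (%)",
    "axis2_pct": "Mediolateral axis share (%)",
    "axis3_pct": "Anteroposterior axis share (%)",
    "hr_max_contest": "Maximum contest HR (b/min)",
    "pct_hrmax": "Maximum contest HR (% HRmax)",
    "bla": "BLa 1 min post-contest (mmol/L)",
    "rpe": "RPE (Borg 6-20)",
}


def vector_magnitude(x, y, z):
    """Euclidean norm of per-epoch axis counts, VM = sqrt(x^2 + y^2 + z^2).

    Accepts scalars or arrays; counts must be non-negative.
    """
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    if (x < 0).any() or (y < 0).any() or (z < 0).any():
        raise ValueError("axis counts must be non-negative")
    out = np.sqrt(x * x + y * y + z * z)
    return float(out) if out.ndim == 0 else out


def summarize_trace(
    trace: ContestTrace, physiology: PhysiologyRecord | None = None
) -> ContestSummary:
    """Reduce one trace to its contest outcomes.

    Per-axis cpm is the contest total of that axis scaled to one minute.
    vm_cpm applies the vector magnitude per epoch *before* aggregating
    (the norm is nonlinear, so order matters): per-epoch VMs are summed
    within each contest minute and the per-minute sums averaged. Axis
    percentages are each axis's cpm over the summed axis cpm.
    """
    if trace.n_epochs == 0:
        raise TraceFormatError("empty trace")
    epoch_s = trace.epoch_seconds  # validates uniform spacing
    contest_s = trace.contest_seconds
    per_min = 60.0 / contest_s

    axis_tot = trace.counts.sum(axis=0).astype(float)
    axis_cpm = tuple(axis_tot * per_min)
    total = sum(axis_cpm)
    if total > 0:
        axis_pct = tuple(100.0 * a / total for a in axis_cpm)
    else:
        axis_pct = (0.0, 0.0, 0.0)

    epoch_vm = vector_magnitude(*trace.counts.T)
    epochs_per_min = 60 // epoch_s if 60 % epoch_s == 0 else None
    if epochs_per_min and trace.n_epochs % epochs_per_min == 0:
        minute_sums = epoch_vm.reshape(-1, epochs_per_min).sum(axis=1)
        vm_cpm = float(minute_sums.mean())
    else:  # partial final minute: fall back to the equivalent total-based rate
        vm_cpm = float(epoch_vm.sum() * per_min)

    kwargs = {}
    if physiology is not None:
        kwargs = dict(
            hr_max_contest=physiology.hr_max_contest,
            pct_hrmax=physiology.pct_hrmax,
            bla=physiology.bla,
            rpe=physiology.rpe,
        )
    return ContestSummary(
        athlete_id=trace.athlete_id,
        vm_cpm=vm_cpm,
        axis_cpm=axis_cpm,
        axis_pct=axis_pct,
        **kwargs,
    )


def write_epoch_csv(trace: ContestTrace, path: str | Path) -> None:
    """Write a trace in the epoch CSV dialect."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(EPOCH_CSV_COLUMNS)
        for t, (a1, a2, a3) in zip(trace.t_start, trace.counts):
            writer.writerow([int(t), int(a1), int(a2), int(a3)])


def read_epoch_csv(path: str | Path, athlete_id: str | None = None) -> ContestTrace:
    """Read an epoch CSV, enforcing the dialect strictly.

    Raises :class:`TraceFormatError` naming the offending line for a
    missing column, non-integer or negative count, or non-uniform epoch
    spacing. Column order is free as long as the names match.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise TraceFormatError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        missing = set(EPOCH_CSV_COLUMNS) - set(header)
        if missing:
            raise TraceFormatError(f"{path}: missing column(s) {sorted(missing)}")
        idx = {name: header.index(name) for name in EPOCH_CSV_COLUMNS}

        t_start, counts = [], []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                vals = [int(row[idx[c]]) for c in EPOCH_CSV_COLUMNS]
            except (ValueError, IndexError):
                raise TraceFormatError(
                    f"{path}: line {lineno}: counts must be integers"
                ) from None
            if any(v < 0 for v in vals[1:]):
                raise TraceFormatError(f"{path}: line {lineno}: negative count")
            t_start.append(vals[0])
            counts.append(vals[1:])
    if not counts:
        raise TraceFormatError(f"{path}: no epoch rows")
    t_arr = np.array(t_start, dtype=np.int64)
    if len(t_arr) >= 2:
        steps = np.diff(t_arr)
        if len(set(steps.tolist())) != 1 or steps[0] <= 0:
            bad = int(np.flatnonzero(steps != steps[0])[0]) + 3 if len(set(steps.tolist())) != 1 else 2
            raise TraceFormatError(f"{path}: line {bad}: non-uniform t_start spacing")
    return ContestTrace(
        athlete_id=athlete_id or path.stem,
        t_start=t_arr,
        counts=np.array(counts, dtype=np.int64),
    )


def summaries_frame(summaries: Iterable[ContestSummary]) -> pd.DataFrame:
    """Tidy per-athlete outcome table (one row per athlete)."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "athlete_id": s.athlete_id,
                "vm_cpm": s.vm_cpm,
                "axis1_cpm": s.axis_cpm[0],
                "axis2_cpm": s.axis_cpm[1],
                "axis3_cpm": s.axis_cpm[2],
                "axis1_pct": s.axis_pct[0],
                "axis2_pct": s.axis_pct[1],
                "axis3_pct": s.axis_pct[2],
                "hr_max_contest": s.hr_max_contest,
                "pct_hrmax": s.pct_hrmax,
                "bla": s.bla,
                "rpe": s.rpe,
            }
        )
    return pd.DataFrame(rows)


def group_table(
    summaries: Iterable[ContestSummary] | pd.DataFrame,
    manifest: pd.DataFrame,
    outcomes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Cell-level mean +/- SD table for every outcome.

    ``manifest`` maps ``athlete_id`` to ``sex`` and ``weight_class``;
    every athlete must fall in exactly one cell. Cell SD is the sample SD
    (n-1); a one-athlete cell gets sd=0 with ``sd_undefined=True``. Axis
    percentage cells average per-athlete percentages (mean-of-ratios),
    matching how a summary with an SD per cell must have been formed.
    Empty cells are emitted as missing rows with n=0.
    """
    df = summaries if isinstance(summaries, pd.DataFrame) else summaries_frame(summaries)
    required = {"athlete_id", "sex", "weight_class"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest needs columns {sorted(required)}")
    if manifest["athlete_id"].duplicated().any():
        dupes = manifest.loc[manifest["athlete_id"].duplicated(), "athlete_id"]
        raise ValueError(f"manifest maps athletes to multiple cells: {list(dupes)}")
    unmapped = set(df["athlete_id"]) - set(manifest["athlete_id"])
    if unmapped:
        raise ValueError(f"athletes missing from manifest: {sorted(unmapped)}")

    merged = df.merge(manifest[["athlete_id", "sex", "weight_class"]], on="athlete_id")
    merged["cell"] = (
        merged["sex"].str[0].str.upper() + merged["weight_class"].str[0].str.upper()
    )
    if outcomes is None:
        outcomes = [c for c in OUTCOME_LABELS if c in df.columns]

    cells = sorted(merged["cell"].unique())
    rows = []
    for outcome in outcomes:
        for cell in cells:
            vals = merged.loc[merged["cell"] == cell, outcome].dropna().to_numpy()
            n = len(vals)
            if n == 0:
                rows.append(
                    dict(outcome=outcome, cell=cell, mean=np.nan, sd=np.nan, n=0,
                         sd_undefined=True)
                )
                continue
            sd_undef = n < 2
            rows.append(
                dict(
                    outcome=outcome,
                    cell=cell,
                    mean=float(vals.mean()),
                    sd=0.0 if sd_undef else float(vals.std(ddof=1)),
                    n=n,
                    sd_undefined=sd_undef,
                )
            )
    return pd.DataFrame(rows)


def cells_from_summaries(
    summaries: Iterable[ContestSummary] | pd.DataFrame,
    manifest: pd.DataFrame,
    outcome: str = "vm_cpm",
) -> Mapping[tuple[str, str], np.ndarray]:
    """Split one outcome into {(sex, weight_class): values} samples."""
    df = summaries if isinstance(summaries, pd.DataFrame) else summaries_frame(summaries)
    merged = df.merge(manifest[["athlete_id", "sex", "weight_class"]], on="athlete_id")
    out = {}
    for (sex, wc), grp in merged.groupby(["sex", "weight_class"], sort=False):
        out[(sex, wc)] = grp[outcome].dropna().to_numpy(dtype=float)
    return out
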