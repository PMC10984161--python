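"""Model/Results interface over the robust factorial battery.

`RobustFactorialANOVA` is built from a tidy per-athlete DataFrame and
fits the full comparison for one outcome: distributional gates, the
Johansen-type trimmed-means factorial test, pairwise Yuen contrasts with
family-wise control, and Rosenthal effect sizes. The returned
`RobustFactorialResults` carries the estimates and renders a summary
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .robust import (
    DEFAULT_TRIM,
    GatesReport,
    PosthocContrast,
    RobustTestResult,
    distribution_gates,
    pairwise_trimmed_contrasts,
    robust_two_way,
    trimmed_mean,
)

__all__ = ["RobustFactorialANOVA", "RobustFactorialResults"]


class RobustFactorialANOVA:
    """Robust sex x weight comparison of one contest outcome.

    Parameters
    ----------
    data : DataFrame
        Tidy per-athlete table containing the outcome column and the two
        factor columns.
    outcome : str
        Column holding the dependent variable (e.g. ``"vm_cpm"``).
    sex, weight : str
        Factor column names (default ``"sex"`` and ``"weight_class"``).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcome: str,
        sex: str = "sex",
        weight: str = "weight_class",
    ) -> None:
        for col in (outcome, sex, weight):
            if col not in data.columns:
                raise ValueError(f"column {col!r} not in data")
        self.data = data
        self.outcome = outcome
        self.sex_col = sex
        self.weight_col = weight
        clean = data[[outcome, sex, weight]].dropna()
        self.cells: dict[tuple, np.ndarray] = {
            (s, w): grp[outcome].to_numpy(dtype=float)
            for (s, w), grp in clean.groupby([sex, weight], sort=True)
        }
        if not self.cells:
            raise ValueError("no non-missing observations")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str, **kwargs):
        return cls(data, outcome, **kwargs)

    def fit(
        self,
        trim: float = DEFAULT_TRIM,
        alpha: float = 0.05,
        posthoc_method: str = "smm",
    ) -> "RobustFactorialResults":
        labels = {
            key: key[0][0].upper() + str(key[1])[0].upper() for key in self.cells
        }
        gates = distribution_gates({labels[k]: v for k, v in self.cells.items()})
        test = robust_two_way(self.cells, trim=trim)
        contrasts = pairwise_trimmed_contrasts(
            {labels[k]: v for k, v in self.cells.items()},
            trim=trim,
            alpha=alpha,
            method=posthoc_method,
        )
        cell_stats = {
            labels[k]: (
                float(np.mean(v)),
                float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
                trimmed_mean(v, trim),
                len(v),
            )
            for k, v in self.cells.items()
        }
        return RobustFactorialResults(
            outcome=self.outcome,
            trim=trim,
            alpha=alpha,
            test=test,
            contrasts=contrasts,
            gates=gates,
            cell_stats=cell_stats,
        )


@dataclass
class RobustFactorialResults:
    """Fitted robust factorial comparison for one outcome."""

    outcome: str
    trim: float
    alpha: float
    test: RobustTestResult
    contrasts: list[PosthocContrast]
    gates: GatesReport
    cell_stats: dict = field(default_factory=dict)

    @property
    def significant_contrasts(self) -> list[PosthocContrast]:
        return [c for c in self.contrasts if c.significant]

    def effects_frame(self) -> pd.DataFrame:
        t = self.test
        return pd.DataFrame(
            {
                "effect": ["sex", "weight", "sex_by_weight"],
                "statistic": [t.q_sex, t.q_weight, t.q_interaction],
                "p": [t.p_sex, t.p_weight, t.p_interaction],
            }
        )

    def contrasts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_a": [c.cell_a for c in self.contrasts],
                "cell_b": [c.cell_b for c in self.contrasts],
                "diff": [c.diff for c in self.contrasts],
                "t_stat": [c.t_stat for c in self.contrasts],
                "df": [c.df for c in self.contrasts],
                "p": [c.p for c in self.contrasts],
                "significant": [c.significant for c in self.contrasts],
                "r": [c.r for c in self.contrasts],
                "magnitude": [c.magnitude for c in self.contrasts],
            }
        )

    def summary(self) -> str:
        lines = [
            f"Robust factorial comparison: {self.outcome}",
            f"  trimmed means (trim = {self.trim:.2f}), alpha = {self.alpha:.2f}",
            "",
            "  Cells (mean +/- sd [trimmed mean], n):",
        ]
        for label, (mean, sd, tmean, n) in sorted(self.cell_stats.items()):
            lines.append(
                f"    {label}: {mean:,.1f} +/- {sd:,.1f} [{tmean:,.1f}] (n={n})"
            )
        lines.append("")
        lines.append("  Effects (Johansen-corrected):")
        for _, row in self.effects_frame().iterrows():
            flag = "*" if row["p"] < self.alpha else " "
            lines.append(
                f"    {row['effect']:>14}: Q = {row['statistic']:8.3f}, "
                f"p = {row['p']:.4f} {flag}"
            )
        sig = self.significant_contrasts
        lines.append("")
        if sig:
            lines.append(f"  Significant contrasts (family-wise p < {self.alpha:g}):")
            for c in sig:
                lines.append(
                    f"    {c.cell_a} vs {c.cell_b}: p = {c.p:.4f}, "
                    f"r = {c.r:.2f} ({c.magnitude})"
                )
        else:
            lines.append("  No significant pairwise contrasts.")
        if self.gates.bartlett_p is not None:
            lines.append("")
            lines.append(
                f"  Gates: Bartlett p = {self.gates.bartlett_p:.4f}; "
                "robust battery used regardless of gate outcome."
            )
        return "\n".join(lines)
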