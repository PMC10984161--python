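"""Robust statistical battery for contest outcomes.

The six sex x weight cells are compared with heteroscedasticity-tolerant
trimmed-mean methods: a Johansen-type factorial test on 20% trimmed
means (the `t2way` procedure of the robust-ANOVA literature), pairwise
Yuen contrasts with studentized-maximum-modulus family-wise control
(`lincon`), and Rosenthal's r effect sizes from the exact
Wilcoxon-Mann-Whitney Z. Axis-share uniformity is checked with a
one-sample Pearson chi-square against equal thirds, and the study-sizing
calculation is a noncentral-F ANOVA power search. Shapiro-Wilk and
Bartlett gates report whether classical assumptions would have held.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "GatesReport",
    "PosthocContrast",
    "PowerQuery",
    "RobustTestResult",
    "anova_power",
    "chisq_axis_uniformity",
    "distribution_gates",
    "exact_u_counts",
    "pairwise_trimmed_contrasts",
    "required_group_n",
    "robust_two_way",
    "rosenthal_r",
    "trimmed_mean",
    "winsorized_variance",
    "wmw_exact_z",
    "yuen",
]

DEFAULT_TRIM = 0.20


# ---------------------------------------------------------------------------
# trimmed-mean primitives

def _check_trim(values: np.ndarray, trim: float) -> int:
    if not 0.0 <= trim < 0.5:
        raise ValueError(f"trim must lie in [0, 0.5), got {trim}")
    n = len(values)
    g = int(math.floor(trim * n))
    if n - 2 * g < 1:
        raise ValueError(f"trimming {g} from each end of {n} values leaves nothing")
    return g


def trimmed_mean(values, trim: float = DEFAULT_TRIM) -> float:
    """Mean after removing floor(trim*n) observations from each tail."""
    x = np.sort(np.asarray(values, dtype=float))
    g = _check_trim(x, trim)
    return float(x[g : len(x) - g].mean())


def winsorized_variance(values, trim: float = DEFAULT_TRIM) -> float:
    """Sample variance (n-1) after clamping each tail to its trim boundary."""
    x = np.sort(np.asarray(values, dtype=float))
    g = _check_trim(x, trim)
    w = x.copy()
    w[:g] = x[g]
    w[len(x) - g :] = x[len(x) - g - 1]
    return float(w.var(ddof=1)) if len(w) > 1 else 0.0


def _trimmed_sq_se(values: np.ndarray, trim: float) -> tuple[float, int]:
    """Squared standard error of the trimmed mean and the post-trim count h.

    d = (n-1) s_w^2 / (h (h-1)) with s_w^2 the winsorized variance.
    """
    n = len(values)
    g = int(math.floor(trim * n))
    h = n - 2 * g
    if h < 2:
        raise ValueError(f"cell with n={n} leaves h={h} < 2 after trimming")
    d = (n - 1) * winsorized_variance(values, trim) / (h * (h - 1))
    return d, h


def yuen(a, b, trim: float = DEFAULT_TRIM) -> tuple[float, float, float, float]:
    """Yuen's two-sample trimmed-means test.

    Returns ``(t_stat, df, p, diff)`` where diff is the difference of
    trimmed means (a minus b) and df the Welch-Satterthwaite degrees of
    freedom on winsorized variances.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    da, ha = _trimmed_sq_se(a, trim)
    db, hb = _trimmed_sq_se(b, trim)
    diff = trimmed_mean(a, trim) - trimmed_mean(b, trim)
    denom = da + db
    if denom == 0:
        t = 0.0 if diff == 0 else math.inf
        df = ha + hb - 2.0
        p = 1.0 if diff == 0 else 0.0
        return t, df, p, diff
    t = diff / math.sqrt(denom)
    df = denom**2 / (da**2 / (ha - 1) + db**2 / (hb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p), float(diff)


# ---------------------------------------------------------------------------
# Johansen-type factorial test on trimmed means (t2way)

@dataclass(frozen=True)
class RobustTestResult:
    """Factorial trimmed-means test output for a 2 x 3 (sex x weight) grid."""

    q_sex: float
    q_weight: float
    q_interaction: float
    p_sex: float
    p_weight: float
    p_interaction: float
    trim: float


def _johansen(cmat: np.ndarray, tmeans: np.ndarray, v: np.ndarray,
              h: np.ndarray) -> tuple[float, float]:
    """Johansen's heteroscedastic test of C mu = 0 on trimmed means.

    ``v`` is the diagonal matrix of squared trimmed-mean SEs and ``h``
    the post-trim cell counts. Returns (statistic, p). The chi-square
    reference is corrected for small samples: the critical value at
    level a is c + c/(2f) * A * (1 + 3c/(f+2)) with f = rank(C) and
    A = sum_j R_jj^2/(h_j - 1), R = V C'(C V C')^{-1} C; the p-value is
    the level at which the statistic equals its critical value.
    """
    cv = cmat @ v @ cmat.T
    effect = cmat @ tmeans
    if not np.any(np.diag(v) > 0):
        # degenerate cells with zero winsorized spread
        if np.allclose(effect, 0.0):
            return 0.0, 1.0
        return math.inf, 0.0
    invc = np.linalg.inv(cv)
    q = float(effect @ invc @ effect)
    r = v @ cmat.T @ invc @ cmat
    a_corr = float(np.sum(np.diag(r) ** 2 / (h - 1)))
    f = cmat.shape[0]

    def crit(alpha: float) -> float:
        c = stats.chi2.isf(alpha, f)
        return c + (c / (2 * f)) * a_corr * (1 + 3 * c / (f + 2))

    if q <= 0:
        return max(q, 0.0), 1.0
    lo, hi = 1e-12, 1 - 1e-9
    if q <= crit(hi):
        return q, 1.0
    if q >= crit(lo):
        return q, float(lo)
    p = optimize.brentq(lambda a: q - crit(a), lo, hi, xtol=1e-12)
    return q, float(p)


def _as_grid(cells) -> tuple[list[list[np.ndarray]], list, list]:
    """Normalise cell samples to a J x K nested list plus level labels."""
    if isinstance(cells, Mapping):
        rows = sorted({k[0] for k in cells}, key=str)
        cols = sorted({k[1] for k in cells}, key=str)
        grid = []
        for r in rows:
            grid.append([np.asarray(cells.get((r, c), []), dtype=float) for c in cols])
        return grid, rows, cols
    grid = [[np.asarray(c, dtype=float) for c in row] for row in cells]
    return grid, list(range(len(grid))), list(range(len(grid[0])))


def robust_two_way(cells, trim: float = DEFAULT_TRIM) -> RobustTestResult:
    """Two-way heteroscedastic factorial test on trimmed means.

    ``cells`` is either a ``{(row_level, col_level): sample}`` mapping or
    a J x K nested sequence (rows = sex, columns = weight class). Returns
    main-effect and interaction statistics with Johansen-corrected
    p-values. Results are invariant to relabelling factor levels.
    """
    grid, rows, cols = _as_grid(cells)
    J, K = len(grid), len(grid[0])
    if any(len(row) != K for row in grid):
        raise ValueError("ragged cell grid")
    for r, row in zip(rows, grid):
        for c, cell in zip(cols, row):
            if len(cell) == 0:
                raise ValueError(f"empty cell ({r}, {c})")

    flat = [cell for row in grid for cell in row]
    tmeans = np.array([trimmed_mean(c, trim) for c in flat])
    dh = [_trimmed_sq_se(c, trim) for c in flat]
    v = np.diag([d for d, _ in dh])
    h = np.array([hh for _, hh in dh], dtype=float)

    cj = np.zeros((J - 1, J))
    for i in range(J - 1):
        cj[i, i], cj[i, i + 1] = 1.0, -1.0
    ck = np.zeros((K - 1, K))
    for i in range(K - 1):
        ck[i, i], ck[i, i + 1] = 1.0, -1.0
    ones_j = np.ones((1, J))
    ones_k = np.ones((1, K))

    q_a, p_a = _johansen(np.kron(cj, ones_k), tmeans, v, h)
    q_b, p_b = _johansen(np.kron(ones_j, ck), tmeans, v, h)
    q_ab, p_ab = _johansen(np.kron(cj, ck), tmeans, v, h)
    return RobustTestResult(
        q_sex=q_a, q_weight=q_b, q_interaction=q_ab,
        p_sex=p_a, p_weight=p_b, p_interaction=p_ab, trim=trim,
    )


# ---------------------------------------------------------------------------
# pairwise contrasts (lincon) with FWE control

@dataclass(frozen=True)
class PosthocContrast:
    """One pairwise trimmed-means comparison between two cells."""

    cell_a: str
    cell_b: str
    diff: float        # trimmed-mean difference, a minus b
    t_stat: float
    df: float
    p: float           # family-wise adjusted
    significant: bool
    r: float           # Rosenthal's r from the exact WMW Z
    magnitude: str     # below-small / small / moderate / great


def _smm_adjust(t_abs: float, df: float, n_comparisons: int) -> float:
    """Family-wise p for |T| under the studentized-maximum-modulus
    (independence) approximation: 1 - (2 F_t(|T|) - 1)^C."""
    core = 2.0 * stats.t.cdf(t_abs, df) - 1.0
    return float(np.clip(1.0 - max(core, 0.0) ** n_comparisons, 0.0, 1.0))


def pairwise_trimmed_contrasts(
    cells: Mapping[str, Sequence[float]] | Mapping[tuple, Sequence[float]],
    trim: float = DEFAULT_TRIM,
    alpha: float = 0.05,
    method: str = "smm",
) -> list[PosthocContrast]:
    """All pairwise Yuen trimmed-mean comparisons with FWE control.

    ``cells`` maps labels to samples (for the contest analysis, the six
    sex x weight cells giving 15 comparisons). ``method`` is ``"smm"``
    (studentized-maximum-modulus critical values, the lincon convention)
    or ``"hochberg"`` (step-up adjustment of the raw Yuen p-values).
    Rosenthal's r accompanies every contrast.
    """
    if method not in ("smm", "hochberg"):
        raise ValueError(f"unknown method {method!r}")
    labels = list(cells)
    for lab in labels:
        if len(np.asarray(cells[lab])) == 0:
            raise ValueError(f"empty cell {lab}")
    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]
    n_comp = len(pairs)

    raw = []
    for a, b in pairs:
        t, df, p_raw, diff = yuen(cells[a], cells[b], trim)
        z = wmw_exact_z(cells[a], cells[b])
        n_tot = len(np.asarray(cells[a])) + len(np.asarray(cells[b]))
        r, mag = rosenthal_r(z, n_tot)
        raw.append((a, b, t, df, p_raw, diff, r, mag))

    if method == "smm":
        adj = [_smm_adjust(abs(t), df, n_comp) for _, _, t, df, _, _, _, _ in raw]
    else:  # Hochberg step-up
        ps = np.array([p for _, _, _, _, p, _, _, _ in raw])
        order = np.argsort(ps)[::-1]  # largest first
        adj_arr = np.empty_like(ps)
        running = 1.0
        for rank, idx in enumerate(order):
            factor = rank + 1  # m, m-1, ... as p descends -> multiplier 1, 2, ...
            running = min(running, ps[idx] * factor)
            adj_arr[idx] = running
        adj = np.clip(adj_arr, 0.0, 1.0).tolist()

    out = []
    for (a, b, t, df, _, diff, r, mag), p_adj in zip(raw, adj):
        out.append(
            PosthocContrast(
                cell_a=str(a), cell_b=str(b), diff=diff, t_stat=t, df=df,
                p=p_adj, significant=p_adj < alpha, r=r, magnitude=mag,
            )
        )
    return out


# ---------------------------------------------------------------------------
# exact Wilcoxon-Mann-Whitney and Rosenthal's r

#: beyond this combined sample size the normal approximation is used
EXACT_WMW_MAX_N = 40


@lru_cache(maxsize=256)
def exact_u_counts(n1: int, n2: int) -> np.ndarray:
    """Number of rank arrangements giving each Mann-Whitney U value.

    Entry u of the returned array counts the subsets of size ``n1`` of
    the combined ranks with U statistic u; entries sum to C(n1+n2, n1).
    Built by the standard dynamic-programming recurrence
    N(u; i, j) = N(u-j; i-1, j) + N(u; i, j-1). The returned array is
    cached and read-only.
    """
    max_u = n1 * n2
    # dp[j] holds the count vector for (i items from a, j items from b)
    prev = [np.zeros(max_u + 1) for _ in range(n2 + 1)]
    for j in range(n2 + 1):
        prev[j][0] = 1.0  # i = 0: only U = 0
    for i in range(1, n1 + 1):
        cur = [np.zeros(max_u + 1) for _ in range(n2 + 1)]
        cur[0][0] = 1.0
        for j in range(1, n2 + 1):
            cur[j][j:] = prev[j][: max_u + 1 - j]
            cur[j] += cur[j - 1]
        prev = cur
    out = prev[n2]
    out.flags.writeable = False
    return out


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a: pairs with a > b, counting ties as half."""
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def wmw_exact_z(a, b) -> float:
    """Standard-normal deviate of the Wilcoxon-Mann-Whitney test.

    The two-sided p comes from the exact U distribution (full DP
    enumeration) when the combined sample is tie-free and no larger than
    40; otherwise from the tie-corrected, continuity-corrected normal
    approximation. Z is the standard-normal quantile of that p, signed
    positive when sample ``a`` stochastically dominates ``b``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 + n2 < 2 or n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(a, b)
    mu = n1 * n2 / 2.0
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < n1 + n2

    if np.all(combined == combined[0]):
        return 0.0

    if not has_ties and n1 + n2 <= EXACT_WMW_MAX_N:
        counts = exact_u_counts(n1, n2)
        total = counts.sum()
        ui = int(round(u))
        p_le = counts[: ui + 1].sum() / total
        p_ge = counts[ui:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        n = n1 + n2
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            return 0.0
        cc = 0.5 if u != mu else 0.0
        z_abs = (abs(u - mu) - cc) / math.sqrt(var)
        z_abs = max(z_abs, 0.0)
        p = min(1.0, 2.0 * stats.norm.sf(z_abs))

    z = stats.norm.isf(p / 2.0) if p < 1.0 else 0.0
    return float(math.copysign(z, u - mu)) if u != mu else 0.0


def rosenthal_r(z: float, n_total: int) -> tuple[float, str]:
    """Effect size r = |Z|/sqrt(N) with its conventional magnitude label.

    Labels: great for r > 0.80, moderate for r > 0.50, small for
    r > 0.20, below-small otherwise.
    """
    if n_total < 2:
        raise ValueError("N must be at least 2")
    r = abs(z) / math.sqrt(n_total)
    if r > 0.80:
        mag = "great"
    elif r > 0.50:
        mag = "moderate"
    elif r > 0.20:
        mag = "small"
    else:
        mag = "below-small"
    return float(r), mag


# ---------------------------------------------------------------------------
# axis-uniformity chi-square

def chisq_axis_uniformity(axis_pct) -> tuple[float, float]:
    """One-sample Pearson chi-square of the three axis shares against
    equal thirds.

    The percentage shares are treated as observations on their own total
    (100 when they sum to 100), with expected total/3 per axis and df=2.
    """
    obs = np.asarray(axis_pct, dtype=float)
    if obs.shape != (3,):
        raise ValueError("axis_pct must have exactly three entries")
    if (obs < 0).any():
        raise ValueError("axis shares must be non-negative")
    total = obs.sum()
    if total <= 0:
        raise ValueError("axis shares sum to zero")
    expected = total / 3.0
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=2))
    return chi2, p


# ---------------------------------------------------------------------------
# ANOVA power / sample size

@dataclass(frozen=True)
class PowerQuery:
    """One-way fixed-effects ANOVA sizing question."""

    k_groups: int
    effect_f: float
    alpha: float = 0.05
    power: float = 0.85

    def validate(self) -> None:
        if self.k_groups < 2:
            raise ValueError("k_groups must be at least 2")
        if self.effect_f <= 0:
            raise ValueError("effect_f must be positive (power is unreachable at f=0)")
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must lie in (0, 1)")


def anova_power(n_per_group: int, k_groups: int, effect_f: float,
                alpha: float = 0.05) -> float:
    """Power of the one-way fixed-effects ANOVA F-test.

    Noncentrality lambda = k * n * f^2 on df (k-1, k(n-1)).
    """
    if n_per_group < 2:
        return 0.0
    df1 = k_groups - 1
    df2 = k_groups * (n_per_group - 1)
    lam = k_groups * n_per_group * effect_f**2
    crit = stats.f.isf(alpha, df1, df2)
    return float(stats.ncf.sf(crit, df1, df2, lam))


def required_group_n(query: PowerQuery, n_max: int = 100_000) -> int:
    """Smallest per-group n reaching the requested ANOVA power."""
    query.validate()
    for n in range(2, n_max + 1):
        if anova_power(n, query.k_groups, query.effect_f, query.alpha) >= query.power:
            return n
    raise ValueError(f"power {query.power} not reached by n = {n_max}")


# ---------------------------------------------------------------------------
# distributional gating

@dataclass(frozen=True)
class GatesReport:
    """Normality and homoscedasticity gate results.

    ``normality`` maps cell label to (W, p) or None when untestable
    (n < 3 or zero spread); Bartlett fields are None when fewer than two
    cells are testable.
    """

    normality: dict
    bartlett_stat: float | None
    bartlett_p: float | None

    def any_violation(self, alpha: float = 0.05) -> bool:
        norm_fail = any(v is not None and v[1] < alpha for v in self.normality.values())
        bart_fail = self.bartlett_p is not None and self.bartlett_p < alpha
        return norm_fail or bart_fail


def distribution_gates(samples: Mapping[str, Sequence[float]]) -> GatesReport:
    """Shapiro-Wilk per cell plus Bartlett's test across cells.

    These are reporting gates: in the contest analysis they motivate the
    robust battery rather than alter it.
    """
    normality: dict = {}
    testable = []
    for label, vals in samples.items():
        x = np.asarray(vals, dtype=float)
        if len(x) < 3 or np.ptp(x) == 0:
            normality[str(label)] = None
            continue
        w, p = stats.shapiro(x)
        normality[str(label)] = (float(w), float(p))
        if len(x) >= 2:
            testable.append(x)
    if len(testable) >= 2:
        b_stat, b_p = stats.bartlett(*testable)
        return GatesReport(normality, float(b_stat), float(b_p))
    return GatesReport(normality, None, None)
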