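"""Migration kinetics and statistical comparisons.

Per-frame absolute areas become migration kinetics by normalising each well
to its own first frame: percent cell-free area = 100 * A(t) / A(t0).  Values
above 100 are legal and meaningful — they are the retraction regime, where an
inhibitor causes the zone to grow.  The baseline is deliberately each well's
own first frame rather than the theoretical zone area, since only
self-normalisation can represent that regime.

Statistical operations mirror a standard assay analysis: paired t-test,
one-way ANOVA across replicate groups, and a balanced two-factor
(treatment x time) ANOVA with interaction followed by per-timepoint pairwise
treatment comparisons using the pooled residual mean square and a
Sidak (default) or Bonferroni family correction at alpha = 0.05.

The two-factor decomposition is computed from the classical balanced
closed-form sums of squares; zero-variance layouts are guarded explicitly
(MS_effect = 0 -> F = 0, p = 1; MS_error = 0 with a non-zero effect ->
F = inf, p = 0), which generic regression-based routes report as NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "percent_area",
    "percent_table",
    "aggregate",
    "paired_t_test",
    "one_way_anova",
    "two_way_anova",
    "TwoWayAnovaResult",
    "plot_kinetics",
]


def percent_area(df: pd.DataFrame) -> pd.DataFrame:
    """Normalise one well's area series to its first frame.

    Expects columns ``time_h`` and ``area_mm2`` (plus any id columns, which
    are preserved); returns a copy sorted by time with a ``percent_area``
    column.  The first frame must have non-zero area.
    """
    if df.empty:
        raise ValueError("empty area series")
    out = df.sort_values("time_h").reset_index(drop=True).copy()
    baseline = float(out.loc[0, "area_mm2"])
    if baseline <= 0:
        well = out["well_id"].iloc[0] if "well_id" in out else "<unknown>"
        raise ValueError(f"zero baseline area for well {well!r}; cannot normalise")
    out["percent_area"] = 100.0 * out["area_mm2"] / baseline
    return out


def percent_table(df: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`percent_area` per well of a long-format area table.

    Expects columns ``well_id``, ``time_h``, ``area_mm2`` and optionally
    ``treatment``.
    """
    for col in ("well_id", "time_h", "area_mm2"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    parts = [percent_area(g) for _, g in df.groupby("well_id", sort=True)]
    return pd.concat(parts, ignore_index=True)


def aggregate(records: pd.DataFrame) -> pd.DataFrame:
    """Per-(treatment, time) mean, sample SD and SEM of percent area.

    SD uses the n-1 denominator.  Cells with a single replicate get SD and
    SEM 0 with a warning.
    """
    for col in ("treatment", "time_h", "percent_area"):
        if col not in records.columns:
            raise ValueError(f"missing required column {col!r}")
    rows = []
    single = False
    for (treatment, time_h), g in records.groupby(["treatment", "time_h"], sort=True):
        vals = g["percent_area"].to_numpy(dtype=float)
        n = vals.size
        if n == 1:
            single = True
            sd = 0.0
        else:
            sd = float(vals.std(ddof=1))
        rows.append(
            {
                "treatment": treatment,
                "time_h": float(time_h),
                "mean_percent": float(vals.mean()),
                "sd": sd,
                "sem": sd / np.sqrt(n),
                "n": n,
            }
        )
    if single:
        warnings.warn("single-replicate cell(s): SD reported as 0", stacklevel=2)
    return pd.DataFrame(rows)


def paired_t_test(x, y) -> tuple[float, int, float]:
    """Two-sided paired t-test; returns (t, df, p).

    t = mean(d) / (sd(d)/sqrt(n)) on differences d = x - y, df = n - 1.
    A zero-variance, zero-mean difference vector gives t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0:
        if mean == 0:
            return 0.0, n - 1, 1.0
        return float(np.inf) * np.sign(mean), n - 1, 0.0
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p)


def one_way_anova(groups) -> tuple[float, int, int, float]:
    """One-way fixed-effects ANOVA; returns (F, df_between, df_within, p).

    Degenerate layouts are guarded: identical constant groups give F = 0,
    p = 1; zero within-group variance with distinct means gives F = inf,
    p = 0.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.ndim != 1 or a.size < 2 for a in arrs):
        raise ValueError("each group needs at least 2 values")
    k = len(arrs)
    n_total = sum(a.size for a in arrs)
    grand = np.concatenate(arrs).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df_b = k - 1
    df_w = n_total - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_b == 0:
        return 0.0, df_b, df_w, 1.0
    if ms_w == 0:
        return float(np.inf), df_b, df_w, 0.0
    f = ms_b / ms_w
    p = stats.f.sf(f, df_b, df_w)
    return float(f), df_b, df_w, float(p)


@dataclass(frozen=True)
class TwoWayAnovaResult:
    """Balanced two-factor ANOVA table plus per-timepoint comparisons."""

    table: pd.DataFrame  # rows treatment/time/interaction/residual
    comparisons: pd.DataFrame
    alpha: float

    def _row(self, name: str) -> pd.Series:
        return self.table.loc[name]

    @property
    def f_treatment(self) -> float:
        return float(self._row("treatment")["F"])

    @property
    def f_time(self) -> float:
        return float(self._row("time")["F"])

    @property
    def f_interaction(self) -> float:
        return float(self._row("interaction")["F"])

    @property
    def p_treatment(self) -> float:
        return float(self._row("treatment")["p"])

    @property
    def p_time(self) -> float:
        return float(self._row("time")["p"])

    @property
    def p_interaction(self) -> float:
        return float(self._row("interaction")["p"])

    def summary(self) -> str:
        lines = ["Two-way ANOVA (treatment x time)", str(self.table.round(6)), ""]
        lines.append(f"Pairwise treatment comparisons per timepoint (alpha={self.alpha}):")
        lines.append(str(self.comparisons.round(6)))
        return "\n".join(lines)


def _guarded_f(ms_effect: float, ms_error: float, df_effect: int, df_error: int):
    if ms_effect == 0:
        return 0.0, 1.0
    if ms_error == 0:
        return float(np.inf), 0.0
    f = ms_effect / ms_error
    return float(f), float(stats.f.sf(f, df_effect, df_error))


def two_way_anova(
    records: pd.DataFrame,
    alpha: float = 0.05,
    correction: str = "sidak",
) -> TwoWayAnovaResult:
    """Balanced two-factor ANOVA with interaction and post-hoc comparisons.

    Expects long-format columns ``treatment``, ``time_h``, ``percent_area``
    with an equal number of replicates in every (treatment, time) cell and at
    least 2 levels per factor and 2 replicates per cell.  Unbalanced layouts
    raise (balanced-only implementation).

    Post-hoc: for every timepoint, every treatment pair is compared with a
    t statistic using the pooled residual mean square of the two-way fit
    (df = a*b*(r-1)); p-values are corrected over the whole family of
    pairs x timepoints by the Sidak (default) or Bonferroni rule.
    """
    if correction not in ("sidak", "bonferroni"):
        raise ValueError("correction must be 'sidak' or 'bonferroni'")
    for col in ("treatment", "time_h", "percent_area"):
        if col not in records.columns:
            raise ValueError(f"missing required column {col!r}")
    treatments = sorted(records["treatment"].unique())
    times = sorted(records["time_h"].unique())
    a, b = len(treatments), len(times)
    if a < 2 or b < 2:
        raise ValueError("need at least 2 levels of each factor")
    counts = records.groupby(["treatment", "time_h"]).size()
    if counts.size != a * b or counts.nunique() != 1:
        raise ValueError("unbalanced design: every cell needs the same replicate count")
    r = int(counts.iloc[0])
    if r < 2:
        raise ValueError("need at least 2 replicates per cell")

    # y[i, j, k]: treatment i, time j, replicate k
    y = np.empty((a, b, r))
    grouped = records.groupby(["treatment", "time_h"], sort=True)
    for (ti, tj), g in grouped:
        i = treatments.index(ti)
        j = times.index(tj)
        y[i, j, :] = g["percent_area"].to_numpy(dtype=float)

    grand = y.mean()
    mean_a = y.mean(axis=(1, 2))
    mean_b = y.mean(axis=(0, 2))
    mean_cell = y.mean(axis=2)
    ss_a = r * b * ((mean_a - grand) ** 2).sum()
    ss_b = r * a * ((mean_b - grand) ** 2).sum()
    ss_ab = r * ((mean_cell - mean_a[:, None] - mean_b[None, :] + grand) ** 2).sum()
    ss_e = ((y - mean_cell[:, :, None]) ** 2).sum()
    # snap floating-point residue to exact zero so the degenerate guards fire
    tol = 1e-12 * max(ss_a + ss_b + ss_ab + ss_e, np.abs(y).max() ** 2, 1.0)
    ss_a, ss_b, ss_ab, ss_e = (
        0.0 if ss < tol else float(ss) for ss in (ss_a, ss_b, ss_ab, ss_e)
    )
    df_a, df_b_, df_ab, df_e = a - 1, b - 1, (a - 1) * (b - 1), a * b * (r - 1)
    ms = [ss_a / df_a, ss_b / df_b_, ss_ab / df_ab, ss_e / df_e]
    f_a, p_a = _guarded_f(ms[0], ms[3], df_a, df_e)
    f_b, p_b = _guarded_f(ms[1], ms[3], df_b_, df_e)
    f_ab, p_ab = _guarded_f(ms[2], ms[3], df_ab, df_e)
    table = pd.DataFrame(
        {
            "SS": [ss_a, ss_b, ss_ab, ss_e],
            "df": [df_a, df_b_, df_ab, df_e],
            "MS": ms,
            "F": [f_a, f_b, f_ab, np.nan],
            "p": [p_a, p_b, p_ab, np.nan],
        },
        index=["treatment", "time", "interaction", "residual"],
    )

    # per-timepoint pairwise treatment comparisons, pooled error term
    mse = ss_e / df_e
    n_pairs = a * (a - 1) // 2
    m = n_pairs * b  # family size: all pairs at all timepoints
    rows = []
    for j, t in enumerate(times):
        for i1 in range(a):
            for i2 in range(i1 + 1, a):
                diff = mean_cell[i1, j] - mean_cell[i2, j]
                if mse == 0:
                    tstat = 0.0 if diff == 0 else float(np.inf) * np.sign(diff)
                    p_raw = 1.0 if diff == 0 else 0.0
                else:
                    se = np.sqrt(mse * 2.0 / r)
                    tstat = diff / se
                    p_raw = 2.0 * stats.t.sf(abs(tstat), df_e)
                if correction == "sidak":
                    p_adj = 1.0 - (1.0 - min(p_raw, 1.0)) ** m
                else:
                    p_adj = min(1.0, p_raw * m)
                rows.append(
                    {
                        "time_h": float(t),
                        "group1": treatments[i1],
                        "group2": treatments[i2],
                        "mean_diff": float(diff),
                        "t": float(tstat),
                        "df": df_e,
                        "p_raw": float(p_raw),
                        "p_adj": float(p_adj),
                        "significant": bool(p_adj < alpha),
                    }
                )
    comparisons = pd.DataFrame(rows)
    return TwoWayAnovaResult(table, comparisons, alpha)


def plot_kinetics(aggregates: pd.DataFrame, path=None, ax=None):
    """Line plot of mean percent cell-free area +/- SEM per treatment.

    Accepts the output of :func:`aggregate`.  Returns the matplotlib Axes;
    saves to ``path`` when given.
    """
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    for treatment, g in aggregates.groupby("treatment", sort=True):
        g = g.sort_values("time_h")
        ax.errorbar(
            g["time_h"],
            g["mean_percent"],
            yerr=g["sem"],
            marker="o",
            markersize=3,
            capsize=2,
            label=str(treatment),
        )
    ax.set_xlabel("time (h)")
    ax.set_ylabel("% cell-free area")
    ax.axhline(100.0, color="0.8", lw=0.8, zorder=0)
    ax.legend(frameon=False, fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
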