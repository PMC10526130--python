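"""Longitudinal two-arm cohort statistics.

The cohort table holds one row per (subject, arm, timepoint, metric).  The
primary endpoint is the percentage change of each per-tumor median metric
relative to the subject's pre-treatment value; arms are compared per
metric and timepoint with a two-sided Mann-Whitney U test at the 0.05
level.  Missing (subject, timepoint) rows are handled by pairwise
deletion: a subject drops out of the comparisons that need the missing
row and no others.  No multiple-testing correction is applied — many
metric x timepoint combinations are each tested at 0.05, so isolated
significant results must be read accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ArmComparison",
    "DensityEstimate",
    "relative_change",
    "compare_arms",
    "voxel_density",
    "median_ci",
    "pipeline_report",
]

ALPHA = 0.05
EXACT_MAX_N = 20  # combined sample size up to which the exact test is used


@dataclass
class ArmComparison:
    """Two-sided Mann-Whitney U comparison of one metric at one timepoint."""
    metric: str
    timepoint: str
    u_statistic: float
    p_value: float
    n_per_arm: tuple[int, int]
    significant: bool
    method: str  # exact | asymptotic


@dataclass
class DensityEstimate:
    grid: np.ndarray
    density: np.ndarray
    hist_edges: np.ndarray
    hist_density: np.ndarray
    n: int


def relative_change(table: pd.DataFrame,
                    baseline_label: str = "baseline") -> pd.DataFrame:
    """Percentage change of each metric relative to the subject's baseline.

    Returns rows (subject, arm, timepoint, metric, pct_change, defined) for
    every non-baseline row whose subject has a baseline row for that
    metric; subjects missing either row are dropped for that comparison
    only.  A zero baseline yields defined=False with NaN change.
    """
    required = {"subject", "arm", "timepoint", "metric", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"cohort table must have columns {sorted(required)}")
    base = table[table.timepoint == baseline_label].set_index(
        ["subject", "metric"])["value"]
    rows = []
    follow = table[table.timepoint != baseline_label]
    for rec in follow.itertuples(index=False):
        key = (rec.subject, rec.metric)
        if key not in base.index:
            continue  # pairwise deletion: no baseline for this subject/metric
        v0 = float(base.loc[key])
        if v0 == 0:
            rows.append({"subject": rec.subject, "arm": rec.arm,
                         "timepoint": rec.timepoint, "metric": rec.metric,
                         "pct_change": np.nan, "defined": False})
            continue
        rows.append({"subject": rec.subject, "arm": rec.arm,
                     "timepoint": rec.timepoint, "metric": rec.metric,
                     "pct_change": 100.0 * (float(rec.value) - v0) / v0,
                     "defined": True})
    return pd.DataFrame(
        rows, columns=["subject", "arm", "timepoint", "metric",
                       "pct_change", "defined"])


def compare_arms(
    changes: pd.DataFrame,
    metric: str,
    timepoint: str,
    value_column: str = "pct_change",
    alpha: float = ALPHA,
) -> ArmComparison:
    """Two-sided Mann-Whitney U test between the two arms.

    Exact null distribution for combined n <= 20 without ties; normal
    approximation with tie correction otherwise.
    """
    sel = changes[(changes.metric == metric)
                  & (changes.timepoint == timepoint)]
    if "defined" in sel.columns:
        sel = sel[sel.defined]
    arms = sorted(sel.arm.unique())
    if len(arms) != 2:
        raise ValueError(
            f"need exactly two arms with data for {metric}/{timepoint}, "
            f"found {arms}")
    x = sel[sel.arm == arms[0]][value_column].to_numpy(dtype=float)
    y = sel[sel.arm == arms[1]][value_column].to_numpy(dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError(f"an arm is empty for {metric}/{timepoint}")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size + y.size <= EXACT_MAX_N and not has_ties) \
        else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return ArmComparison(metric=metric, timepoint=timepoint,
                         u_statistic=float(res.statistic),
                         p_value=float(res.pvalue),
                         n_per_arm=(int(x.size), int(y.size)),
                         significant=bool(res.pvalue < alpha),
                         method=method)


def voxel_density(values: np.ndarray, grid: Optional[np.ndarray] = None,
                  n_bins: int = 50, bw_method="silverman") -> DensityEstimate:
    """Gaussian-kernel probability density of pooled voxel values.

    Silverman's rule sets the bandwidth by default (pass a scalar
    ``bw_method`` for a fixed bandwidth factor); the estimate integrates
    to 1 over its support.  The matching sample-size-normalized histogram
    is emitted alongside.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size < 10:
        raise ValueError(f"need at least 10 values, got {v.size}")
    kde = sps.gaussian_kde(v, bw_method=bw_method)
    if grid is None:
        lo, hi = v.min(), v.max()
        pad = 3 * kde.factor * v.std()
        grid = np.linspace(lo - pad, hi + pad, 512)
    density = kde(grid)
    hist_density, hist_edges = np.histogram(v, bins=n_bins, density=True)
    return DensityEstimate(grid=grid, density=density, hist_edges=hist_edges,
                           hist_density=hist_density, n=int(v.size))


def median_ci(values: np.ndarray, n_boot: int = 2000, seed: int = 0,
              level: float = 0.95) -> tuple[float, float, float]:
    """Median with a percentile-bootstrap confidence interval."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return (np.nan, np.nan, np.nan)
    rng = np.random.default_rng(seed)
    boots = np.median(
        rng.choice(v, size=(n_boot, v.size), replace=True), axis=1)
    lo, hi = np.quantile(boots, [(1 - level) / 2, (1 + level) / 2])
    return (float(np.median(v)), float(lo), float(hi))


def _check_arms(table: pd.DataFrame):
    for arm, sub in table.groupby("arm"):
        if sub.empty:
            raise ValueError(f"arm {arm!r} has no rows")
    if table.arm.nunique() < 2:
        raise ValueError(
            f"report needs two arms, found {sorted(table.arm.unique())}")


def pipeline_report(
    table: pd.DataFrame,
    metrics: Optional[Sequence[str]] = None,
    baseline_label: str = "baseline",
    seed: int = 0,
    out_dir=None,
) -> dict:
    """Cohort summary tables and figures.

    Produces, per arm: median + IQR absolute values and median relative
    changes for tumor volume; median + bootstrap 95% CI for each PK/texture
    metric with delta rows; the arm-comparison p-values per metric and
    timepoint; and (when ``out_dir`` is given) strip plots of relative
    changes and per-arm density plots saved as PNG.
    """
    _check_arms(table)
    if metrics is None:
        metrics = sorted(table.metric.unique())
    changes = relative_change(table, baseline_label=baseline_label)
    timepoints = [t for t in table.timepoint.unique() if t != baseline_label]

    summary_rows, test_rows = [], []
    for metric in metrics:
        for arm in sorted(table.arm.unique()):
            for tp in table.timepoint.unique():
                vals = table[(table.metric == metric) & (table.arm == arm)
                             & (table.timepoint == tp)].value.to_numpy()
                if vals.size == 0:
                    continue
                med, lo, hi = median_ci(vals, seed=seed)
                q1, q3 = np.quantile(vals, [0.25, 0.75])
                row = {"metric": metric, "arm": arm, "timepoint": tp,
                       "n": vals.size, "median": med, "ci_lo": lo,
                       "ci_hi": hi, "iqr_lo": float(q1), "iqr_hi": float(q3)}
                ch = changes[(changes.metric == metric) & (changes.arm == arm)
                             & (changes.timepoint == tp) & changes.defined]
                if not ch.empty:
                    dmed, dlo, dhi = median_ci(ch["pct_change"].to_numpy(),
                                               seed=seed)
                    row.update({"delta_median_pct": dmed,
                                "delta_ci_lo": dlo, "delta_ci_hi": dhi})
                summary_rows.append(row)
        for tp in timepoints:
            try:
                cmp_res = compare_arms(changes, metric, tp)
            except ValueError:
                continue
            test_rows.append(vars(cmp_res))

    report = {"summary": pd.DataFrame(summary_rows),
              "tests": pd.DataFrame(test_rows),
              "changes": changes}

    if out_dir is not None:
        report["figures"] = _save_figures(table, changes, metrics,
                                          baseline_label, out_dir)
    return report


def _save_figures(table, changes, metrics, baseline_label, out_dir):
    import pathlib

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    arms = sorted(table.arm.unique())
    for metric in metrics:
        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        # strip/box of relative change per timepoint per arm
        ax = axes[0]
        tps = [t for t in table.timepoint.unique() if t != baseline_label]
        for ai, arm in enumerate(arms):
            for ti, tp in enumerate(tps):
                vals = changes[(changes.metric == metric)
                               & (changes.arm == arm)
                               & (changes.timepoint == tp)
                               & changes.defined]["pct_change"]
                if vals.empty:
                    continue
                x = ti + (ai - 0.5) * 0.3
                ax.boxplot([vals], positions=[x], widths=0.22,
                           tick_labels=[""])
                ax.plot(np.full(len(vals), x), vals, ".", alpha=0.6,
                        label=arm if ti == 0 else None)
        ax.set_xticks(range(len(tps)), tps)
        ax.axhline(0, color="gray", lw=0.5)
        ax.set_ylabel(f"Δ {metric} [%]")
        ax.legend(fontsize=8)
        # density of absolute values per arm
        ax = axes[1]
        for arm in arms:
            vals = table[(table.metric == metric)
                         & (table.arm == arm)].value.to_numpy()
            if vals.size >= 10:
                d = voxel_density(vals)
                ax.plot(d.grid, d.density, label=arm)
        ax.set_xlabel(metric)
        ax.set_ylabel("probability density")
        ax.legend(fontsize=8)
        fig.suptitle(metric)
        fig.tight_layout()
        path = out_dir / f"report_{metric}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        paths.append(path)
    return paths
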