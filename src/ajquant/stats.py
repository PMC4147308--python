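"""Group statistics and report tables.

Per-cell metrics are grouped by experimental condition and compared
with a two-tailed Student's t-test (classic equal-variance by default;
Welch available), reported as mean ± SEM with the significance
convention * for P < 0.05 and ** for P < 0.01.  The unit of replication
is the individual cell (typically 10-40 cells per condition); no
multiple-testing correction is applied by default, with an optional
Benjamini-Hochberg toggle.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparison", "compare_groups", "stars_for", "batch_report"]

STAR_CUTOFFS = (0.05, 0.01)
CELLS_PER_CONDITION = (10, 40)  # customary per-cell replication regime


def stars_for(p: float) -> str:
    """Significance label: ** for P<0.01, * for P<0.05, else ns."""
    if np.isnan(p):
        return "na"
    if p < STAR_CUTOFFS[1]:
        return "**"
    if p < STAR_CUTOFFS[0]:
        return "*"
    return "ns"


@dataclass
class GroupComparison:
    metric: str
    condition_a: str
    condition_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t_statistic: float
    p_value: float
    stars: str
    dropped_a: int = 0
    dropped_b: int = 0


def _sem(x: np.ndarray) -> float:
    return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan


def compare_groups(
    values_a,
    values_b,
    equal_variance: bool = True,
    metric: str = "",
    labels: tuple[str, str] = ("A", "B"),
) -> GroupComparison:
    """Two-tailed t-test between two per-cell metric groups.

    Each group needs >= 2 finite values.  When both groups have zero
    variance and equal means the p-value is undefined by convention
    (t = 0, p = NaN, stars = "na") rather than fabricated.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"need >= 2 finite values per group, got {len(a)} and {len(b)}")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            t, p = 0.0, np.nan
        else:
            t, p = np.inf * np.sign(a.mean() - b.mean()), 0.0
    else:
        t, p = sps.ttest_ind(a, b, equal_var=equal_variance)
        t, p = float(t), float(p)
    return GroupComparison(
        metric=metric, condition_a=labels[0], condition_b=labels[1],
        n_a=len(a), n_b=len(b),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sem_a=_sem(a), sem_b=_sem(b),
        t_statistic=t, p_value=p, stars=stars_for(p),
    )


def batch_report(
    table: pd.DataFrame,
    metrics: list[str] | None = None,
    condition_col: str = "condition",
    equal_variance: bool = True,
    fdr: bool = False,
) -> pd.DataFrame:
    """One GroupComparison per metric per condition pair.

    ``table`` is tidy: one row per cell, metric columns plus a condition
    label.  Missing values are dropped per metric and counted in
    ``dropped_a`` / ``dropped_b``.  A warning is issued when a group
    falls outside the customary 10-40 cells-per-condition regime.  A
    single condition yields descriptive statistics only.  With
    ``fdr=True`` Benjamini-Hochberg adjusted p-values are appended
    (off by default).
    """
    if condition_col not in table.columns:
        raise ValueError(f"table lacks a {condition_col!r} column")
    conds = sorted(table[condition_col].astype(str).unique())
    if metrics is None:
        metrics = [
            c for c in table.columns
            if c not in (condition_col, "cell_id", "channel", "flags")
            and pd.api.types.is_numeric_dtype(table[c])
        ]
    rows: list[dict] = []
    if len(conds) < 2:
        for m in metrics:
            vals = table[m].to_numpy(float)
            vals = vals[np.isfinite(vals)]
            rows.append(
                {"metric": m, "condition_a": conds[0] if conds else "",
                 "condition_b": "", "n_a": len(vals), "n_b": 0,
                 "mean_a": vals.mean() if len(vals) else np.nan, "mean_b": np.nan,
                 "sem_a": _sem(vals), "sem_b": np.nan,
                 "t_statistic": np.nan, "p_value": np.nan, "stars": "na",
                 "dropped_a": int(len(table) - len(vals)), "dropped_b": 0}
            )
        return pd.DataFrame(rows)

    for m in metrics:
        for i, ca in enumerate(conds):
            for cb in conds[i + 1:]:
                va = table.loc[table[condition_col].astype(str) == ca, m].to_numpy(float)
                vb = table.loc[table[condition_col].astype(str) == cb, m].to_numpy(float)
                fa, fb = va[np.isfinite(va)], vb[np.isfinite(vb)]
                for lab, n in ((ca, len(fa)), (cb, len(fb))):
                    if not (CELLS_PER_CONDITION[0] <= n <= CELLS_PER_CONDITION[1]):
                        warnings.warn(
                            f"{m} / {lab}: {n} cells, outside the customary "
                            f"{CELLS_PER_CONDITION[0]}-{CELLS_PER_CONDITION[1]} per-condition regime",
                            stacklevel=2,
                        )
                cmp_ = compare_groups(fa, fb, equal_variance=equal_variance,
                                      metric=m, labels=(ca, cb))
                cmp_.dropped_a = int(len(va) - len(fa))
                cmp_.dropped_b = int(len(vb) - len(fb))
                rows.append(asdict(cmp_))
    report = pd.DataFrame(rows)
    if fdr and len(report):
        p = report["p_value"].to_numpy(float)
        finite = np.isfinite(p)
        adj = np.full_like(p, np.nan)
        if finite.any():
            adj[finite] = sps.false_discovery_control(p[finite], method="bh")
        report["p_adj_bh"] = adj
    return report
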