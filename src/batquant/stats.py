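"""Cohort statistics: the study's group comparisons and report tables.

Inter-group comparisons use one-way ANOVA with Bonferroni-adjusted pairwise
t-tests; intra-group (within-subject) comparisons use a paired t-test; the
ex-vivo assays use an unpaired t-test.  Report tables print mean +/- SEM per
cell with significance markers at the p < 0.10 reporting threshold and
propagate NQ (not quantifiable) / NA cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "unpaired_t",
    "paired_t",
    "anova_bonferroni",
    "build_report",
    "MARKER_P_THRESHOLD",
]

#: Table-symbol reporting threshold (0.05 remains the significance level).
MARKER_P_THRESHOLD = 0.10


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    statistic: float
    df: float
    p: float
    degenerate: bool = False


def _as_group(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    a = a[np.isfinite(a)]
    if a.size < 2:
        raise ValueError(f"{name} needs >= 2 finite values, got {a.size}")
    return a


def unpaired_t(group_a, group_b, equal_var: bool = False) -> TestResult:
    """Two-sided unpaired t-test (Welch by default; pooled if equal_var)."""
    a = _as_group(group_a, "group_a")
    b = _as_group(group_b, "group_b")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            # no variance, no difference: conventionally p = 1
            return TestResult(0.0, float(a.size + b.size - 2), 1.0, degenerate=True)
        return TestResult(np.sign(a.mean() - b.mean()) * np.inf,
                          float(a.size + b.size - 2), 0.0, degenerate=True)
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue))


def paired_t(values_before, values_after) -> TestResult:
    """Two-sided paired t-test (one-sample t on the differences)."""
    before = np.asarray(values_before, dtype=float)
    after = np.asarray(values_after, dtype=float)
    if before.shape != after.shape or before.ndim != 1:
        raise ValueError("paired vectors must be 1-D and of equal length")
    ok = np.isfinite(before) & np.isfinite(after)
    before, after = before[ok], after[ok]
    if before.size < 2:
        raise ValueError("need >= 2 complete pairs")
    diff = after - before
    if diff.std() == 0:
        c = float(diff[0])
        if c == 0:
            return TestResult(0.0, float(diff.size - 1), 1.0, degenerate=True)
        return TestResult(np.sign(c) * np.inf, float(diff.size - 1), 0.0,
                          degenerate=True)
    res = sps.ttest_rel(after, before)
    return TestResult(float(res.statistic), float(diff.size - 1),
                      float(res.pvalue))


def anova_bonferroni(
    groups: dict[str, np.ndarray] | list,
    equal_var: bool = False,
) -> dict:
    """One-way fixed-effects ANOVA plus Bonferroni-adjusted pairwise t-tests.

    Pairwise comparisons use :func:`unpaired_t` (Welch by default) with
    p_adj = min(1, m * p), m = k(k-1)/2.

    Returns a dict with keys ``F``, ``df`` (between, within), ``p_omnibus``
    and ``pairwise`` (DataFrame: group_a, group_b, t, df, p, p_adj).
    """
    if isinstance(groups, dict):
        labels = list(groups)
        data = [(_as_group(groups[k], k)) for k in labels]
    else:
        labels = [f"group{i}" for i in range(len(groups))]
        data = [_as_group(g, lab) for g, lab in zip(groups, labels)]
    k = len(data)
    if k < 2:
        raise ValueError("ANOVA needs >= 2 groups")

    f_res = sps.f_oneway(*data)
    n_total = sum(g.size for g in data)
    m = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            r = unpaired_t(data[i], data[j], equal_var=equal_var)
            rows.append({
                "group_a": labels[i], "group_b": labels[j],
                "t": r.statistic, "df": r.df, "p": r.p,
                "p_adj": min(1.0, m * r.p),
            })
    return {
        "F": float(f_res.statistic),
        "df": (k - 1, n_total - k),
        "p_omnibus": float(f_res.pvalue),
        "pairwise": pd.DataFrame(rows),
    }


def _fmt_cell(mean: float, sem: float, markers: str = "") -> str:
    return f"{mean:.2f}±{sem:.2f}{markers}"


def build_report(
    measurements: pd.DataFrame,
    measurement: str,
    baseline_condition: str = "baseline",
    acute_condition: str = "acute_cold",
    condition_order: list[str] | None = None,
    marker_p: float = MARKER_P_THRESHOLD,
) -> pd.DataFrame:
    """Assemble one report table (rows = tracer, columns = condition).

    ``measurements`` is tidy with columns: tracer, condition, measurement,
    value, quantifiable.  Cells show mean +/- SEM; an up-arrow marker flags
    p < ``marker_p`` vs. the baseline condition and a dagger flags
    p < ``marker_p`` vs. the acute-cold condition (paired where subjects
    repeat, here unpaired on the per-subject values).  Groups whose values
    are flagged not quantifiable print NQ; missing condition cells print NA.
    """
    df = measurements[measurements["measurement"] == measurement]
    if "quantifiable" not in df.columns:
        df = df.assign(quantifiable=True)
    tracers = list(dict.fromkeys(df["tracer"]))
    if condition_order is None:
        condition_order = list(dict.fromkeys(df["condition"]))

    def group_values(tracer, cond):
        g = df[(df["tracer"] == tracer) & (df["condition"] == cond)]
        if g.empty:
            return None  # NA
        if not g["quantifiable"].all():
            return "NQ"
        return g["value"].to_numpy(dtype=float)

    table = {}
    for tracer in tracers:
        ref = {c: group_values(tracer, c)
               for c in (baseline_condition, acute_condition)}
        row = {}
        for cond in condition_order:
            v = group_values(tracer, cond)
            if v is None:
                row[cond] = "NA"
                continue
            if isinstance(v, str):
                row[cond] = v
                continue
            markers = ""
            for refname, symbol in ((baseline_condition, "↑"),
                                    (acute_condition, "†")):
                r = ref[refname]
                later = (refname in condition_order and cond in condition_order
                         and condition_order.index(cond)
                         > condition_order.index(refname))
                if (later and isinstance(r, np.ndarray)
                        and len(r) >= 2 and len(v) >= 2):
                    if unpaired_t(v, r).p < marker_p:
                        markers += symbol
            sem = v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0
            row[cond] = _fmt_cell(float(v.mean()), float(sem), markers)
        table[tracer] = row
    out = pd.DataFrame.from_dict(table, orient="index")
    out = out.reindex(columns=condition_order)
    out.index.name = "tracer"
    return out
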