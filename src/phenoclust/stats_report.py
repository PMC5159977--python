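"""Association statistics and per-cluster summary tables.

Continuous variables are compared across clusters with a one-way F-test
that can be computed either from raw values or directly from printed
group summaries (n, mean, SD): the between-group sum of squares comes from
the group means around the weighted grand mean, the within-group sum from
``sum (n_g - 1) SD_g^2``; the two paths agree to machine precision when
the summaries are exact.  Right-skewed biomarkers are summarized
geometrically (GM with asymmetric +u/-l deltas) and tested on the log
scale.  Categorical variables use the Pearson chi-square test without
continuity correction; percentages printed with group sizes can be
reconstructed into integer counts first.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from phenoclust.cohort import geometric_interval

#: cohort variables summarized and tested on the geometric/log scale
GEOMETRIC_VARIABLES = ("feno", "blood_eos", "pc20", "sputum_eos")


@dataclass(frozen=True)
class GroupSummary:
    """Summary of one variable within one group."""

    group: str
    n: int
    location: float      # mean, or geometric mean
    spread: float        # SD, or geometric SD
    scale: str = "arithmetic"   # "arithmetic" | "geometric"

    def __post_init__(self) -> None:
        if self.scale not in ("arithmetic", "geometric"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.spread <= 0:
            raise ValueError("spread must be positive")

    def interval(self) -> tuple[float, float] | None:
        """``(+u, -l)`` deltas for a geometric summary, else None."""
        if self.scale != "geometric":
            return None
        return geometric_interval(self.location, self.spread)


def summarize(values: np.ndarray, group: str = "", geometric: bool = False) -> GroupSummary:
    """Arithmetic or geometric summary of observed values."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need at least 2 observed values")
    if geometric:
        if (x <= 0).any():
            raise ValueError("geometric summary requires positive values")
        logs = np.log(x)
        return GroupSummary(group=group, n=x.size,
                            location=float(np.exp(logs.mean())),
                            spread=float(np.exp(logs.std(ddof=1))),
                            scale="geometric")
    return GroupSummary(group=group, n=x.size, location=float(x.mean()),
                        spread=float(x.std(ddof=1)), scale="arithmetic")


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df1: int
    df2: int
    p: float


def anova_from_summary(groups: list[GroupSummary] | list[tuple]) -> AnovaResult:
    """One-way ANOVA from per-group (n, mean, SD) summaries.

    Accepts GroupSummary objects or bare ``(n, mean, sd)`` tuples.
    Identical to the raw-data F-test whenever the summaries are exact.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    parsed = []
    for g in groups:
        if isinstance(g, GroupSummary):
            parsed.append((g.n, g.location, g.spread))
        else:
            parsed.append(tuple(g))
    ns = np.array([p[0] for p in parsed], dtype=float)
    means = np.array([p[1] for p in parsed], dtype=float)
    sds = np.array([p[2] for p in parsed], dtype=float)
    if (ns < 2).any():
        raise ValueError("every group needs n >= 2")
    if not np.isfinite(sds).all():
        raise ValueError("missing SD")
    N = ns.sum()
    G = len(parsed)
    grand = float((ns * means).sum() / N)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    df1, df2 = G - 1, int(N) - G
    if ssw == 0:
        f = math.inf if ssb > 0 else 0.0
    else:
        f = (ssb / df1) / (ssw / df2)
    p = float(stats.f.sf(f, df1, df2)) if math.isfinite(f) else 0.0
    return AnovaResult(f=float(f), df1=df1, df2=df2, p=p)


def anova_raw(groups: list[np.ndarray]) -> AnovaResult:
    """One-way ANOVA on raw per-group samples (missing values dropped)."""
    summaries = [summarize(g, group=str(i)) for i, g in enumerate(groups)]
    return anova_from_summary(summaries)


@dataclass(frozen=True)
class ChisqResult:
    chi2: float
    df: int
    p: float


def chisq_table(counts: np.ndarray) -> ChisqResult:
    """Pearson chi-square on an r x c count table, no continuity correction.

    Zero-margin rows/columns are dropped with a warning.
    """
    t = np.asarray(counts, dtype=float)
    if t.ndim != 2 or (t < 0).any():
        raise ValueError("need a nonnegative 2-d count table")
    rows = t.sum(axis=1) > 0
    cols = t.sum(axis=0) > 0
    if not rows.all() or not cols.all():
        warnings.warn("dropping zero-margin rows/columns", stacklevel=2)
        t = t[np.ix_(rows, cols)]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table degenerate after dropping zero margins")
    res = stats.chi2_contingency(t, correction=False)
    return ChisqResult(chi2=float(res.statistic), df=int(res.dof), p=float(res.pvalue))


def counts_from_percentages(
    percentages: np.ndarray,
    group_ns: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct integer counts from printed percentages and group sizes.

    ``percentages`` is categories x groups (percent units); rounding is
    half-away-from-zero.  Returns (counts, consistent) where
    ``consistent[g]`` flags whether the reconstructed counts of group g sum
    to ``group_ns[g]`` (inconsistent columns are flagged, never repaired).
    """
    pct = np.asarray(percentages, dtype=float)
    ns = np.asarray(group_ns)
    raw = pct / 100.0 * ns[None, :]
    counts = np.floor(np.abs(raw) + 0.5).astype(int) * np.sign(raw).astype(int)
    consistent = counts.sum(axis=0) == ns
    return counts, consistent


# ---------------------------------------------------------------------------
# full cluster report

def cluster_table(
    records: pd.DataFrame,
    assignments: pd.Series,
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
    healthy_label: str = "healthy",
) -> pd.DataFrame:
    """Per-cluster summary table with association statistics.

    One row per variable: per-cluster ``mean +/- SD`` (or ``GM +u/-l`` for
    geometric-scale variables, tested on logs) and the F-test p-value; for
    categorical variables per-cluster percentages and a chi-square p-value.
    Rows of a cluster labelled ``healthy_label`` are summarized but excluded
    from the association tests.  Clusters with fewer than 2 observed values
    for a variable are excluded from that variable's test.
    """
    if continuous is None:
        continuous = [c for c in (
            "fev1_pp", "fvc_pp", "fev1_fvc", "bdr", "acq7", "aqlq",
            "feno", "blood_eos", "pc20", "sputum_pmn", "sputum_eos",
            "age", "onset_age", "bmi",
        ) if c in records.columns]
    if categorical is None:
        categorical = [c for c in ("arm", "granulocyte_class", "feno_high",
                                   "eos_high", "either_high") if c in records.columns]

    assignments = assignments.astype(str)
    clusters = sorted(assignments.unique())
    test_clusters = [c for c in clusters if c != healthy_label]
    rows = []
    for var in continuous:
        geometric = var in GEOMETRIC_VARIABLES
        cells = {}
        test_groups = []
        for cl in clusters:
            vals = records.loc[assignments.to_numpy() == cl, var].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if geometric:
                vals = vals[vals > 0]
            if vals.size < 2:
                cells[cl] = "na"
                continue
            s = summarize(vals, group=cl, geometric=geometric)
            if geometric:
                u, l = s.interval()
                cells[cl] = f"{s.location:.3g} +{u:.3g}/-{l:.3g}"
                if cl in test_clusters:
                    test_groups.append(np.log(vals))
            else:
                cells[cl] = f"{s.location:.3g} ± {s.spread:.3g}"
                if cl in test_clusters:
                    test_groups.append(vals)
        p = anova_raw(test_groups).p if len(test_groups) >= 2 else float("nan")
        rows.append({"variable": var, "kind": "geometric" if geometric else "mean",
                     **cells, "p_value": p})

    for var in categorical:
        sub = records[[var]].copy()
        sub["cluster"] = assignments.to_numpy()
        sub = sub.dropna()
        if sub.empty:
            continue
        table = pd.crosstab(sub[var], sub["cluster"])
        cells = {}
        for cl in clusters:
            if cl in table.columns and table[cl].sum() > 0:
                top = table[cl].idxmax()
                cells[cl] = " / ".join(
                    f"{100 * v / table[cl].sum():.0f}% {idx}"
                    for idx, v in table[cl].items() if v > 0
                ) if len(table) <= 4 else f"mode: {top}"
            else:
                cells[cl] = "na"
        test_cols = [c for c in test_clusters if c in table.columns]
        if len(test_cols) >= 2 and len(table) >= 2:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p = chisq_table(table[test_cols].to_numpy()).p
            except ValueError:
                p = float("nan")
        else:
            p = float("nan")
        rows.append({"variable": var, "kind": "categorical", **cells, "p_value": p})

    return pd.DataFrame(rows)
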