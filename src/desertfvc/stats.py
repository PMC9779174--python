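"""Grade-wise comparison of index accuracy: one-way ANOVA and Duncan's test.

For each desertification grade and each accuracy metric (OA in percent,
kappa, |RE|), the 19 indices form a balanced one-way layout (k = 19 groups,
n = 6 images per group).  A textbook ANOVA decomposes the total sum of
squares into between- and within-group parts (df 18 / 95 / 113 for the full
design), and Duncan's multiple range test assigns compact letter groupings
to the sorted group means.

Duncan's critical range for a span of p ordered means is

    R_p = q*(p, df_within) * sqrt(MS_within / n),

where q* is the studentized-range quantile at the protection level
1 - (1 - alpha)^(p - 1) (computed from scipy's studentized-range
distribution, not interpolated from historical tables).  Groups whose
extreme difference falls below R_p — and every pair inside such a span —
share a letter.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaTable",
    "DuncanResult",
    "one_way_anova",
    "anova_consistency",
    "duncan_mrt",
    "replicate_study",
    "anova_frame",
    "duncan_frame",
]

METRICS = ("oa_percent", "kappa", "abs_re")


@dataclass(frozen=True)
class AnovaTable:
    """One-way ANOVA decomposition; ``f``/``p`` are NaN when MS_within = 0."""

    ss_between: float
    ss_within: float
    ss_total: float
    df_between: int
    df_within: int
    df_total: int
    ms_between: float
    ms_within: float
    f: float
    p: float


@dataclass(frozen=True)
class DuncanResult:
    """Duncan letters over group means sorted in descending order."""

    names: tuple[str, ...]          # sorted by descending mean
    means: tuple[float, ...]        # descending
    critical_ranges: dict[int, float]   # span p -> R_p
    letters: dict[str, str]         # group name -> letter string ("a", "ab", ...)
    alpha: float


def one_way_anova(groups) -> AnovaTable:
    """Textbook one-way ANOVA of k groups of observations.

    ``groups`` is a sequence of k >= 2 sequences, each with >= 2 values.
    When every observation is identical (MS_within = 0 and MS_between = 0)
    the F ratio is reported as 0; when MS_within = 0 with non-zero
    between-group spread, F and p are NaN (undefined).
    """
    arrs = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.ndim != 1 or a.size < 2 for a in arrs):
        raise ValueError("every group needs at least 2 observations")
    all_vals = np.concatenate(arrs)
    n_total = all_vals.size
    grand = all_vals.mean()
    ss_between = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrs))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrs))
    ss_total = float(((all_vals - grand) ** 2).sum())
    df_between = len(arrs) - 1
    df_within = n_total - len(arrs)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        f = 0.0 if ms_between == 0.0 else float("nan")
        p = 1.0 if ms_between == 0.0 else float("nan")
    else:
        f = ms_between / ms_within
        p = float(sps.f.sf(f, df_between, df_within))
    return AnovaTable(
        ss_between=ss_between, ss_within=ss_within, ss_total=ss_total,
        df_between=df_between, df_within=df_within,
        df_total=n_total - 1,
        ms_between=ms_between, ms_within=ms_within, f=f, p=p,
    )


def anova_consistency(
    tss_between: float, df_between: int, tss_within: float, df_within: int
) -> tuple[float, float, float]:
    """Mean squares and F recomputed from printed TSS/df columns.

    Audit helper for published ANOVA tables: returns
    (MS_between, MS_within, F).
    """
    if df_between <= 0 or df_within <= 0:
        raise ValueError("degrees of freedom must be positive")
    ms_b = tss_between / df_between
    ms_w = tss_within / df_within
    return ms_b, ms_w, ms_b / ms_w


@lru_cache(maxsize=4096)
def _duncan_quantile(p: int, df_within: int, alpha: float) -> float:
    """Studentized-range quantile at Duncan's protection level
    1 - (1 - alpha)^(p - 1); cached, as the scipy solver is expensive."""
    level = (1 - alpha) ** (p - 1)
    return float(sps.studentized_range.ppf(level, p, df_within))


def duncan_mrt(
    groups,
    alpha: float = 0.05,
    names=None,
    ms_within: float | None = None,
    df_within: int | None = None,
) -> DuncanResult:
    """Duncan's multiple range test on balanced groups.

    ``groups`` is a sequence of k equal-length groups.  ``ms_within`` /
    ``df_within`` default to the companion ANOVA of the same groups.  Ties
    in the means are broken by input order (stable sort).
    """
    arrs = [np.asarray(g, dtype=np.float64) for g in groups]
    k = len(arrs)
    if k < 2:
        raise ValueError("need at least 2 groups")
    sizes = {a.size for a in arrs}
    if len(sizes) != 1:
        raise ValueError("Duncan's test requires balanced groups")
    n = arrs[0].size
    if names is None:
        names = [f"group{i}" for i in range(k)]
    names = list(names)
    if len(names) != k:
        raise ValueError("names length must match number of groups")
    if ms_within is None or df_within is None:
        table = one_way_anova(arrs)
        ms_within = table.ms_within
        df_within = table.df_within

    means = np.array([a.mean() for a in arrs])
    order = np.argsort(-means, kind="stable")
    sorted_means = means[order]
    sorted_names = [names[i] for i in order]

    se = np.sqrt(ms_within / n)
    ranges = {
        p: float(_duncan_quantile(p, int(df_within), float(alpha)) * se) if se > 0 else 0.0
        for p in range(2, k + 1)
    }

    # Step-down: spans from widest to narrowest; a span inside an already
    # accepted (non-significant) span is not tested.
    nonsig = np.zeros((k, k), dtype=bool)  # nonsig[i, j], i < j over sorted order
    for i in range(k):
        nonsig[i, i] = True
    protected: list[tuple[int, int]] = []
    for p in range(k, 1, -1):
        for i in range(0, k - p + 1):
            j = i + p - 1
            if any(a <= i and j <= b for a, b in protected):
                continue
            if sorted_means[i] - sorted_means[j] <= ranges[p]:
                protected.append((i, j))
                nonsig[i:j + 1, i:j + 1] = True

    # Letters: maximal non-significant intervals over the sorted means.
    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k and nonsig[i, j + 1]:
            j += 1
        intervals.append((i, j))
    maximal = [
        iv for idx, iv in enumerate(intervals)
        if not any(o[0] <= iv[0] and iv[1] <= o[1] and o != iv for o in intervals)
    ]
    # Deduplicate while preserving order.
    seen = set()
    blocks = []
    for iv in maximal:
        if iv not in seen:
            seen.add(iv)
            blocks.append(iv)

    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {name: "" for name in sorted_names}
    for bi, (a, b) in enumerate(blocks):
        ch = alphabet[bi % len(alphabet)] * (bi // len(alphabet) + 1)
        for idx in range(a, b + 1):
            letters[sorted_names[idx]] += ch

    return DuncanResult(
        names=tuple(sorted_names),
        means=tuple(float(m) for m in sorted_means),
        critical_ranges=ranges,
        letters=letters,
        alpha=alpha,
    )


def replicate_study(
    metric_table: pd.DataFrame, alpha: float = 0.05
) -> dict[tuple[str, str], tuple[AnovaTable, DuncanResult]]:
    """Per-grade, per-metric ANOVA and Duncan letters of a balanced layout.

    ``metric_table`` has columns (index, image_id, grade, metric, value); for
    every (grade, metric) cell the layout must be balanced across indices.
    """
    required = {"index", "image_id", "grade", "metric", "value"}
    missing = required - set(metric_table.columns)
    if missing:
        raise ValueError(f"metric table missing columns {sorted(missing)}")
    results: dict[tuple[str, str], tuple[AnovaTable, DuncanResult]] = {}
    for (grade, metric), block in metric_table.groupby(["grade", "metric"], sort=False):
        counts = block.groupby("index")["value"].count()
        if counts.nunique() != 1:
            raise ValueError(
                f"unbalanced layout at grade={grade!r}, metric={metric!r}: "
                f"{counts.to_dict()}"
            )
        names = [n for n in block["index"].unique()]
        groups = [block.loc[block["index"] == n, "value"].to_numpy() for n in names]
        table = one_way_anova(groups)
        duncan = duncan_mrt(groups, alpha=alpha, names=names,
                            ms_within=table.ms_within, df_within=table.df_within)
        results[(grade, metric)] = (table, duncan)
    return results


def anova_frame(results: dict) -> pd.DataFrame:
    """Flatten replicate_study ANOVA tables into the printed-table layout."""
    rows = []
    for (grade, metric), (t, _) in results.items():
        rows.append(dict(grade=grade, metric=metric, source="Between Groups",
                         tss=t.ss_between, df=t.df_between, ms=t.ms_between,
                         f=t.f, p=t.p))
        rows.append(dict(grade=grade, metric=metric, source="Within Groups",
                         tss=t.ss_within, df=t.df_within, ms=t.ms_within,
                         f=np.nan, p=np.nan))
        rows.append(dict(grade=grade, metric=metric, source="Grand Total",
                         tss=t.ss_total, df=t.df_total, ms=np.nan,
                         f=np.nan, p=np.nan))
    return pd.DataFrame(rows)


def duncan_frame(results: dict) -> pd.DataFrame:
    """Flatten replicate_study Duncan letters into (grade, metric, index) rows."""
    rows = []
    for (grade, metric), (_, d) in results.items():
        for name, mean in zip(d.names, d.means):
            rows.append(dict(grade=grade, metric=metric, index=name,
                             mean=mean, letters=d.letters[name]))
    return pd.DataFrame(rows)
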