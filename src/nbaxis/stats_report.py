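"""Condition comparison statistics: descriptive summaries and the
two-tailed Mann–Whitney U test.

The U statistic is computed from midranks.  For small tie-free samples
(combined n ≤ 20) the two-tailed p value is exact, from the complete
distribution of U under the permutation null (shift-algorithm recursion);
otherwise the normal approximation with tie correction and continuity
correction is used.  Two-tailed p = min(1, 2 · one-sided).  The method
actually used is recorded in every result.

Descriptive summaries follow the usual boxplot conventions: median, linear
interpolation (type-7) quartiles, whiskers at the most extreme data points
within 1.5 × IQR of the quartiles, points beyond them listed as outliers.

No multiple-testing correction is applied by default — pairwise raw p
values are reported, with an optional Holm adjustment flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "ConditionSummary",
    "TestResult",
    "summarize",
    "mann_whitney_u",
    "compare_conditions",
    "EXACT_MAX_N",
]

#: Combined sample size at or below which the exact null distribution is
#: used (when the pooled sample has no ties).
EXACT_MAX_N = 20


@dataclass(frozen=True)
class ConditionSummary:
    """Descriptive summary of one condition's sample."""

    condition: str
    n: int
    mean: float
    sd: float          # sample SD, n-1 denominator; 0 with flag for n == 1
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: tuple[float, ...]
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class TestResult:
    """One pairwise two-tailed Mann–Whitney U comparison."""

    condition_a: str
    condition_b: str
    n1: int
    n2: int
    u: float              # U of the first sample, in [0, n1*n2]
    p_value: float
    method: str           # "exact" | "normal-approximation"
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p value {self.p_value} outside (0, 1]")
        if not (-1e-9 <= self.u <= self.n1 * self.n2 + 1e-9):
            raise ValueError("U outside [0, n1*n2]")


def summarize(values: Sequence[float], condition: str = "") -> ConditionSummary:
    """Boxplot-style descriptive summary of a sample."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    flags: list[str] = []
    if x.size == 1:
        sd = 0.0
        flags.append("single-value-sd-undefined")
    else:
        sd = float(np.std(x, ddof=1))
    q1, med, q3 = (float(q) for q in np.percentile(x, [25, 50, 75]))  # type-7
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    whisker_lo = float(inside.min()) if inside.size else q1
    whisker_hi = float(inside.max()) if inside.size else q3
    outliers = tuple(float(v) for v in np.sort(x[(x < lo_fence) | (x > hi_fence)]))
    return ConditionSummary(
        condition=condition,
        n=int(x.size),
        mean=float(x.mean()),
        sd=sd,
        median=med,
        q1=q1,
        q3=q3,
        whisker_lo=whisker_lo,
        whisker_hi=whisker_hi,
        outliers=outliers,
        flags=tuple(flags),
    )


@lru_cache(maxsize=None)
def _u_null_counts(n1: int, n2: int) -> np.ndarray:
    """Counts of arrangements with each U value under the tie-free null.

    Shift-algorithm recursion N(u; n1, n2) = N(u - n2; n1-1, n2)
    + N(u; n1, n2-1); entry u holds the number of the C(n1+n2, n1)
    rank assignments giving U = u.
    """
    if n1 == 0 or n2 == 0:
        return np.ones(1)
    a = _u_null_counts(n1 - 1, n2)
    b = _u_null_counts(n1, n2 - 1)
    out = np.zeros(n1 * n2 + 1)
    out[n2 : n2 + a.size] += a
    out[: b.size] += b
    return out


def exact_u_cdf(u: float, n1: int, n2: int) -> float:
    """P(U ≤ u) under the exact tie-free permutation null."""
    counts = _u_null_counts(n1, n2)
    return float(counts[: int(np.floor(u)) + 1].sum() / counts.sum())


def mann_whitney_u(
    sample1: Sequence[float],
    sample2: Sequence[float],
    condition_a: str = "a",
    condition_b: str = "b",
) -> TestResult:
    """Two-tailed Mann–Whitney U test.

    U comes from midrank rank sums.  Exact p (complete null distribution)
    when the combined sample is tie-free with n1 + n2 ≤ ``EXACT_MAX_N``;
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks for ties
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1

    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and n1 + n2 <= EXACT_MAX_N:
        p_one = exact_u_cdf(min(u1, u2), n1, n2)
        p = min(1.0, 2.0 * p_one)
        method = "exact"
    else:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        _, t = np.unique(pooled, return_counts=True)
        tie_term = float(((t**3 - t).sum())) / (n * (n - 1)) if n > 1 else 0.0
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0  # all observations identical
        else:
            z = (abs(u1 - mu) - 0.5) / np.sqrt(var)  # continuity correction
            z = max(z, 0.0)
            p = min(1.0, 2.0 * float(norm.sf(z)))
        method = "normal-approximation"
    return TestResult(
        condition_a=condition_a,
        condition_b=condition_b,
        n1=n1,
        n2=n2,
        u=float(u1),
        p_value=float(p),
        method=method,
    )


def _holm(pvals: list[float]) -> list[float]:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


def compare_conditions(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]],
    value_col: str = "value",
    condition_col: str = "condition",
    holm: bool = False,
) -> dict:
    """Summaries per condition plus pairwise U tests.

    ``table`` holds one measurement per row with a condition label.  Raw
    pairwise p values are reported (no multiple-testing correction unless
    ``holm=True``, which adds a ``p_adjusted`` column).  Returns a dict
    with ``summaries`` and ``tests`` DataFrames and a human-readable
    ``report`` string.
    """
    if condition_col not in table or value_col not in table:
        raise ValueError(f"table needs columns {condition_col!r} and {value_col!r}")
    groups = {str(k): np.asarray(v[value_col], dtype=float) for k, v in table.groupby(condition_col)}
    if len(groups) < 2:
        raise ValueError("need at least 2 conditions to compare")
    for a, b in pairs:
        for name in (a, b):
            if name not in groups:
                raise ValueError(f"unknown condition {name!r}; have {sorted(groups)}")

    summaries = [summarize(groups[name], name) for name in sorted(groups)]
    tests = [mann_whitney_u(groups[a], groups[b], a, b) for a, b in pairs]
    if holm and tests:
        adj = _holm([t.p_value for t in tests])
        tests = [
            TestResult(**{**t.__dict__, "p_adjusted": a}) for t, a in zip(tests, adj)
        ]

    sum_df = pd.DataFrame([s.__dict__ for s in summaries]).drop(columns=["flags"])
    sum_df["outliers"] = sum_df["outliers"].apply(lambda o: ";".join(f"{v:g}" for v in o))
    test_df = pd.DataFrame([t.__dict__ for t in tests])
    if not holm and "p_adjusted" in test_df:
        test_df = test_df.drop(columns=["p_adjusted"])

    lines = [
        "Condition comparison report",
        "quartiles: linear interpolation (type-7); whiskers: 1.5 x IQR;",
        f"U test: exact null distribution when combined n <= {EXACT_MAX_N} and no ties,",
        "else tie-corrected normal approximation with continuity correction;",
        "p values are raw pairwise values (no multiple-testing correction)"
        + (" with Holm adjustment shown in p_adjusted" if holm else "")
        + ".",
        "",
    ]
    for s in summaries:
        lines.append(
            f"{s.condition}: {s.mean:.1f} +/- {s.sd:.1f} (n = {s.n}), "
            f"median {s.median:.1f} [{s.q1:.1f}, {s.q3:.1f}]"
        )
    lines.append("")
    for t in tests:
        extra = f", Holm-adjusted {t.p_adjusted:.3g}" if t.p_adjusted is not None else ""
        lines.append(
            f"{t.condition_a} vs {t.condition_b}: U = {t.u:g}, "
            f"two-tailed p = {t.p_value:.3g} ({t.method}){extra}"
        )
    return {"summaries": sum_df, "tests": test_df, "report": "\n".join(lines)}


def write_report_csv(result: dict, summaries_path, tests_path) -> None:
    """Write the two report tables with convention-declaring '#' headers."""
    header = (
        "# angles in degrees / fractions in percent; quartiles type-7 (linear"
        " interpolation); whiskers 1.5*IQR; U test exact for combined n <= "
        f"{EXACT_MAX_N} without ties, else tie-corrected normal approximation\n"
    )
    for df, path in ((result["summaries"], summaries_path), (result["tests"], tests_path)):
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
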