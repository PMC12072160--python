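"""Group-comparison statistics for ROI/image metrics.

One-way ANOVA across treatment groups, Bonferroni-adjusted pairwise
t-tests as the post hoc, and medians with confidence intervals
(percentile bootstrap or the distribution-free order-statistic
interval).  ``compare_groups`` bundles these into a results object with
a ``summary()``.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "one_way_anova",
    "bonferroni_pairwise",
    "median_ci",
    "compare_groups",
    "GroupComparisonResult",
]


def _as_groups(data) -> dict[str, np.ndarray]:
    if isinstance(data, dict):
        groups = {str(k): np.asarray(v, dtype=float) for k, v in data.items()}
    else:
        raise TypeError("data must be a mapping label -> values")
    if any(g.size == 0 for g in groups.values()):
        raise ValueError("every group must be nonempty")
    return groups


def one_way_anova(data: dict) -> tuple[float, float, dict]:
    """Classical one-way ANOVA: F = MS_between / MS_within.

    Returns ``(F, p, info)`` where ``info`` records degrees of freedom
    and a flag for degenerate inputs: equal group means give F = 0 and
    p = 1; zero within-group variance with unequal means gives the
    limiting F = inf, p = 0, flagged.
    """
    groups = _as_groups(data)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    values = np.concatenate(list(groups.values()))
    k, n = len(groups), values.size
    if n <= k:
        raise ValueError("total n must exceed the number of groups")
    grand = values.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups.values())
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
    dfb, dfw = k - 1, n - k
    info = {"df_between": dfb, "df_within": dfw, "ss_between": ssb, "ss_within": ssw, "flag": None}
    if ssb == 0:
        return 0.0, 1.0, info
    if ssw == 0:
        info["flag"] = "zero within-group variance with unequal means; limiting p = 0"
        return math.inf, 0.0, info
    F = (ssb / dfb) / (ssw / dfw)
    p = float(sps.f.sf(F, dfb, dfw))
    return float(F), p, info


def bonferroni_pairwise(data: dict, equal_var: bool = True) -> dict:
    """Two-sample t-tests on all unordered pairs, Bonferroni-adjusted.

    Pooled-variance t by default (``equal_var=False`` for Welch).  The
    adjusted p is min(1, raw p x number of comparisons performed); a
    pair containing a size-1 group is skipped with a flag.
    """
    groups = _as_groups(data)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    pairs = list(combinations(sorted(groups), 2))
    results: dict = {}
    tested = [(a, b) for a, b in pairs if groups[a].size > 1 and groups[b].size > 1]
    m = len(tested)
    for a, b in pairs:
        if (a, b) not in tested:
            results[(a, b)] = {"raw_p": None, "adjusted_p": None, "flag": "group of size 1; skipped"}
            continue
        t, p = sps.ttest_ind(groups[a], groups[b], equal_var=equal_var)
        results[(a, b)] = {
            "t": float(t),
            "raw_p": float(p),
            "adjusted_p": min(1.0, float(p) * m),
            "flag": None,
        }
    return results


def median_ci(
    values,
    level: float = 0.95,
    method: str = "bootstrap",
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float, float, str | None]:
    """Sample median with a confidence interval.

    ``bootstrap``: percentile interval over ``n_boot`` seeded resamples.
    ``order_statistic``: distribution-free interval from binomial order
    statistics, coverage >= level.  With n < 3 the full data range is
    returned, flagged as degenerate.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 1:
        raise ValueError("need at least one value")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    med = float(np.median(x))
    if n < 3:
        return med, float(x[0]), float(x[-1]), "n < 3: CI is the data range"
    alpha = 1.0 - level
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        meds = np.median(x[idx], axis=1)
        lo, hi = np.quantile(meds, [alpha / 2, 1 - alpha / 2])
        return med, float(lo), float(hi), None
    if method == "order_statistic":
        # largest k with P(Bin(n, 1/2) <= k - 1) <= alpha/2; interval (x_(k), x_(n-k+1)) 1-based
        k = int(sps.binom.ppf(alpha / 2, n, 0.5))
        while k > 0 and sps.binom.cdf(k - 1, n, 0.5) > alpha / 2:
            k -= 1
        k = max(k, 1)
        return med, float(x[k - 1]), float(x[n - k]), None
    raise ValueError(f"unknown method {method!r}")


@dataclass
class GroupComparisonResult:
    """ANOVA + Bonferroni post hoc + per-group summaries."""

    F: float
    p: float
    anova_info: dict
    pairwise: dict
    group_summaries: pd.DataFrame

    def summary(self) -> str:
        lines = [
            "One-way ANOVA",
            f"  F({self.anova_info['df_between']}, {self.anova_info['df_within']}) = {self.F:.4g}, p = {self.p:.4g}",
        ]
        if self.anova_info.get("flag"):
            lines.append(f"  note: {self.anova_info['flag']}")
        lines.append("Bonferroni pairwise comparisons")
        for (a, b), r in self.pairwise.items():
            if r.get("flag"):
                lines.append(f"  {a} vs {b}: {r['flag']}")
            else:
                lines.append(
                    f"  {a} vs {b}: raw p = {r['raw_p']:.4g}, adjusted p = {r['adjusted_p']:.4g}"
                )
        lines.append("Group summaries (median [CI], mean +/- SD)")
        for _, row in self.group_summaries.iterrows():
            lines.append(
                f"  {row['group']}: median {row['median']:.4g} "
                f"[{row['ci_lo']:.4g}, {row['ci_hi']:.4g}], "
                f"mean {row['mean']:.4g} +/- {row['sd']:.4g} (n={int(row['n'])})"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "F": self.F,
            "p": self.p,
            "anova_info": self.anova_info,
            "pairwise": {f"{a}|{b}": r for (a, b), r in self.pairwise.items()},
            "groups": self.group_summaries.to_dict(orient="records"),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)


def compare_groups(
    data: dict,
    level: float = 0.95,
    ci_method: str = "bootstrap",
    equal_var: bool = True,
    seed: int = 0,
) -> GroupComparisonResult:
    """Full group comparison: ANOVA, Bonferroni post hoc, medians with CIs.

    Both median-based and mean +/- SD summaries are reported, matching
    the two summary conventions in common use.
    """
    groups = _as_groups(data)
    F, p, info = one_way_anova(groups)
    pairwise = bonferroni_pairwise(groups, equal_var=equal_var)
    rows = []
    for label, vals in groups.items():
        med, lo, hi, flag = median_ci(vals, level=level, method=ci_method, seed=seed)
        rows.append(
            {
                "group": label,
                "n": vals.size,
                "median": med,
                "ci_lo": lo,
                "ci_hi": hi,
                "ci_flag": flag,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            }
        )
    return GroupComparisonResult(F, p, info, pairwise, pd.DataFrame(rows))
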