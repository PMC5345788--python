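"""Group-level statistics for per-cell kinetic metrics.

Summaries are arithmetic mean +/- sample SD; inference covers unpaired and
paired t tests, one-way ANOVA with a Newman-Keuls stepdown post hoc on the
studentized range, and a repeated-measures ANOVA.  Treatment effects are
expressed as percent of control with a delta-method standard error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "CohortResult",
    "NormalizedEffect",
    "summarize",
    "compare",
    "newman_keuls",
    "normalize_to_control",
]


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float


@dataclass
class CohortResult:
    groups: list[GroupSummary]
    test: str
    statistic: float
    p_value: float
    posthoc: Optional[list[tuple[str, str, bool]]] = None
    alpha: float = 0.05


@dataclass(frozen=True)
class NormalizedEffect:
    treatment_label: str
    control_label: str
    percent_of_control: float
    dispersion: float  # propagated SE, percentage points


def _as_groups(groups: dict[str, Sequence[float]]) -> dict[str, np.ndarray]:
    out = {}
    for label, vals in groups.items():
        arr = np.asarray(list(vals), dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {label!r} is empty")
        out[label] = arr
    return out


def summarize(groups: dict[str, Sequence[float]]) -> list[GroupSummary]:
    """Arithmetic mean and sample SD (ddof=1) per group."""
    out = []
    for label, arr in _as_groups(groups).items():
        sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
        out.append(GroupSummary(label=label, n=int(arr.size), mean=float(np.mean(arr)), sd=sd))
    return out


def newman_keuls(
    groups: dict[str, Sequence[float]], alpha: float = 0.05
) -> list[tuple[str, str, bool]]:
    """Newman-Keuls stepdown pairwise comparisons after a one-way ANOVA.

    Means are ranked; each pair spanning p ordered means is tested against
    the studentized-range critical value q(alpha, p, df_error) using the
    pooled within-group mean square and the harmonic mean of the two group
    sizes.  Stepdown rule: a pair nested inside a non-significant span is
    declared non-significant without testing.
    """
    g = _as_groups(groups)
    labels = list(g)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least two groups")
    ns = np.array([g[l].size for l in labels])
    if np.any(ns < 2):
        raise ValueError("each group needs n >= 2")
    means = np.array([g[l].mean() for l in labels])
    df_err = int(ns.sum() - k)
    mse = sum(np.sum((g[l] - g[l].mean()) ** 2) for l in labels) / df_err

    order = np.argsort(means)  # ascending
    sig: dict[frozenset, bool] = {}
    # test spans from widest to narrowest
    for span in range(k, 1, -1):
        for start in range(0, k - span + 1):
            i, j = order[start], order[start + span - 1]
            pair = frozenset((labels[i], labels[j]))
            # nested inside an already non-significant wider span?
            blocked = any(
                not s
                for key, s in sig.items()
                if key != pair and _span_contains(labels, order, means, key, labels[i], labels[j])
            )
            if blocked:
                sig[pair] = False
                continue
            nh = 2.0 / (1.0 / ns[i] + 1.0 / ns[j])
            q = abs(means[j] - means[i]) / np.sqrt(mse / nh)
            qcrit = sps.studentized_range.ppf(1.0 - alpha, span, df_err)
            sig[pair] = bool(q > qcrit)

    out = []
    for a in range(k):
        for b in range(a + 1, k):
            pair = frozenset((labels[a], labels[b]))
            out.append((labels[a], labels[b], sig[frozenset(pair)]))
    return out


def _span_contains(labels, order, means, key: frozenset, la: str, lb: str) -> bool:
    """True when the ordered span of pair `key` contains the span (la, lb)."""
    pos = {labels[idx]: rank for rank, idx in enumerate(order)}
    ka, kb = sorted(key, key=lambda l: pos[l])
    lo, hi = sorted((pos[la], pos[lb]))
    return pos[ka] <= lo and hi <= pos[kb]


def compare(
    groups: dict[str, Sequence[float]],
    design: str = "anova_1way",
    alpha: float = 0.05,
) -> CohortResult:
    """Classical test of a group effect on per-cell values.

    design: 't_unpaired', 't_paired', 'anova_1way' (with Newman-Keuls
    post hoc when the omnibus test is significant) or 'anova_rm'
    (repeated measures, groups treated as within-subject conditions with
    matched ordering).
    """
    g = _as_groups(groups)
    labels = list(g)
    summaries = summarize(groups)

    if design == "t_unpaired":
        if len(g) != 2:
            raise ValueError("t_unpaired requires exactly two groups")
        stat, p = sps.ttest_ind(g[labels[0]], g[labels[1]])
    elif design == "t_paired":
        if len(g) != 2:
            raise ValueError("t_paired requires exactly two groups")
        a, b = g[labels[0]], g[labels[1]]
        if len(a) != len(b):
            raise ValueError("paired design requires matched lengths")
        stat, p = sps.ttest_rel(a, b)
        if np.isnan(stat):  # identical pairs
            stat, p = 0.0, 1.0
    elif design == "anova_1way":
        stat, p = sps.f_oneway(*g.values())
        if np.isnan(stat):  # zero within-group variance and equal means
            stat, p = 0.0, 1.0
    elif design == "anova_rm":
        lens = {len(v) for v in g.values()}
        if len(lens) != 1:
            raise ValueError("repeated-measures design requires matched lengths")
        from statsmodels.stats.anova import AnovaRM

        n = lens.pop()
        long = pd.DataFrame(
            {
                "subject": np.tile(np.arange(n), len(g)),
                "condition": np.repeat(labels, n),
                "value": np.concatenate([g[l] for l in labels]),
            }
        )
        res = AnovaRM(long, depvar="value", subject="subject", within=["condition"]).fit()
        stat = float(res.anova_table["F Value"].iloc[0])
        p = float(res.anova_table["Pr > F"].iloc[0])
    else:
        raise ValueError(f"unknown design {design!r}")

    result = CohortResult(
        groups=summaries, test=design, statistic=float(stat), p_value=float(p), alpha=alpha
    )
    if design == "anova_1way" and result.p_value < alpha and len(g) > 2:
        result.posthoc = newman_keuls(groups, alpha=alpha)
    return result


def normalize_to_control(
    treated: Sequence[float],
    control: Sequence[float],
    treatment_label: str = "treated",
    control_label: str = "control",
) -> NormalizedEffect:
    """Treated group mean expressed as percent of the control group mean.

    Dispersion is the delta-method SE of the ratio of means,
    pct * sqrt(SE_t^2/mean_t^2 + SE_c^2/mean_c^2), in percentage points.
    """
    t = np.asarray(list(treated), dtype=float)
    c = np.asarray(list(control), dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValueError("both groups must be non-empty")
    mc = c.mean()
    if mc <= 0:
        raise ValueError("control mean must be positive")
    mt = t.mean()
    pct = 100.0 * mt / mc
    se_t = t.std(ddof=1) / np.sqrt(t.size) if t.size > 1 else 0.0
    se_c = c.std(ddof=1) / np.sqrt(c.size) if c.size > 1 else 0.0
    disp = abs(pct) * np.sqrt((se_t / mt) ** 2 + (se_c / mc) ** 2) if mt != 0 else np.nan
    return NormalizedEffect(
        treatment_label=treatment_label,
        control_label=control_label,
        percent_of_control=float(pct),
        dispersion=float(disp),
    )
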