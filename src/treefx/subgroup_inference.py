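"""Subgroup statistics: leaf contrasts, Fisher/Wilcoxon group comparisons,
trend tests across ordered leaves, Pearson correlations, summary tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .trial_data import BINARY, CovariateSpec, TrialDataset

__all__ = [
    "SubgroupContrast",
    "TrendTestResult",
    "leaf_contrast",
    "fisher_exact_2x2",
    "wilcoxon_rank_sum",
    "mantel_trend",
    "linear_trend",
    "pearson_correlation",
    "subpopulation_tables",
]


@dataclass(frozen=True)
class SubgroupContrast:
    """Arm contrast within one leaf: difference in means with Welch 95% CI."""

    leaf_label: int
    n1: int
    n0: int
    mean1: float
    mean0: float
    diff: float
    ci_low: float
    ci_high: float
    p: float


@dataclass(frozen=True)
class TrendTestResult:
    method: str  # "mantel" | "linear"
    statistic: float
    p: float
    scores: tuple[float, ...]


def leaf_contrast(
    y: Sequence[float], w: Sequence[int], leaf_label: int = 0, level: float = 0.95
) -> SubgroupContrast:
    """Welch two-sample contrast (active minus control) with CI and p.

    If both arm variances are zero the CI collapses to [diff, diff] and
    p is 0 for a nonzero difference, 1 otherwise.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=int)
    y1, y0 = y[w == 1], y[w == 0]
    if len(y1) == 0 or len(y0) == 0:
        raise ValidationError("both arms must be non-empty")
    m1, m0 = float(y1.mean()), float(y0.mean())
    diff = m1 - m0
    v1 = float(y1.var(ddof=1)) if len(y1) > 1 else 0.0
    v0 = float(y0.var(ddof=1)) if len(y0) > 1 else 0.0
    if v1 == 0.0 and v0 == 0.0:
        return SubgroupContrast(
            leaf_label, len(y1), len(y0), m1, m0, diff, diff, diff,
            0.0 if diff != 0.0 else 1.0,
        )
    se2 = v1 / len(y1) + v0 / len(y0)
    se = math.sqrt(se2)
    df = se2**2 / (
        (v1 / len(y1)) ** 2 / max(len(y1) - 1, 1)
        + (v0 / len(y0)) ** 2 / max(len(y0) - 1, 1)
    )
    tcrit = float(sps.t.ppf(0.5 + level / 2.0, df))
    t = diff / se
    p = float(2.0 * sps.t.sf(abs(t), df))
    return SubgroupContrast(
        leaf_label, len(y1), len(y0), m1, m0, diff,
        diff - tcrit * se, diff + tcrit * se, p,
    )


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p by the probability-sum convention."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("table must be 2x2 with non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValidationError("all margins must be positive")
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided rank-sum p: exact when both n <= 10 with no ties, else
    normal approximation with tie and continuity corrections."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(a) <= 10 and len(b) <= 10 and not has_ties:
        return float(sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")[1])
    n1, n2 = len(a), len(b)
    ranks = sps.rankdata(pooled)
    u = float(np.sum(ranks[:n1])) - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie-corrected variance
    _, counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0.0:
        return 1.0  # all observations identical: no discrimination
    z = (abs(u - mu) - 0.5) / math.sqrt(var)  # continuity correction
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * sps.norm.sf(z)))


def mantel_trend(
    successes: Sequence[int], totals: Sequence[int], scores: Sequence[float]
) -> TrendTestResult:
    """Mantel trend chi-square for a binary trait across ordered groups.

    Expands counts to patient level; statistic = (N-1) r^2 where r is the
    Pearson correlation between the binary indicator and the group score;
    p from chi-square with 1 df.  No trend at all yields statistic 0, p 1.
    """
    successes = np.asarray(successes, dtype=int)
    totals = np.asarray(totals, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(successes) < 2 or len(successes) != len(totals) or len(totals) != len(scores):
        raise ValidationError("need >= 2 groups with matching successes/totals/scores")
    if (successes > totals).any() or (successes < 0).any() or (totals <= 0).any():
        raise ValidationError("require 0 <= successes <= totals, totals > 0")
    y: list[int] = []
    s: list[float] = []
    for k in range(len(totals)):
        y += [1] * int(successes[k]) + [0] * int(totals[k] - successes[k])
        s += [float(scores[k])] * int(totals[k])
    ya = np.asarray(y, dtype=float)
    sa = np.asarray(s, dtype=float)
    n = len(ya)
    if ya.std() == 0.0 or sa.std() == 0.0:
        return TrendTestResult("mantel", 0.0, 1.0, tuple(scores))
    r = float(np.corrcoef(ya, sa)[0, 1])
    stat = (n - 1) * r * r
    if stat == 0.0:
        return TrendTestResult("mantel", 0.0, 1.0, tuple(scores))
    p = float(sps.chi2.sf(stat, 1))
    return TrendTestResult("mantel", float(stat), p, tuple(scores))


def linear_trend(
    values: Sequence[float], group_scores: Sequence[float]
) -> TrendTestResult:
    """Two-sided p of the least-squares slope of value on group score."""
    y = np.asarray(values, dtype=float)
    x = np.asarray(group_scores, dtype=float)
    if len(y) < 3 or len(y) != len(x):
        raise ValidationError("need >= 3 patients with matching scores")
    if len(np.unique(x)) < 2:
        raise ValidationError("group scores must span >= 2 distinct values")
    sxx = float(np.sum((x - x.mean()) ** 2))
    slope = float(np.sum((x - x.mean()) * (y - y.mean()))) / sxx
    resid = y - y.mean() - slope * (x - x.mean())
    df = len(y) - 2
    rss = float(np.sum(resid**2))
    if rss <= 1e-300:
        # degenerate: perfect fit -> p 0 unless the slope itself is 0
        t = math.inf if slope != 0.0 else 0.0
        return TrendTestResult("linear", t, 0.0 if slope != 0.0 else 1.0,
                               tuple(np.unique(x)))
    se = math.sqrt(rss / df / sxx)
    t = slope / se
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TrendTestResult("linear", float(t), p, tuple(np.unique(x)))


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; errors on n < 3 or zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValidationError("need n >= 3 paired observations")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValidationError("zero variance in one of the variables")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# table builders


def _pct(x: float) -> str:
    return str(Decimal(str(100.0 * x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _fmt_median_range(v: np.ndarray) -> str:
    return f"{np.median(v):g} ({v.min():g}–{v.max():g})"


def _fmt_p(p: float) -> str:
    return "NA" if math.isnan(p) else f"{p:.3f}"


def subpopulation_tables(
    ds: TrialDataset,
    leaf_labels: Sequence[int],
    catalog: Sequence[CovariateSpec] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Arm-comparison and leaf-trend characteristic tables.

    The first table gives per-arm summaries ("n (x.x%)" for binary,
    "median (min–max)" for continuous) with Fisher / Wilcoxon p-values.
    The second gives per-leaf summaries with Mantel / linear trend
    p-values using leaf scores 1..L.
    """
    catalog = list(catalog or ds.catalog)
    leaf_labels = np.asarray(leaf_labels, dtype=int)
    if len(leaf_labels) != ds.n:
        raise ValidationError("leaf assignment length must match dataset")
    arm = ds.arm
    labels = sorted(np.unique(leaf_labels))
    scores = list(range(1, len(labels) + 1))

    rows1, rows2 = [], []
    for spec in catalog:
        v = ds.covariates[spec.name].to_numpy(float)
        if spec.kind == BINARY:
            yes1, yes0 = int(v[arm == 1].sum()), int(v[arm == 0].sum())
            n1, n0 = int((arm == 1).sum()), int((arm == 0).sum())
            p1 = fisher_exact_2x2([[yes0, n0 - yes0], [yes1, n1 - yes1]])
            rows1.append(
                {
                    "characteristic": spec.name,
                    "control": f"{yes0} ({_pct(yes0 / n0)}%)",
                    "active": f"{yes1} ({_pct(yes1 / n1)}%)",
                    "p": _fmt_p(p1),
                }
            )
            succ = [int(v[leaf_labels == L].sum()) for L in labels]
            tot = [int((leaf_labels == L).sum()) for L in labels]
            # trend undefined for a single leaf (root-only tree)
            p2 = mantel_trend(succ, tot, scores).p if len(labels) > 1 else math.nan
            row = {"characteristic": spec.name}
            for L, s, t in zip(labels, succ, tot):
                row[f"leaf{L}"] = f"{s} ({_pct(s / t)}%)"
            row["p"] = _fmt_p(p2)
            rows2.append(row)
        else:
            a, b = v[arm == 0], v[arm == 1]
            p1 = wilcoxon_rank_sum(a, b)
            rows1.append(
                {
                    "characteristic": spec.name,
                    "control": _fmt_median_range(a),
                    "active": _fmt_median_range(b),
                    "p": _fmt_p(p1),
                }
            )
            if len(labels) < 2:
                p2 = math.nan
            elif len(np.unique(v)) == 1:
                p2 = 1.0  # constant covariate: no trend by convention
            else:
                sc = np.array([scores[labels.index(L)] for L in leaf_labels], float)
                p2 = linear_trend(v, sc).p
            row = {"characteristic": spec.name}
            for L in labels:
                row[f"leaf{L}"] = _fmt_median_range(v[leaf_labels == L])
            row["p"] = _fmt_p(p2)
            rows2.append(row)

    table1 = pd.DataFrame(rows1, columns=["characteristic", "control", "active", "p"])
    cols2 = ["characteristic"] + [f"leaf{L}" for L in labels] + ["p"]
    table2 = pd.DataFrame(rows2, columns=cols2)
    return table1, table2
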