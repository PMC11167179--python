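"""Group-comparison statistics used across the pipeline.

All tests are computed from their defining formulas (only distribution
functions come from scipy), so they can be cross-checked against independent
reference implementations:

* Welch's t (two groups, unequal variances, Satterthwaite df)
* Kruskal-Wallis H with tie correction, chi-square reference
* Pearson chi-square on contingency tables, no continuity correction
* Tukey HSD (Tukey-Kramer for unequal group sizes), studentized range
* Pearson correlation with the t-based two-sided p-value
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's two-sample t-test.

    Returns ``(t, df, p)`` where df is the Welch-Satterthwaite approximation
    and p is two-sided.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0:
        raise ValueError("both groups have zero variance")
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi-square with g-1 df.

    Degenerate case: if every observation is tied, H is 0 and p is 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    # tie correction factor
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    offset = 0
    h = 0.0
    for g in groups:
        r = ranks[offset : offset + g.size]
        h += r.sum() ** 2 / g.size
        offset += g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    if tie == 0.0:
        return 0.0, 1.0
    h /= tie
    p = float(sps.chi2.sf(h, len(groups) - 1))
    return float(h), p


def pearson_chi2(table) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c contingency table (no Yates correction)."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    if (expected <= 0).any():
        raise ValueError(
            "zero expected counts; merge sparse rows/columns before testing"
        )
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(chi2, df))
    return chi2, df, p


def tukey_hsd(values, groups) -> pd.DataFrame:
    """One-way ANOVA followed by Tukey's HSD on all group pairs.

    Uses the Tukey-Kramer standard error for unequal group sizes; adjusted
    p-values come from the studentized range distribution. Returns a frame
    with one row per pair: group_a, group_b, mean_diff, p_adj.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups).tolist())
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = {lab: values[groups == lab] for lab in labels}
    if any(s.size < 2 for s in samples.values()):
        raise ValueError("each group needs at least 2 observations")
    k = len(labels)
    n_total = values.size
    df_within = n_total - k
    sse = sum(((s - s.mean()) ** 2).sum() for s in samples.values())
    if sse == 0:
        raise ValueError("zero within-group variance everywhere")
    mse = sse / df_within
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = samples[labels[i]], samples[labels[j]]
            diff = a.mean() - b.mean()
            se = np.sqrt(mse / 2.0 * (1.0 / a.size + 1.0 / b.size))
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, df_within))
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "mean_diff": float(diff),
                    "q": float(q),
                    "p_adj": min(1.0, p),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class CorrelationResult:
    r: float
    r_squared: float
    p: float
    n: int
    significant: bool


def pearson_corr(x, y, alpha: float = 0.05, r2_threshold: float = 0.25) -> CorrelationResult:
    """Pearson r with the t-based two-sided p-value.

    ``significant`` is the conjunction used in the in-vivo analysis:
    p < alpha AND r^2 > r2_threshold.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the variables")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(xc.dot(yc) / np.sqrt(xc.dot(xc) * yc.dot(yc)))
    r = max(-1.0, min(1.0, r))
    n = x.size
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    r2 = r * r
    return CorrelationResult(r=r, r_squared=r2, p=p, n=n, significant=(p < alpha and r2 > r2_threshold))


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, rank-preserving)."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out
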