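"""Group-level statistical reporting for subject-day summaries.

Normality-gated omnibus tests (ANOVA / Kruskal-Wallis), Tukey HSD
post-hoc comparisons, Cohen's d effect sizes with qualitative bands, and
Pearson/Spearman correlations. All via standard statistical routines.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

ALPHA = 0.05

EFFECT_BANDS = (
    (1.0, "large"),
    (0.5, "medium"),
    (0.25, "small"),
    (0.0, "weak"),
)


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with the pooled (ddof=1) standard deviation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0.0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def effect_band(d: float) -> str:
    mag = abs(d)
    for lo, label in EFFECT_BANDS:
        if mag >= lo:
            return label
    return "weak"


def _is_normal(x: np.ndarray, alpha: float = ALPHA) -> bool:
    """Kolmogorov-Smirnov check against a fitted normal."""
    x = np.asarray(x, dtype=float)
    if x.size < 4 or x.std(ddof=1) == 0.0:
        return True
    z = (x - x.mean()) / x.std(ddof=1)
    return stats.kstest(z, "norm").pvalue >= alpha


def summarize_groups(
    table: pd.DataFrame,
    value_cols: list[str],
    group_col: str = "group",
    recovery_col: str | None = None,
    alpha: float = ALPHA,
) -> dict:
    """Compare ``value_cols`` across groups and report effects.

    Groups with fewer than 2 observations are excluded from testing (and
    noted). When every group passes the normality check, a one-way ANOVA
    is used, otherwise Kruskal-Wallis; significant omnibus tests get Tukey
    HSD post-hoc comparisons and pairwise Cohen's d. If ``recovery_col``
    is given, Spearman rank correlations of each measure with it are
    added (computed over rows with a recovery value).
    """
    report: dict = {"alpha": alpha, "measures": {}, "excluded_groups": {}}
    for col in value_cols:
        sub = table[[group_col, col]].dropna()
        groups = {g: v[col].to_numpy(dtype=float) for g, v in sub.groupby(group_col)}
        small = [g for g, v in groups.items() if v.size < 2]
        groups = {g: v for g, v in groups.items() if v.size >= 2}
        entry: dict = {
            "group_means": {g: float(v.mean()) for g, v in groups.items()},
            "group_sds": {g: float(v.std(ddof=1)) for g, v in groups.items()},
            "group_ns": {g: int(v.size) for g, v in groups.items()},
        }
        if small:
            report["excluded_groups"][col] = small
        if len(groups) >= 2:
            normal = all(_is_normal(v, alpha) for v in groups.values())
            if normal:
                stat, p = stats.f_oneway(*groups.values())
                entry["omnibus"] = {"test": "anova", "stat": float(stat), "p": float(p)}
            else:
                stat, p = stats.kruskal(*groups.values())
                entry["omnibus"] = {"test": "kruskal", "stat": float(stat), "p": float(p)}
            entry["pairwise"] = {}
            if p < alpha:
                flat = np.concatenate(list(groups.values()))
                labels = np.concatenate([[g] * v.size for g, v in groups.items()])
                tukey = pairwise_tukeyhsd(flat, labels, alpha=alpha)
                res = pd.DataFrame(
                    tukey.summary().data[1:], columns=tukey.summary().data[0]
                )
                for _, row in res.iterrows():
                    g1, g2 = str(row["group1"]), str(row["group2"])
                    d = cohens_d(groups[g1], groups[g2])
                    entry["pairwise"][f"{g1}-{g2}"] = {
                        "p_adj": float(row["p-adj"]),
                        "significant": bool(row["reject"]),
                        "cohens_d": d,
                        "effect_band": effect_band(d),
                    }
        report["measures"][col] = entry

    if recovery_col is not None and recovery_col in table.columns:
        report["recovery_correlations"] = {}
        paired = table.dropna(subset=[recovery_col])
        for col in value_cols:
            both = paired.dropna(subset=[col])
            if len(both) >= 3:
                rho, p = stats.spearmanr(both[col], both[recovery_col])
                report["recovery_correlations"][col] = {"rho": float(rho), "p": float(p)}
    return report


def pearson_agreement(x: np.ndarray, y: np.ndarray) -> dict:
    """Pearson correlation between two paired activity measures."""
    r, p = stats.pearsonr(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
    return {"r": float(r), "p": float(p)}
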