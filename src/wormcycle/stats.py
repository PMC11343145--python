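"""Group-comparison decision tree and Monte-Carlo power estimation.

The dispatch mirrors the standard physiology workflow: per-group IQR
outlier removal, Shapiro-Wilk normality and Brown-Forsythe (median-centered
Levene) equal-variance gates at alpha = 0.05, then

two groups
    Student t (normal, equal variance) / Welch t (normal, unequal
    variance) / Mann-Whitney rank-sum (non-normal); paired data use the
    paired t or Wilcoxon signed-rank on the differences.
three or more groups
    one-way ANOVA with Holm-Sidak pairwise post hocs, or Kruskal-Wallis
    with Dunn's rank post hocs.

Power (1 − β) is estimated by Monte-Carlo simulation for every branch:
datasets are drawn under the alternative, the chosen test is re-run, and
power is the rejection fraction with binomial standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "PowerEstimate",
    "iqr_outliers",
    "auto_compare_two",
    "auto_compare_many",
    "monte_carlo_power",
    "dunn_posthoc",
]

GATE_ALPHA = 0.05  # level of the normality and equal-variance gates


class PowerEstimate(NamedTuple):
    power: float
    se: float
    reps: int
    method: str


@dataclass
class StatResult:
    test_name: str
    statistic: float
    pvalue: float
    alpha: float
    group_summaries: list[dict]
    normality: dict[str, float]  # group label -> Shapiro-Wilk p
    normal: bool
    equal_variance_p: float | None
    equal_variance: bool | None
    posthoc: pd.DataFrame | None = None
    power: PowerEstimate | None = None
    n_removed_outliers: int = 0

    @property
    def significant(self) -> bool:
        return self.pvalue < self.alpha


def iqr_outliers(values: Sequence[float]) -> np.ndarray:
    """Boolean keep-mask from Tukey's IQR fences.

    Quartiles use linear interpolation between order statistics; values
    outside ``[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`` are flagged for removal.
    Below n = 4 no removal is attempted.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if np.any(np.isnan(x)):
        raise ValueError("values must be numeric and non-missing")
    if len(x) < 4:
        return np.ones(len(x), dtype=bool)
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return (x >= q1 - 1.5 * iqr) & (x <= q3 + 1.5 * iqr)


def _summary(label: str, x: np.ndarray) -> dict:
    return {
        "group": label,
        "n": int(len(x)),
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if len(x) > 1 else float("nan"),
        "sem": float(sps.sem(x)) if len(x) > 1 else float("nan"),
        "median": float(np.median(x)),
    }


def _shapiro_p(x: np.ndarray) -> float:
    if np.ptp(x) == 0.0:
        return 0.0  # a constant sample is treated as non-normal
    return float(sps.shapiro(x).pvalue)


def _brown_forsythe_p(*groups: np.ndarray) -> float:
    if all(np.ptp(g) == 0.0 for g in groups):
        return 1.0
    return float(sps.levene(*groups, center="median").pvalue)


def auto_compare_two(
    group_a: Sequence[float],
    group_b: Sequence[float],
    paired: bool = False,
    alpha: float = 0.05,
    labels: tuple[str, str] = ("A", "B"),
    remove_outliers: bool = True,
    power_reps: int = 0,
    seed: int | None = None,
) -> StatResult:
    """Two-group comparison with automatic test dispatch.

    Set ``power_reps > 0`` to append a Monte-Carlo power estimate for the
    chosen branch at the observed plug-in effect size.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if paired and len(a) != len(b):
        raise ValueError("paired comparison requires equal group lengths")
    removed = 0
    if remove_outliers:
        if paired:
            keep = iqr_outliers(a - b)
            removed = int((~keep).sum())
            a, b = a[keep], b[keep]
        else:
            ka, kb = iqr_outliers(a), iqr_outliers(b)
            removed = int((~ka).sum() + (~kb).sum())
            a, b = a[ka], b[kb]
    if min(len(a), len(b)) < 3:
        raise ValueError("each group needs n >= 3 after outlier removal")

    if paired:
        diff = a - b
        p_norm = {"diff": _shapiro_p(diff)}
        normal = p_norm["diff"] >= GATE_ALPHA
        p_var, eqvar = None, None
        if normal:
            name = "paired t"
            stat, p = sps.ttest_rel(a, b)
        else:
            name = "Wilcoxon signed-rank"
            if np.all(diff == 0):
                stat, p = 0.0, 1.0
            else:
                stat, p = sps.wilcoxon(a, b)
    else:
        p_norm = {labels[0]: _shapiro_p(a), labels[1]: _shapiro_p(b)}
        normal = all(p >= GATE_ALPHA for p in p_norm.values())
        p_var = _brown_forsythe_p(a, b)
        eqvar = p_var >= GATE_ALPHA
        if normal and eqvar:
            name = "Student t"
            stat, p = sps.ttest_ind(a, b, equal_var=True)
        elif normal:
            name = "Welch t"
            stat, p = sps.ttest_ind(a, b, equal_var=False)
        else:
            name = "Mann-Whitney rank-sum"
            stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    if np.isnan(p):  # identical constant groups
        stat, p = 0.0, 1.0

    result = StatResult(
        test_name=name,
        statistic=float(stat),
        pvalue=float(p),
        alpha=alpha,
        group_summaries=[_summary(labels[0], a), _summary(labels[1], b)],
        normality=p_norm,
        normal=bool(normal),
        equal_variance_p=p_var,
        equal_variance=eqvar,
        n_removed_outliers=removed,
    )
    if power_reps > 0:
        sd_pool = np.sqrt((np.var(a, ddof=1) + np.var(b, ddof=1)) / 2.0)
        d = 0.0 if sd_pool == 0 else (np.mean(a) - np.mean(b)) / sd_pool
        spec = {
            "Student t": "student_t",
            "Welch t": "welch_t",
            "Mann-Whitney rank-sum": "rank_sum",
            "paired t": "paired_t",
            "Wilcoxon signed-rank": "signed_rank",
        }[name]
        result.power = monte_carlo_power(
            spec, abs(float(d)), (len(a), len(b)), alpha=alpha,
            reps=power_reps, seed=seed,
        )
    return result


def dunn_posthoc(
    groups: Sequence[np.ndarray],
    labels: Sequence[str],
    adjust: str = "holm-sidak",
) -> pd.DataFrame:
    """Dunn's rank-based pairwise post-hoc test after Kruskal-Wallis.

    Z statistics compare mean ranks on the pooled tie-corrected ranking;
    two-sided p-values are adjusted across the pairwise family.
    """
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie = (counts**3 - counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie
    mean_ranks, ns = [], []
    offset = 0
    for g in groups:
        mean_ranks.append(ranks[offset : offset + len(g)].mean())
        ns.append(len(g))
        offset += len(g)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(var_base * (1.0 / ns[i] + 1.0 / ns[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append((labels[i], labels[j], float(z), float(p)))
    table = pd.DataFrame(rows, columns=["group_1", "group_2", "statistic", "p_raw"])
    reject, p_adj, *_ = multipletests(table["p_raw"], method=adjust)
    table["p_adj"] = p_adj
    table["reject"] = reject
    return table


def _holm_sidak_pairwise_t(
    groups: list[np.ndarray], labels: Sequence[str]
) -> pd.DataFrame:
    """Pairwise t-tests with the pooled ANOVA error term, Holm-Sidak adjusted."""
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    means = np.array([np.mean(g) for g in groups])
    df_err = int(ns.sum() - k)
    mse = sum((len(g) - 1) * np.var(g, ddof=1) for g in groups) / df_err
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(mse * (1.0 / ns[i] + 1.0 / ns[j]))
            t = (means[i] - means[j]) / se if se > 0 else 0.0
            p = 2.0 * sps.t.sf(abs(t), df_err)
            rows.append((labels[i], labels[j], float(t), float(p)))
    table = pd.DataFrame(rows, columns=["group_1", "group_2", "statistic", "p_raw"])
    reject, p_adj, *_ = multipletests(table["p_raw"], method="holm-sidak")
    table["p_adj"] = p_adj
    table["reject"] = reject
    return table


def auto_compare_many(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
    remove_outliers: bool = True,
) -> StatResult:
    """Multi-group comparison: ANOVA + Holm-Sidak or Kruskal-Wallis + Dunn."""
    if len(groups) < 3:
        raise ValueError("fewer than 3 groups: use auto_compare_two")
    labels = list(labels) if labels else [f"G{i}" for i in range(len(groups))]
    arrs = [np.asarray(g, dtype=float) for g in groups]
    removed = 0
    if remove_outliers:
        kept = [g[iqr_outliers(g)] for g in arrs]
        removed = sum(len(a) - len(k) for a, k in zip(arrs, kept))
        arrs = kept
    if any(len(g) < 3 for g in arrs):
        raise ValueError("each group needs n >= 3 after outlier removal")
    p_norm = {lab: _shapiro_p(g) for lab, g in zip(labels, arrs)}
    normal = all(p >= GATE_ALPHA for p in p_norm.values())
    p_var = _brown_forsythe_p(*arrs)
    eqvar = p_var >= GATE_ALPHA
    if normal and eqvar:
        name = "one-way ANOVA"
        stat, p = sps.f_oneway(*arrs)
        posthoc = _holm_sidak_pairwise_t(arrs, labels)
    else:
        name = "Kruskal-Wallis"
        stat, p = sps.kruskal(*arrs)
        posthoc = dunn_posthoc(arrs, labels)
    if np.isnan(p):
        stat, p = 0.0, 1.0
        posthoc[["p_raw", "p_adj"]] = 1.0
        posthoc["reject"] = False
    return StatResult(
        test_name=name,
        statistic=float(stat),
        pvalue=float(p),
        alpha=alpha,
        group_summaries=[_summary(lab, g) for lab, g in zip(labels, arrs)],
        normality=p_norm,
        normal=bool(normal),
        equal_variance_p=float(p_var),
        equal_variance=bool(eqvar),
        posthoc=posthoc,
        n_removed_outliers=removed,
    )


def _vectorized_pvalues(
    spec: str, a: np.ndarray, b: np.ndarray
) -> np.ndarray:
    if spec == "student_t":
        return sps.ttest_ind(a, b, axis=1, equal_var=True).pvalue
    if spec == "welch_t":
        return sps.ttest_ind(a, b, axis=1, equal_var=False).pvalue
    if spec == "paired_t":
        return sps.ttest_rel(a, b, axis=1).pvalue
    if spec == "rank_sum":
        return sps.mannwhitneyu(a, b, axis=1, alternative="two-sided").pvalue
    raise AssertionError(spec)


def monte_carlo_power(
    test_spec: str,
    effect_size: float,
    group_ns: tuple[int, int],
    alpha: float = 0.05,
    reps: int = 1000,
    seed: int | None = None,
) -> PowerEstimate:
    """Monte-Carlo power of a two-group test under a normal shift alternative.

    ``effect_size`` is the standardized mean difference (Cohen's d): groups
    are drawn as N(0, 1) and N(d, 1) at sizes ``group_ns``, the named test
    is run on each of ``reps`` replicate datasets, and power is the
    fraction rejecting at ``alpha``, with binomial standard error
    ``sqrt(p(1−p)/reps)``.  ``test_spec="auto"`` re-runs the full dispatch
    per replicate.
    """
    if reps < 100:
        raise ValueError("reps must be at least 100")
    n1, n2 = group_ns
    rng = np.random.default_rng(seed)
    known = {"student_t", "welch_t", "paired_t", "rank_sum", "signed_rank", "auto"}
    if test_spec not in known:
        raise ValueError(f"unknown test_spec {test_spec!r}")
    if test_spec in ("paired_t", "signed_rank") and n1 != n2:
        raise ValueError("paired designs need equal group sizes")
    if test_spec in ("student_t", "welch_t", "paired_t", "rank_sum"):
        a = rng.normal(0.0, 1.0, size=(reps, n1))
        b = rng.normal(effect_size, 1.0, size=(reps, n2))
        pvals = _vectorized_pvalues(test_spec, a, b)
        rejections = int((pvals < alpha).sum())
    else:
        rejections = 0
        for _ in range(reps):
            a = rng.normal(0.0, 1.0, size=n1)
            b = rng.normal(effect_size, 1.0, size=n2)
            if test_spec == "signed_rank":
                d = a - b
                pv = 1.0 if np.all(d == 0) else float(sps.wilcoxon(a, b).pvalue)
            else:  # auto
                pv = auto_compare_two(
                    a, b, alpha=alpha, remove_outliers=False
                ).pvalue
            rejections += pv < alpha
    power = rejections / reps
    se = float(np.sqrt(power * (1.0 - power) / reps))
    return PowerEstimate(float(power), se, reps, f"monte-carlo:{test_spec}")
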