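"""Group-difference testing and ROC analysis for zone and ratio markers.

Routing follows the conventional normality gate: Shapiro-Wilk per group at
alpha 0.05; any rejection sends the variable to Kruskal-Wallis with Dunn's
post-hoc test (Bonferroni-adjusted), otherwise one-way ANOVA with Tukey's
HSD. Sensitivity and specificity along the ROC sweep carry Wilson score
intervals; the AUC standard error and its test against 0.5 use the
Hanley-McNeil normal approximation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

Polarity = Literal["higher_is_positive", "lower_is_positive"]


@dataclass
class PairwiseComparison:
    pair: tuple[str, str]
    p_adjusted: float
    adjustment: str  # "dunn_bonferroni" or "tukey_hsd"


@dataclass
class GroupTestResult:
    variable: str
    global_test: str  # "kruskal_wallis" or "anova"
    global_p: float
    pairwise: list[PairwiseComparison]
    medians: dict[str, float]
    iqrs: dict[str, float]


@dataclass(frozen=True)
class BinomialCI:
    """Wilson score interval for a binomial proportion."""

    estimate: float
    lower: float
    upper: float
    n: int


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: list[BinomialCI]
    specificity: list[BinomialCI]
    auc: float
    auc_se: float
    auc_ci_95: tuple[float, float]
    p_value: float  # vs AUC = 0.5
    polarity: Polarity

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": [c.estimate for c in self.sensitivity],
                "sens_lo": [c.lower for c in self.sensitivity],
                "sens_hi": [c.upper for c in self.sensitivity],
                "specificity": [c.estimate for c in self.specificity],
                "spec_lo": [c.lower for c in self.specificity],
                "spec_hi": [c.upper for c in self.specificity],
            }
        )


def significance_stars(p: float) -> str:
    """Figure-legend star mapping: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p < cut:
            return stars
    return "ns"


def wilson_interval(successes: int, n: int, confidence: float = 0.95) -> BinomialCI:
    """Closed-form Wilson score interval.

    center = (p + z^2/2n) / (1 + z^2/n), half-width
    z/(1 + z^2/n) * sqrt(p(1-p)/n + z^2/4n^2).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError(f"successes {successes} outside [0, {n}]")
    z = float(sps.norm.ppf(0.5 + confidence / 2.0))
    p = successes / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = (z / denom) * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
    # analytically the lower bound is exactly 0 at k=0 and the upper exactly
    # 1 at k=n; enforce that against floating-point residue
    lower = 0.0 if successes == 0 else float(max(0.0, center - half))
    upper = 1.0 if successes == n else float(min(1.0, center + half))
    return BinomialCI(estimate=p, lower=min(lower, p), upper=max(upper, p), n=n)


def _dunn_pairwise(samples: dict[str, np.ndarray]) -> list[PairwiseComparison]:
    """Dunn's rank-sum z test with tie correction, Bonferroni-adjusted."""
    groups = list(samples)
    pooled = np.concatenate([samples[g] for g in groups])
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    # tie correction sum(t^3 - t) over tied groups
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    rank_means: dict[str, float] = {}
    start = 0
    for g in groups:
        size = samples[g].size
        rank_means[g] = float(np.mean(ranks[start : start + size]))
        start += size
    variance_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    n_comparisons = len(groups) * (len(groups) - 1) // 2
    out = []
    for a, b in itertools.combinations(groups, 2):
        se = np.sqrt(variance_base * (1.0 / samples[a].size + 1.0 / samples[b].size))
        if se == 0:
            p_raw = 1.0
        else:
            z = (rank_means[a] - rank_means[b]) / se
            p_raw = float(2.0 * sps.norm.sf(abs(z)))
        out.append(
            PairwiseComparison(
                pair=(a, b),
                p_adjusted=min(1.0, p_raw * n_comparisons),
                adjustment="dunn_bonferroni",
            )
        )
    return out


def test_group_differences(
    table: pd.DataFrame,
    variable: str,
    mode: Literal["auto", "nonparametric", "parametric"] = "auto",
    alpha_normality: float = 0.05,
) -> GroupTestResult:
    """Global and pairwise group-difference tests for one feature column.

    ``table`` needs the feature column and a ``group`` column. Medians and
    interquartile ranges are always reported.
    """
    groups = {
        str(g): sub[variable].to_numpy(dtype=float)
        for g, sub in table.groupby("group", observed=True)
    }
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, values in groups.items():
        if values.size < 3:
            raise ValueError(f"group {g!r} has fewer than 3 observations")

    if mode == "auto":
        nonparametric = False
        for g, values in groups.items():
            if np.ptp(values) == 0:  # Shapiro undefined on constant data
                nonparametric = True
                continue
            if sps.shapiro(values).pvalue < alpha_normality:
                nonparametric = True
    else:
        nonparametric = mode == "nonparametric"

    samples = list(groups.values())
    if np.ptp(np.concatenate(samples)) == 0:  # no variation anywhere
        global_p, global_test = 1.0, "kruskal_wallis" if nonparametric else "anova"
        pairwise = [
            PairwiseComparison(pair=(a, b), p_adjusted=1.0,
                               adjustment="dunn_bonferroni" if nonparametric else "tukey_hsd")
            for a, b in itertools.combinations(groups, 2)
        ]
    elif nonparametric:
        global_test = "kruskal_wallis"
        global_p = float(sps.kruskal(*samples).pvalue)
        pairwise = _dunn_pairwise(groups)
    else:
        global_test = "anova"
        global_p = float(sps.f_oneway(*samples).pvalue)
        tukey = sps.tukey_hsd(*samples)
        names = list(groups)
        pairwise = [
            PairwiseComparison(
                pair=(names[i], names[j]),
                p_adjusted=float(tukey.pvalue[i, j]),
                adjustment="tukey_hsd",
            )
            for i, j in itertools.combinations(range(len(names)), 2)
        ]
    medians = {g: float(np.median(v)) for g, v in groups.items()}
    iqrs = {g: float(sps.iqr(v)) for g, v in groups.items()}
    return GroupTestResult(
        variable=variable,
        global_test=global_test,
        global_p=global_p,
        pairwise=pairwise,
        medians=medians,
        iqrs=iqrs,
    )


def roc_analysis(
    scores: Sequence[float] | np.ndarray,
    labels: Sequence[int] | np.ndarray,
    polarity: Polarity = "higher_is_positive",
    confidence: float = 0.95,
) -> RocResult:
    """ROC threshold sweep with Wilson intervals and Hanley-McNeil AUC error.

    ``labels`` are 0/1 with 1 the positive (disease) class. The AUC is the
    trapezoidal area, identical to the Mann-Whitney statistic with ties
    counted half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.size != labels.size:
        raise ValueError("scores and labels differ in length")
    if np.isnan(scores).any():
        raise ValueError("missing scores")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    oriented = scores if polarity == "higher_is_positive" else -scores

    # Mann-Whitney AUC with ties counted half (equals trapezoid over the sweep)
    ranks = sps.rankdata(oriented)
    auc = float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))

    thresholds = np.unique(oriented)
    sens_cis, spec_cis = [], []
    for t in thresholds:
        predicted_pos = oriented >= t
        tp = int(np.sum(predicted_pos & (labels == 1)))
        tn = int(np.sum(~predicted_pos & (labels == 0)))
        sens_cis.append(wilson_interval(tp, n_pos, confidence))
        spec_cis.append(wilson_interval(tn, n_neg, confidence))

    # Hanley-McNeil standard error of the AUC
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc * auc)
        + (n_neg - 1) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    z_conf = float(sps.norm.ppf(0.5 + confidence / 2.0))
    ci = (max(0.0, auc - z_conf * se), min(1.0, auc + z_conf * se))
    # Hanley-McNeil variance at the null AUC = 0.5 (Q1 = Q2 = 1/3), which
    # reduces to the Mann-Whitney null variance (n_pos + n_neg + 1)/(12 n1 n2)
    var0 = (0.25 + (n_pos + n_neg - 2) * (1.0 / 3.0 - 0.25)) / (n_pos * n_neg)
    p_value = float(2.0 * sps.norm.sf(abs(auc - 0.5) / np.sqrt(var0)))
    return RocResult(
        thresholds=thresholds if polarity == "higher_is_positive" else -thresholds,
        sensitivity=sens_cis,
        specificity=spec_cis,
        auc=auc,
        auc_se=se,
        auc_ci_95=ci,
        p_value=p_value,
        polarity=polarity,
    )


#: ROC polarity per spectral marker: Z4a/Z5 rises and Z6/Z7 falls in disease.
MARKER_POLARITY: dict[str, Polarity] = {
    "Z4a_over_Z5": "higher_is_positive",
    "Z6_over_Z7": "lower_is_positive",
}


def marker_roc_table(table: pd.DataFrame, positive_group: str, control_group: str = "control") -> pd.DataFrame:
    """AUC summary rows (AUC, SE, 95% CI, p) for both ratio markers on one
    group-vs-control comparison."""
    rows = []
    sub = table[table["group"].isin([control_group, positive_group])]
    labels = (sub["group"] == positive_group).astype(int).to_numpy()
    for marker, polarity in MARKER_POLARITY.items():
        roc = roc_analysis(sub[marker].to_numpy(dtype=float), labels, polarity)
        rows.append(
            {
                "marker": marker,
                "comparison": f"{control_group}_vs_{positive_group}",
                "auc": roc.auc,
                "auc_se": roc.auc_se,
                "ci_lower": roc.auc_ci_95[0],
                "ci_upper": roc.auc_ci_95[1],
                "p_value": roc.p_value,
                "polarity": polarity,
            }
        )
    return pd.DataFrame(rows)
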