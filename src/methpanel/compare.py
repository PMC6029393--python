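"""Paired DRE-vs-FV analyses and group comparisons.

Sixty-ish patients contribute both a post-DRE and a first-void urine sample;
paired analyses ask whether the two collection routes recover marker
methylation equally well and whether the two 6-of-19 tests disagree:

* per-marker paired t-test on within-patient level differences (DRE - FV);
* exact binomial (McNemar-style) comparison of two binary tests conditioned
  on discordant pairs, two-sided by doubling the smaller tail (p = 1 when the
  discordants balance);
* concordance — the fraction of patients with identical calls.

Group comparisons relate methylation burden to biopsy outcome and CAPRA risk
group (0 = negative biopsy, 1 = CAPRA 1-2, 2 = CAPRA >= 3): Wilcoxon
rank-sum on scores, Pearson correlation with a Fisher-z CI, and box-plot
summaries (type-7 linear-interpolation quantiles).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedMarkerDiff",
    "PairedTestComparison",
    "paired_marker_difference",
    "exact_binomial_p",
    "compare_paired_tests",
    "concordance",
    "wilcoxon_rank_sum",
    "fisher_z_ci",
    "pearson_with_ci",
    "group_summaries",
]


@dataclass(frozen=True)
class PairedMarkerDiff:
    marker_id: str
    n_pairs: int
    mean_difference: float
    ci_low: float
    ci_high: float
    p_value: float
    degenerate: bool = False  # zero variance of the differences


def paired_marker_difference(
    dre_levels: Sequence[float],
    fv_levels: Sequence[float],
    marker_id: str = "",
    alpha: float = 0.05,
) -> PairedMarkerDiff:
    """Within-patient mean difference (DRE - FV) with paired t-test and t CI.

    Inputs are aligned per-patient level vectors for one marker.  With zero
    variance of the differences the CI collapses to a point and the result is
    flagged degenerate (p = 1 if the common difference is 0, else p = 0).
    """
    a = np.asarray(dre_levels, dtype=float)
    b = np.asarray(fv_levels, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired level vectors must be 1-d and equally long")
    if a.size < 2:
        raise ValueError("need at least 2 complete pairs")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    n = d.size
    if sd <= 1e-10 * max(1.0, abs(mean)):  # constant differences up to roundoff
        return PairedMarkerDiff(
            marker_id, n, mean, mean, mean, 1.0 if mean == 0 else 0.0, degenerate=True
        )
    se = sd / np.sqrt(n)
    tcrit = stats.t.ppf(1 - alpha / 2, df=n - 1)
    t = mean / se
    p = float(2 * stats.t.sf(abs(t), df=n - 1))
    return PairedMarkerDiff(marker_id, n, mean, mean - tcrit * se, mean + tcrit * se, p)


def exact_binomial_p(b: int, c: int) -> float:
    """Exact two-sided test that discordant pairs split evenly.

    ``b`` and ``c`` count the two kinds of discordant pairs.  Under the null
    that both tests err alike, b ~ Binomial(b + c, 1/2); the two-sided p
    doubles the smaller tail, capped at 1 (so p = 1 when b = c or b + c = 0).
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return 1.0
    tail = stats.binom.cdf(min(b, c), n, 0.5)
    return float(min(1.0, 2 * tail))


@dataclass(frozen=True)
class PairedTestComparison:
    n_pairs: int
    n_cases: int
    n_controls: int
    sensitivity_a: float
    sensitivity_b: float
    diff_sensitivity: float
    sens_ci: tuple[float, float]
    p_sensitivity: float
    specificity_a: float
    specificity_b: float
    diff_specificity: float
    spec_ci: tuple[float, float]
    p_specificity: float
    concordance: float


def _paired_proportion_diff(
    a: np.ndarray, b: np.ndarray, alpha: float
) -> tuple[float, float, float, tuple[float, float], float]:
    """Difference in paired proportions with Wald CI and exact binomial p."""
    n = a.size
    pa, pb = float(a.mean()), float(b.mean())
    disc_ab = int((a & ~b).sum())  # a positive where b is not
    disc_ba = int((~a & b).sum())
    diff = pa - pb
    var = (disc_ab + disc_ba - (disc_ab - disc_ba) ** 2 / n) / n**2
    half = stats.norm.ppf(1 - alpha / 2) * np.sqrt(max(var, 0.0))
    return pa, pb, diff, (diff - half, diff + half), exact_binomial_p(disc_ab, disc_ba)


def compare_paired_tests(
    calls_a: pd.Series,
    calls_b: pd.Series,
    labels: pd.Series,
    alpha: float = 0.05,
) -> PairedTestComparison:
    """Compare two binary tests evaluated on the same patients.

    Sensitivity differences are computed among cases and specificity
    differences among controls; each difference gets a Wald CI with paired
    variance and an exact binomial p conditioned on the discordant pairs.
    """
    idx_a, idx_b = set(calls_a.index), set(calls_b.index)
    if idx_a != idx_b or idx_a != set(labels.index):
        raise ValueError(
            "calls_a, calls_b and labels must cover the same patients; "
            f"symmetric differences: a^b={sorted(idx_a ^ idx_b)}, "
            f"a^labels={sorted(idx_a ^ set(labels.index))}"
        )
    a = calls_a.astype(bool)
    b = calls_b.reindex(a.index).astype(bool)
    y = labels.reindex(a.index).astype(bool)
    if not y.any() or y.all():
        raise ValueError("need both cases and controls among the paired patients")

    sa, sb, dsens, sens_ci, p_sens = _paired_proportion_diff(
        a[y].to_numpy(), b[y].to_numpy(), alpha
    )
    # specificity = proportion of negative calls among controls
    fa, fb, dspec, spec_ci, p_spec = _paired_proportion_diff(
        (~a[~y]).to_numpy(), (~b[~y]).to_numpy(), alpha
    )
    return PairedTestComparison(
        n_pairs=len(a),
        n_cases=int(y.sum()),
        n_controls=int((~y).sum()),
        sensitivity_a=sa,
        sensitivity_b=sb,
        diff_sensitivity=dsens,
        sens_ci=sens_ci,
        p_sensitivity=p_sens,
        specificity_a=fa,
        specificity_b=fb,
        diff_specificity=dspec,
        spec_ci=spec_ci,
        p_specificity=p_spec,
        concordance=float((a == b).mean()),
    )


def concordance(
    calls_a: pd.Series, calls_b: pd.Series, labels: pd.Series | None = None
) -> dict[str, float]:
    """Fraction of patients with identical calls (and, with labels, the
    fraction where both tests also agree with the biopsy)."""
    if set(calls_a.index) != set(calls_b.index):
        raise ValueError(
            "calls cover different patients: "
            f"{sorted(set(calls_a.index) ^ set(calls_b.index))}"
        )
    a = calls_a.astype(bool)
    b = calls_b.reindex(a.index).astype(bool)
    out = {"pairwise": float((a == b).mean())}
    if labels is not None:
        y = labels.reindex(a.index).astype(bool)
        out["three_way"] = float(((a == b) & (a == y)).mean())
    return out


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 20
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank sum of x, p).

    Uses the exact null distribution when the combined sample size is at most
    ``exact_max_n`` and there are no ties across the pooled data; otherwise a
    normal approximation with midranks, tie-corrected variance and continuity
    correction.
    """
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    n1, n2 = a.size, b.size
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    if not ties and n1 + n2 <= exact_max_n:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return w, float(res.pvalue)
    u = w - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / ((n1 + n2) * (n1 + n2 - 1))
    sigma2 = n1 * n2 / 12 * (n1 + n2 + 1 - tie_term)
    if sigma2 == 0:
        return w, 1.0
    z = max(abs(u - mu) - 0.5, 0.0) / np.sqrt(sigma2)
    return w, float(min(1.0, 2 * stats.norm.sf(z)))


def fisher_z_ci(r: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Fisher-z CI for a Pearson correlation: tanh(atanh r +/- z / sqrt(n-3))."""
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    if n < 4:
        raise ValueError("need n >= 4 for a Fisher-z interval")
    if abs(r) == 1.0:
        return (r, r)
    z = np.arctanh(r)
    half = stats.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def pearson_with_ci(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> tuple[float, float, float, float]:
    """Pearson r with Fisher-z CI and t-test p (n - 2 df): (r, low, high, p)."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.size != b.size or a.size < 4:
        raise ValueError("need equal-length samples with n >= 4")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(a, b)
    r = float(res.statistic)
    if abs(r) > 1 - 1e-12:  # numerically perfect correlation: degenerate CI
        r = math.copysign(1.0, r)
    low, high = fisher_z_ci(r, a.size, alpha)
    return r, low, high, float(res.pvalue)


def group_summaries(
    profiles: pd.DataFrame,
    groups: pd.Series,
    statistics: Sequence[str] = ("n_positive", "avg_methylation"),
) -> pd.DataFrame:
    """Box-plot summaries of sample scores per risk group and sample type.

    ``groups`` maps patient_id -> group code (0 = negative biopsy, 1 = CAPRA
    1-2, 2 = CAPRA >= 3).  Quantiles use linear interpolation (type 7).
    Empty groups are simply absent from the output.
    """
    rows = []
    for st, grp in profiles.groupby(level="sample_type", sort=True):
        scores = grp.droplevel("sample_type")
        g = groups.reindex(scores.index)
        for stat in statistics:
            for code, sub in scores.groupby(g):
                v = sub[stat].to_numpy(dtype=float)
                if v.size == 0:
                    continue
                q1, med, q3 = np.percentile(v, [25, 50, 75])
                rows.append(
                    {
                        "sample_type": st,
                        "statistic": stat,
                        "group": code,
                        "n": v.size,
                        "min": v.min(),
                        "q1": q1,
                        "median": med,
                        "mean": v.mean(),
                        "q3": q3,
                        "max": v.max(),
                    }
                )
    return pd.DataFrame(rows)
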