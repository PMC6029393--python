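"""Diagnostic operating characteristics with confidence intervals.

Biopsy outcome is the reference standard: biopsy-positive patients are cases,
biopsy-negative patients are controls.  For a binary test,

* sensitivity = TP / (TP + FN)   (among cases)
* specificity = TN / (TN + FP)   (among controls)
* PPV = TP / (TP + FP),  NPV = TN / (TN + FN)

Zero-denominator metrics are reported as explicitly undefined (``None`` with a
reason code), never as 0.  Binomial CIs default to the Wilson score interval;
normal (Wald), Clopper-Pearson, and a seeded percentile bootstrap are
available.  Report tables round to 2 decimal places with half-up rounding;
machine-readable outputs keep full precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .panel import PanelDefinition

__all__ = [
    "ConfusionCounts",
    "MetricEstimate",
    "DiagnosticRow",
    "confusion_counts",
    "proportion_ci",
    "diagnostic_metrics",
    "assay_performance_table",
    "threshold_sweep",
    "round_half_up",
]

CI_METHODS = ("wilson", "normal", "clopper-pearson", "bootstrap")
_STATSMODELS_METHOD = {"wilson": "wilson", "normal": "normal", "clopper-pearson": "beta"}


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), as used in report tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.tn + self.fp

    @property
    def n(self) -> int:
        return self.n_cases + self.n_controls


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion with its CI, or an explicit undefined marker."""

    value: float | None
    ci_low: float | None = None
    ci_high: float | None = None
    undefined_reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.value is not None


@dataclass(frozen=True)
class DiagnosticRow:
    label: str
    sample_type: str
    counts: ConfusionCounts
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    ci_method: str = "wilson"

    def to_dict(self, ndigits: int | None = None) -> dict:
        def fmt(v: float | None) -> float | None:
            if v is None:
                return None
            return round_half_up(v, ndigits) if ndigits is not None else v

        out: dict = {
            "label": self.label,
            "sample_type": self.sample_type,
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "tn": self.counts.tn,
            "fn": self.counts.fn,
            "ci_method": self.ci_method,
        }
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            m: MetricEstimate = getattr(self, name)
            out[name] = fmt(m.value)
            out[f"{name}_ci_low"] = fmt(m.ci_low)
            out[f"{name}_ci_high"] = fmt(m.ci_high)
        return out


def confusion_counts(calls: pd.Series, labels: pd.Series) -> ConfusionCounts:
    """Cross-tabulate per-patient binary test calls against biopsy labels.

    Both series are indexed by patient id; the index sets must match exactly.
    """
    calls_idx, labels_idx = set(calls.index), set(labels.index)
    if calls_idx != labels_idx:
        raise ValueError(
            "calls and labels cover different patients; symmetric difference: "
            f"{sorted(calls_idx ^ labels_idx)}"
        )
    c = calls.astype(bool)
    y = labels.reindex(calls.index).astype(bool)
    return ConfusionCounts(
        tp=int((c & y).sum()),
        fp=int((c & ~y).sum()),
        tn=int((~c & ~y).sum()),
        fn=int((~c & y).sum()),
    )


def proportion_ci(
    successes: int,
    n: int,
    method: str = "wilson",
    alpha: float = 0.05,
    seed: int | None = None,
    n_boot: int = 2000,
) -> tuple[float, float]:
    """Two-sided (1 - alpha) CI for a binomial proportion, clipped to [0, 1]."""
    if n < 1:
        raise ValueError("n must be >= 1 (undefined metric)")
    if not 0 <= successes <= n:
        raise ValueError(f"need 0 <= successes <= n, got {successes}/{n}")
    if method in _STATSMODELS_METHOD:
        low, high = proportion_confint(successes, n, alpha=alpha, method=_STATSMODELS_METHOD[method])
        return (float(np.clip(low, 0.0, 1.0)), float(np.clip(high, 0.0, 1.0)))
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        draws = rng.binomial(n, successes / n, size=n_boot) / n
        low, high = np.quantile(draws, [alpha / 2, 1 - alpha / 2])
        # percentile interval; widen degenerate endpoints to include the estimate
        p = successes / n
        return (float(min(low, p)), float(max(high, p)))
    raise ValueError(f"unknown CI method {method!r}; expected one of {CI_METHODS}")


def _estimate(
    successes: int,
    n: int,
    method: str,
    alpha: float,
    seed: int | None,
    reason_if_undefined: str,
) -> MetricEstimate:
    if n == 0:
        return MetricEstimate(None, undefined_reason=reason_if_undefined)
    low, high = proportion_ci(successes, n, method=method, alpha=alpha, seed=seed)
    return MetricEstimate(successes / n, low, high)


def diagnostic_metrics(
    counts: ConfusionCounts,
    ci_method: str = "wilson",
    alpha: float = 0.05,
    seed: int | None = None,
    label: str = "",
    sample_type: str = "",
) -> DiagnosticRow:
    """All four operating characteristics with CIs for one 2x2 table."""
    if ci_method not in CI_METHODS:
        raise ValueError(f"unknown CI method {ci_method!r}")
    return DiagnosticRow(
        label=label,
        sample_type=sample_type,
        counts=counts,
        sensitivity=_estimate(counts.tp, counts.n_cases, ci_method, alpha, seed, "no cases"),
        specificity=_estimate(counts.tn, counts.n_controls, ci_method, alpha, seed, "no controls"),
        ppv=_estimate(counts.tp, counts.tp + counts.fp, ci_method, alpha, seed, "no positive calls"),
        npv=_estimate(counts.tn, counts.tn + counts.fn, ci_method, alpha, seed, "no negative calls"),
        ci_method=ci_method,
    )


def _rows_to_frame(rows: list[DiagnosticRow], ndigits: int | None = None) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict(ndigits) for r in rows])


def assay_performance_table(
    levels: pd.DataFrame,
    panel: PanelDefinition,
    labels: pd.Series,
    ci_method: str = "wilson",
    alpha: float = 0.05,
    seed: int | None = None,
    as_frame: bool = True,
) -> pd.DataFrame | list[DiagnosticRow]:
    """Per-assay operating characteristics, stratified by sample type.

    Positivity is level > 0 per assay.  For dual-assay markers an additional
    "<marker> Comb." row evaluates the merged (either-assay) status, which by
    the union rule can only gain sensitivity and lose specificity relative to
    each individual assay.
    """
    wide = levels.pivot_table(
        index=["patient_id", "sample_type"], columns="assay_id", values="level"
    )
    rows: list[DiagnosticRow] = []
    for st, grp in wide.groupby(level="sample_type", sort=True):
        pos = (grp > 0).droplevel("sample_type")
        y = labels.loc[pos.index]
        for assay in panel.assay_ids:
            counts = confusion_counts(pos[assay], y)
            rows.append(
                diagnostic_metrics(counts, ci_method, alpha, seed, label=assay, sample_type=st)
            )
        for marker in panel.dual_assay_markers:
            union = pos[list(panel.assays_for(marker))].any(axis=1)
            counts = confusion_counts(union, y)
            rows.append(
                diagnostic_metrics(
                    counts, ci_method, alpha, seed, label=f"{marker} Comb.", sample_type=st
                )
            )
    return _rows_to_frame(rows) if as_frame else rows


def threshold_sweep(
    profiles: pd.DataFrame,
    labels: pd.Series,
    thresholds: Iterable[int] = range(1, 20),
    ci_method: str = "wilson",
    alpha: float = 0.05,
    seed: int | None = None,
    as_frame: bool = True,
    n_markers: int = 19,
) -> pd.DataFrame | list[DiagnosticRow]:
    """Operating characteristics of the n-of-19 count score at each threshold.

    ``profiles`` is the frame from :func:`methpanel.scoring.profile_table`
    (indexed by patient_id, sample_type, with an ``n_positive`` column).
    Sensitivity is non-increasing and specificity non-decreasing in the
    threshold by construction of the >= rule.
    """
    thresholds = sorted(int(t) for t in thresholds)
    if any(t < 1 for t in thresholds):
        raise ValueError("thresholds must be >= 1")
    rows: list[DiagnosticRow] = []
    for st, grp in profiles.groupby(level="sample_type", sort=True):
        counts_by_patient = grp["n_positive"].droplevel("sample_type")
        y = labels.loc[counts_by_patient.index]
        for t in thresholds:
            calls = counts_by_patient >= t
            rows.append(
                diagnostic_metrics(
                    confusion_counts(calls, y),
                    ci_method,
                    alpha,
                    seed,
                    label=f">= {t} of {n_markers}",
                    sample_type=st,
                )
            )
    return _rows_to_frame(rows) if as_frame else rows
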