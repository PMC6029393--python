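"""Re-analysis of the original study cohort from its distributed marker table.

The clinical study behind the default panel distributes its per-patient
marker data as a supplementary spreadsheet (transformed 0-15 levels per assay
per sample, plus biopsy outcome); there is no public accession.  This module
loads such a table once the user has obtained it and re-runs the headline
analyses: n-of-19 operating characteristics, score medians, ROC AUCs, and the
paired DRE/FV comparison.

Expected input: a spreadsheet or delimited table with one row per sample and
columns ``patient_id``, ``sample_type`` (DRE/FV), ``biopsy`` (0/1), and one
column per assay holding the transformed level (0 = no amplification).  Place
it at ``data/study_marker_levels.tsv`` relative to the working directory, or
pass an explicit path.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .diagnostics import diagnostic_metrics, confusion_counts
from .compare import compare_paired_tests
from .panel import PanelDefinition, default_panel
from .roc import empirical_auc
from .scoring import profile_table

__all__ = ["DEFAULT_MARKER_DATA_PATH", "load_marker_table", "reproduce_study"]

DEFAULT_MARKER_DATA_PATH = Path("data/study_marker_levels.tsv")


def load_marker_table(
    path: str | Path = DEFAULT_MARKER_DATA_PATH, panel: PanelDefinition | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Load the study's per-patient marker table -> (long levels, biopsy labels).

    Accepts TSV/CSV or XLSX.  Raises ``FileNotFoundError`` with guidance when
    the table has not been obtained.
    """
    panel = panel or default_panel()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"study marker table not found at {path}; the original per-patient "
            "marker data is distributed as a supplementary spreadsheet with the "
            "study (no public accession) and must be obtained and converted to "
            "a table with columns patient_id, sample_type, biopsy, and one "
            "column per assay"
        )
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).strip() for c in df.columns]
    required = {"patient_id", "sample_type", "biopsy"}
    if not required <= set(df.columns):
        raise ValueError(f"marker table lacks required columns {sorted(required - set(df.columns))}")
    assay_cols = [c for c in df.columns if c in set(panel.assay_ids) | set(panel.aliases)]
    if len(assay_cols) < panel.n_assays:
        raise ValueError(
            f"marker table has {len(assay_cols)} recognizable assay columns; "
            f"expected {panel.n_assays}"
        )
    long = df.melt(
        id_vars=["patient_id", "sample_type"],
        value_vars=assay_cols,
        var_name="assay_id",
        value_name="level",
    )
    long["patient_id"] = long["patient_id"].astype(str)
    long["sample_type"] = long["sample_type"].astype(str).str.upper()
    long["assay_id"] = long["assay_id"].map(panel.canonical_assay_id)
    long["level"] = long["level"].fillna(0.0).astype(float)
    labels = (
        df.assign(patient_id=df["patient_id"].astype(str))
        .drop_duplicates("patient_id")
        .set_index("patient_id")["biopsy"]
        .astype(bool)
    )
    return long, labels


def reproduce_study(
    path: str | Path = DEFAULT_MARKER_DATA_PATH,
    panel: PanelDefinition | None = None,
    threshold: int = 6,
) -> dict:
    """Recompute the headline study results from the per-patient marker table.

    Returns a dict with, per sample type: sensitivity/specificity at the
    n-of-19 threshold, case/control medians of the marker count, and AUCs of
    the count and average-methylation scores; plus the paired FV-vs-DRE
    sensitivity difference and its exact binomial p.
    """
    panel = panel or default_panel()
    levels, labels = load_marker_table(path, panel)
    profiles = profile_table(levels, panel, threshold=threshold)
    out: dict = {}
    by_type = {}
    for st, grp in profiles.groupby(level="sample_type"):
        scores = grp.droplevel("sample_type")
        by_type[st] = scores
        y = labels.loc[scores.index]
        row = diagnostic_metrics(
            confusion_counts(scores["test_positive"], y), label=f">= {threshold}", sample_type=st
        )
        out[st] = {
            "sensitivity": row.sensitivity.value,
            "specificity": row.specificity.value,
            "median_n_positive_cases": float(scores.loc[y, "n_positive"].median()),
            "median_n_positive_controls": float(scores.loc[~y, "n_positive"].median()),
            "auc_n_positive": empirical_auc(scores["n_positive"], y),
            "auc_avg_methylation": empirical_auc(scores["avg_methylation"], y),
        }
    if {"DRE", "FV"} <= set(by_type):
        paired = sorted(set(by_type["DRE"].index) & set(by_type["FV"].index))
        res = compare_paired_tests(
            by_type["FV"]["test_positive"].loc[paired],
            by_type["DRE"]["test_positive"].loc[paired],
            labels.loc[paired],
        )
        out["paired"] = {
            "n_pairs": res.n_pairs,
            "diff_sensitivity_fv_minus_dre": res.diff_sensitivity,
            "p_sensitivity": res.p_sensitivity,
            "diff_specificity": res.diff_specificity,
            "p_specificity": res.p_specificity,
            "concordance": res.concordance,
        }
    return out
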