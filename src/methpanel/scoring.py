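"""Marker-level scores: dual-assay merge, n-of-19 count, average methylation.

Markers probed by two assays (different portions of the same CpG island) are
merged by taking the highest level detected by either assay: the union rule —
a marker is positive iff at least one of its assays amplified.  Because
genomic fragments of one island are not recovered from urine DNA in equal
copy numbers, the strongest detection best reflects the island's methylation
status.

Two sample-level scores summarize a profile:

* ``n_positive`` — the number of markers with level > 0 (the n-of-19 score);
* ``avg_methylation`` — the arithmetic mean of the merged marker levels.

A sample is called test-positive when ``n_positive`` reaches a threshold
(default 6 of 19, chosen in the source study for a target specificity of 70%).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .panel import PanelDefinition

__all__ = [
    "DEFAULT_THRESHOLD",
    "merge_dual_assays",
    "count_positive_markers",
    "average_methylation",
    "classify_sample",
    "profile_table",
]

DEFAULT_THRESHOLD = 6


def merge_dual_assays(
    assay_levels: Mapping[str, float], panel: PanelDefinition
) -> dict[str, float]:
    """Merge per-assay levels into per-marker levels (max over a marker's assays)."""
    missing = set(panel.assay_ids) - set(assay_levels)
    if missing:
        raise ValueError(f"assay levels missing for {sorted(missing)}")
    unknown = set(assay_levels) - set(panel.assay_ids)
    if unknown:
        raise ValueError(f"levels supplied for assays not in panel: {sorted(unknown)}")
    return {
        m.marker_id: max(float(assay_levels[a]) for a in m.assay_ids)
        for m in panel.markers
    }


def _check_size(marker_levels: Mapping[str, float], n_markers: int) -> np.ndarray:
    values = np.asarray(list(marker_levels.values()), dtype=float)
    if values.size != n_markers:
        raise ValueError(
            f"expected levels for exactly {n_markers} markers, got {values.size}"
        )
    if (values < 0).any():
        raise ValueError("marker levels must be non-negative")
    return values


def count_positive_markers(
    marker_levels: Mapping[str, float], n_markers: int = 19
) -> int:
    """Number of markers with any detected methylation (level strictly > 0)."""
    values = _check_size(marker_levels, n_markers)
    return int((values > 0).sum())


def average_methylation(
    marker_levels: Mapping[str, float], n_markers: int = 19
) -> float:
    """Mean of the merged marker levels (sum over markers divided by panel size)."""
    values = _check_size(marker_levels, n_markers)
    return float(values.sum() / n_markers)


def classify_sample(n_positive: int, threshold: int = DEFAULT_THRESHOLD) -> bool:
    """Test-positive call: at least ``threshold`` markers methylated (inclusive)."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    return int(n_positive) >= threshold


def profile_table(
    levels: pd.DataFrame,
    panel: PanelDefinition,
    threshold: int = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Build per-sample methylation profiles from a long assay-level table.

    ``levels`` is the frame produced by :func:`methpanel.ingest.read_cq_table`
    (columns patient_id, sample_type, assay_id, level).  Returns one row per
    sample indexed by (patient_id, sample_type) with one column per marker
    (merged level) plus ``n_positive``, ``avg_methylation`` and
    ``test_positive``.
    """
    wide = levels.pivot_table(
        index=["patient_id", "sample_type"],
        columns="assay_id",
        values="level",
        aggfunc="first",
    )
    missing = set(panel.assay_ids) - set(wide.columns)
    if missing:
        raise ValueError(f"levels table lacks assays {sorted(missing)}")
    if wide[list(panel.assay_ids)].isna().any().any():
        raise ValueError("levels table has missing assay levels; impute on ingest")

    merged = pd.DataFrame(index=wide.index)
    for m in panel.markers:
        merged[m.marker_id] = wide[list(m.assay_ids)].max(axis=1)

    marker_cols = list(panel.marker_ids)
    merged["n_positive"] = (merged[marker_cols] > 0).sum(axis=1).astype(int)
    merged["avg_methylation"] = merged[marker_cols].sum(axis=1) / panel.n_markers
    merged["test_positive"] = merged["n_positive"] >= threshold
    return merged
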