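"""Raw MS-qPCR Cq tables -> transformed methylation levels.

The instrument reports one quantification cycle (Cq) per well; a well that
never crosses the fluorescence threshold within the run has no Cq
(no amplification).  The analysis works on a transformed level
``cutoff - Cq`` so that 0 means no amplification / beyond the positivity
cutoff and larger values mean more methylated template (lower Cq).  With the
default cutoff of 32 cycles the observed study range was 0 to 15; levels
above 15 (Cq < 17) are legal and only logged.

Input tables are long-format delimited files with columns ``patient_id``,
``sample_type`` (DRE or FV), ``assay_id``, ``replicate``, ``cq``; an empty
``cq`` field (or one of the sentinels in ``NO_AMP_SENTINELS``) marks no
amplification.  Duplicate wells for the same assay x sample are aggregated
(default: highest level, i.e. lowest Cq).
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .panel import PanelDefinition

__all__ = [
    "DEFAULT_CUTOFF",
    "NO_AMP_SENTINELS",
    "cq_to_level",
    "aggregate_replicates",
    "read_cq_table",
    "write_assay_levels",
]

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 32.0
NO_AMP_SENTINELS = {"", "NA", "ND", "NAN", "NO_AMP", "NOAMP", "UNDETERMINED", "0", "0.0"}
SAMPLE_TYPES = ("DRE", "FV")
REQUIRED_COLUMNS = ("patient_id", "sample_type", "assay_id", "replicate", "cq")
AGGREGATION_RULES = ("max", "mean", "mean_of_positives")


def cq_to_level(cq: float | None, cutoff: float = DEFAULT_CUTOFF) -> float:
    """Transform one Cq value to a methylation level.

    No amplification (``None``/NaN) and Cq at or beyond the cutoff map to 0;
    otherwise the level is ``cutoff - cq`` (> 0, strictly decreasing in Cq).
    """
    if cutoff <= 0 or not math.isfinite(cutoff):
        raise ValueError(f"cutoff must be a positive finite cycle count, got {cutoff}")
    if cq is None or (isinstance(cq, float) and math.isnan(cq)):
        return 0.0
    cq = float(cq)
    if not math.isfinite(cq) or cq <= 0:
        raise ValueError(f"Cq must be a positive finite cycle count, got {cq}")
    return 0.0 if cq >= cutoff else cutoff - cq


def aggregate_replicates(levels: Iterable[float], rule: str = "max") -> float:
    """Collapse replicate-well levels for one assay x sample to a single level.

    ``max`` (the default) keeps the highest level, i.e. the lowest Cq —
    consistent with taking the strongest detection as the marker's state.
    ``mean_of_positives`` averages amplified wells only (0 if none amplified).
    """
    values = [float(v) for v in levels]
    if not values:
        raise ValueError("aggregate_replicates needs at least one replicate level")
    if any(v < 0 for v in values):
        raise ValueError("levels must be non-negative")
    if rule == "max":
        return max(values)
    if rule == "mean":
        return float(np.mean(values))
    if rule == "mean_of_positives":
        pos = [v for v in values if v > 0]
        return float(np.mean(pos)) if pos else 0.0
    raise ValueError(f"unknown aggregation rule {rule!r}; expected one of {AGGREGATION_RULES}")


def _parse_cq_column(raw: pd.Series) -> pd.Series:
    """Empty fields and no-amplification sentinels -> NaN; else float cycles."""
    as_str = raw.astype("string").str.strip().str.upper()
    no_amp = raw.isna() | as_str.isin(NO_AMP_SENTINELS)
    parsed = pd.to_numeric(raw.where(~no_amp), errors="coerce")
    bad = (~no_amp) & parsed.isna()
    if bad.any():
        raise ValueError(
            f"unparseable cq values at rows {list(raw.index[bad])[:5]}: "
            f"{raw[bad].head().tolist()}"
        )
    return parsed


def read_cq_table(
    path: str | Path,
    panel: PanelDefinition,
    *,
    cutoff: float = DEFAULT_CUTOFF,
    rule: str = "max",
    missing_assay: str = "impute",
    sep: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a long-format Cq table and return (assay levels, QC report).

    The levels frame has one row per (patient_id, sample_type, assay_id) with
    replicate wells aggregated by ``rule`` and every panel assay present:
    assays absent from the file are imputed as level 0 (``missing_assay=
    "impute"``, logged per sample) or the sample is dropped (``"exclude"``).
    Control-assay wells never enter the levels frame; their amplification
    status is reported per sample in the QC frame.

    The QC frame has one row per sample: assays observed, assays imputed, and
    per-control amplification flags.
    """
    if rule not in AGGREGATION_RULES:
        raise ValueError(f"unknown aggregation rule {rule!r}")
    if missing_assay not in ("impute", "exclude"):
        raise ValueError("missing_assay must be 'impute' or 'exclude'")
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep=sep, engine="python", dtype={"patient_id": str})
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cq table {path} lacks required columns {missing_cols}")

    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    df["sample_type"] = df["sample_type"].astype(str).str.upper()
    bad_types = sorted(set(df["sample_type"]) - set(SAMPLE_TYPES))
    if bad_types:
        raise ValueError(f"unknown sample_type values {bad_types}; expected {SAMPLE_TYPES}")

    known = set(panel.assay_ids) | set(panel.control_assay_ids) | set(panel.aliases)
    unknown = sorted(set(df["assay_id"].astype(str)) - known)
    if unknown:
        raise ValueError(f"unknown assay ids {unknown}; not in panel {panel.name!r}")
    df["assay_id"] = df["assay_id"].astype(str).map(panel.canonical_assay_id)

    dup = df.duplicated(subset=["patient_id", "sample_type", "assay_id", "replicate"])
    if dup.any():
        offenders = df.loc[dup, ["patient_id", "sample_type", "assay_id", "replicate"]]
        raise ValueError(
            "duplicate (patient, sample, assay, replicate) rows:\n"
            + offenders.head().to_string(index=False)
        )
    if (pd.to_numeric(df["replicate"], errors="coerce") < 1).any():
        raise ValueError("replicate numbers must be >= 1")

    cq = _parse_cq_column(df["cq"])
    df["level"] = [cq_to_level(v if pd.notna(v) else None, cutoff) for v in cq]

    is_control = df["assay_id"].isin(panel.control_assay_ids)
    controls = df[is_control]
    df = df[~is_control]

    high = df["level"] > 15
    if high.any():
        logger.warning(
            "%d wells exceed the nominal 0-15 level range (Cq < %.1f); kept unclamped",
            int(high.sum()),
            cutoff - 15,
        )

    agg = (
        df.groupby(["patient_id", "sample_type", "assay_id"], sort=True)["level"]
        .agg(lambda v: aggregate_replicates(v, rule))
        .reset_index()
    )

    # complete every sample to the full assay set
    samples = agg[["patient_id", "sample_type"]].drop_duplicates()
    full_index = pd.MultiIndex.from_frame(
        samples.merge(pd.DataFrame({"assay_id": panel.assay_ids}), how="cross")
    )
    wide = agg.set_index(["patient_id", "sample_type", "assay_id"]).reindex(full_index)
    imputed_mask = wide["level"].isna()

    qc_rows = []
    for (pid, st), grp in wide.groupby(level=[0, 1], sort=True):
        n_imputed = int(grp["level"].isna().sum())
        ctl = controls[(controls["patient_id"] == pid) & (controls["sample_type"] == st)]
        ctl_status = {
            f"control_{c}_amplified": bool((ctl.loc[ctl["assay_id"] == c, "level"] > 0).any())
            for c in panel.control_assay_ids
        }
        qc_rows.append(
            {
                "patient_id": pid,
                "sample_type": st,
                "assays_observed": panel.n_assays - n_imputed,
                "assays_imputed": n_imputed,
                **ctl_status,
            }
        )
        if n_imputed:
            logger.warning(
                "sample %s/%s missing %d assay(s): %s",
                pid,
                st,
                n_imputed,
                ", ".join(grp.index.get_level_values(2)[grp["level"].isna()]),
            )
    qc = pd.DataFrame(qc_rows)

    if missing_assay == "exclude":
        incomplete = imputed_mask.groupby(level=[0, 1]).any()
        keep = ~incomplete.reindex(wide.index.droplevel(2)).to_numpy()
        wide = wide[keep]
    else:
        wide = wide.fillna({"level": 0.0})

    levels = wide.reset_index()
    levels.columns = ["patient_id", "sample_type", "assay_id", "level"]
    return levels, qc


def write_assay_levels(levels: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical long-format assay-level table as TSV."""
    levels.to_csv(path, sep="\t", index=False, float_format="%.4g")
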