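"""End-to-end pipeline: Cq tables -> profiles -> report bundle.

Sample-type strata (DRE, FV) are analyzed independently; paired analyses run
on the intersection of patients with both sample types.  Per-stage log lines
record cohort accounting (samples in, cases/controls, pairs) so exclusions
are auditable.  All machine-readable outputs (TSV/JSON) are deterministic
given the same config and inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from . import compare as cmp
from . import diagnostics as dx
from . import roc as rocmod
from .ingest import DEFAULT_CUTOFF, read_cq_table
from .panel import PanelDefinition, load_panel
from .scoring import DEFAULT_THRESHOLD, profile_table
from .synth import GeneratorParams, generate_cohort, write_fixture

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: str | Path = "methpanel_run"
    cq_path: str | Path | None = None
    clinical_path: str | Path | None = None
    panel_path: str | Path | None = None
    synth_params: GeneratorParams | None = None  # generate inputs instead of reading
    threshold: int = DEFAULT_THRESHOLD
    cutoff: float = DEFAULT_CUTOFF
    aggregation_rule: str = "max"
    ci_method: str = "wilson"
    thresholds: Sequence[int] = tuple(range(1, 20))
    subset_sizes: Sequence[int] = (1, 2, 3, 4, 5, 6)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= int(self.threshold) <= 19:
            raise ValueError("threshold must lie in 1..19")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-tag with stage name
                raise PipelineError(name, str(exc)) from exc

        return wrapped

    return deco


@_stage("ingest")
def _load_inputs(config: RunConfig, panel: PanelDefinition, out: Path):
    if config.synth_params is not None:
        cohort = generate_cohort(config.synth_params, panel)
        paths = write_fixture(cohort, out / "inputs")
        cq_path, clinical_path = paths["cq_table"], paths["clinical"]
    else:
        if config.cq_path is None or config.clinical_path is None:
            raise PipelineError("ingest", "cq_path and clinical_path are required without synth_params")
        cq_path, clinical_path = Path(config.cq_path), Path(config.clinical_path)
        for p in (cq_path, clinical_path):
            if not p.exists():
                raise PipelineError("ingest", f"input file not found: {p}")
    levels, qc = read_cq_table(cq_path, panel, cutoff=config.cutoff, rule=config.aggregation_rule)
    clinical = pd.read_csv(clinical_path, sep=None, engine="python", dtype={"patient_id": str})
    if "patient_id" not in clinical.columns or "biopsy" not in clinical.columns:
        raise PipelineError("ingest", "clinical table must have patient_id and biopsy columns")
    clinical = clinical.set_index("patient_id")
    labels = clinical["biopsy"].astype(bool)
    logger.info(
        "ingest: %d samples, %d cases / %d controls",
        levels[["patient_id", "sample_type"]].drop_duplicates().shape[0],
        int(labels.sum()),
        int((~labels).sum()),
    )
    return levels, qc, clinical, labels


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every analysis stage and write the report bundle to ``out_dir``.

    Returns a name -> path map of everything written.  Any stage failure
    raises :class:`PipelineError` tagged with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    panel = load_panel(config.panel_path)
    levels, qc, clinical, labels = _load_inputs(config, panel, out)

    def save_tsv(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        outputs[name] = path

    def save_json(name: str, obj) -> None:
        path = out / f"{name}.json"
        path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")
        outputs[name] = path

    save_tsv("qc_report", qc)
    save_tsv("assay_levels", levels)

    # scoring ---------------------------------------------------------------
    try:
        profiles = profile_table(levels, panel, threshold=config.threshold)
    except Exception as exc:
        raise PipelineError("scoring", str(exc)) from exc
    missing_labels = sorted(set(profiles.index.get_level_values(0)) - set(labels.index))
    if missing_labels:
        raise PipelineError("scoring", f"samples without biopsy labels: {missing_labels}")
    save_tsv("profiles", profiles.reset_index())

    # diagnostics -----------------------------------------------------------
    try:
        assay_table = dx.assay_performance_table(levels, panel, labels, ci_method=config.ci_method, seed=config.seed)
        sweep = dx.threshold_sweep(
            profiles, labels, thresholds=config.thresholds, ci_method=config.ci_method,
            seed=config.seed, n_markers=panel.n_markers,
        )
    except Exception as exc:
        raise PipelineError("diagnostics", str(exc)) from exc
    save_tsv("assay_performance", assay_table)
    save_tsv("threshold_performance", sweep)

    # roc -------------------------------------------------------------------
    try:
        roc_points = []
        auc_summary: dict[str, dict] = {}
        subset_frames = []
        for st, grp in profiles.groupby(level="sample_type", sort=True):
            scores = grp.droplevel("sample_type")
            y = labels.loc[scores.index]
            for score_name in ("n_positive", "avg_methylation"):
                r = rocmod.roc_curve(scores[score_name], y, score_name=score_name, sample_type=st)
                roc_points.append(r.points_frame())
                auc_summary.setdefault(st, {})[score_name] = r.auc
            psa = clinical["psa"].reindex(scores.index)
            ok = psa.notna()
            if ok.sum() and y[ok].nunique() == 2:
                logger.info("roc: %s PSA curve drops %d samples with missing PSA", st, int((~ok).sum()))
                r = rocmod.roc_curve(psa[ok], y[ok], score_name="psa", sample_type=st)
                roc_points.append(r.points_frame())
                auc_summary[st]["psa"] = r.auc
            marker_levels = scores[list(panel.marker_ids)]
            for k in config.subset_sizes:
                dist = rocmod.enumerate_subset_aucs(marker_levels, y.to_numpy(), k, sample_type=st)
                subset_frames.append(dist.to_frame())
                auc_summary[st][f"subset_k{k}"] = dist.summary
    except Exception as exc:
        raise PipelineError("roc", str(exc)) from exc
    save_tsv("roc_points", pd.concat(roc_points, ignore_index=True))
    save_tsv("subset_aucs", pd.concat(subset_frames, ignore_index=True))
    save_json("auc_summary", auc_summary)

    # compare ---------------------------------------------------------------
    try:
        compare_out = _paired_and_group_analyses(profiles, labels, clinical, panel, config)
    except Exception as exc:
        raise PipelineError("compare", str(exc)) from exc
    if compare_out["paired_markers"] is not None:
        save_tsv("paired_marker_differences", compare_out["paired_markers"])
        save_json("paired_comparison", compare_out["paired_tests"])
    save_tsv("group_summaries", compare_out["group_summaries"])

    manifest = {
        "package_version": __version__,
        "panel": panel.name,
        "seed": config.seed,
        "threshold": config.threshold,
        "ci_method": config.ci_method,
        "aggregation_rule": config.aggregation_rule,
        "cutoff": config.cutoff,
        "subset_sizes": list(config.subset_sizes),
        "synthetic": config.synth_params is not None,
        "n_cases": int(labels.sum()),
        "n_controls": int((~labels).sum()),
    }
    save_json("manifest", manifest)
    return outputs


def _paired_and_group_analyses(profiles, labels, clinical, panel, config):
    by_type = {st: grp.droplevel("sample_type") for st, grp in profiles.groupby(level="sample_type")}
    out = {"paired_markers": None, "paired_tests": None}

    if "DRE" in by_type and "FV" in by_type:
        paired_ids = sorted(set(by_type["DRE"].index) & set(by_type["FV"].index))
        logger.info("compare: %d paired patients", len(paired_ids))
        if len(paired_ids) >= 2:
            dre = by_type["DRE"].loc[paired_ids]
            fv = by_type["FV"].loc[paired_ids]
            rows = []
            for stat in ("avg_methylation", "n_positive", *panel.marker_ids):
                d = cmp.paired_marker_difference(dre[stat], fv[stat], marker_id=stat)
                rows.append(
                    {
                        "marker": stat,
                        "n_pairs": d.n_pairs,
                        "mean_difference": d.mean_difference,
                        "ci_low": d.ci_low,
                        "ci_high": d.ci_high,
                        "p_value": d.p_value,
                    }
                )
            out["paired_markers"] = pd.DataFrame(rows)
            y = labels.loc[paired_ids]
            if y.nunique() == 2:
                res = cmp.compare_paired_tests(
                    fv["test_positive"].loc[paired_ids], dre["test_positive"].loc[paired_ids], y
                )
                out["paired_tests"] = {
                    "test_a": "FV", "test_b": "DRE",
                    **{k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(res).items()},
                }

    groups = clinical["capra_group"] if "capra_group" in clinical.columns else labels.astype(int)
    out["group_summaries"] = cmp.group_summaries(profiles, groups)
    return out
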