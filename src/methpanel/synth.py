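"""Seeded synthetic urine-methylation cohorts.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage is exercisable without patient data:

* per-marker positivity probabilities that differ between biopsy-positive and
  biopsy-negative patients — defaults are the published per-assay proportions
  of the default panel's clinical study (:mod:`methpanel.calibration`);
* marker-level state first, then per-assay detection: a dual-assay marker's
  two assays are drawn conditionally on the marker state from a joint
  distribution whose marginals reproduce the published per-assay rates and
  whose union equals the marker state (two assays per island can only gain
  sensitivity);
* methylation levels on the 0-15 transformed scale (truncated normal given
  positive), back-transformed to Cq = cutoff - level so the cohort exercises
  the real ingest path, in duplicate wells;
* paired DRE/FV samples with within-patient state agreement, per-patient
  sample availability, attenuated FV recovery for selected markers;
* PSA (log-normal per biopsy group), age, and CAPRA risk groups that shift
  case methylation burden in log-odds.

All randomness flows from the single ``seed`` through one generator; a given
parameter set is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import truncnorm

from . import calibration as calib
from .ingest import DEFAULT_CUTOFF
from .panel import PanelDefinition, default_panel

__all__ = ["GeneratorParams", "SyntheticCohort", "default_params", "generate_cohort", "write_fixture"]


@dataclass(frozen=True)
class GeneratorParams:
    """Full parameterization of a synthetic cohort; see module docstring.

    ``assay_p_case`` / ``assay_p_control`` are per-assay positivity
    probabilities (the DRE calibration); ``marker_p_case`` / ``marker_p_control``
    the corresponding marker-level (either-assay) probabilities.
    ``fv_attenuation`` multiplies case marker positivity in first-void
    samples (markers recovered less well without a DRE).
    """

    seed: int
    assay_p_case: dict[str, float]
    assay_p_control: dict[str, float]
    marker_p_case: dict[str, float]
    marker_p_control: dict[str, float]
    n_cases: int = 42
    n_controls: int = 52
    level_mean: float = 6.0
    level_sd: float = 3.0
    level_max: float = 15.0
    dre_fv_agreement: float = 0.8
    fv_attenuation: dict[str, float] = field(default_factory=dict)
    psa_median: dict[str, float] = field(default_factory=lambda: {"case": 6.4, "control": 5.2})
    psa_sigma: dict[str, float] = field(default_factory=lambda: {"case": 0.455, "control": 0.385})
    psa_missing_rate: float = 0.03
    capra_effect: float = 0.8
    p_elevated: float = 20 / 35
    # per-patient sample availability: (both DRE and FV, DRE only, FV only)
    availability: tuple[float, float, float] = (60 / 94, 27 / 94, 7 / 94)
    missing_rate: float = 0.0
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("cohort sizes must be non-negative")
        for name in ("assay_p_case", "assay_p_control", "marker_p_case", "marker_p_control"):
            for k, p in getattr(self, name).items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name}[{k!r}] = {p} outside [0, 1]")
        for p in (self.dre_fv_agreement, self.missing_rate, self.psa_missing_rate, self.p_elevated):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if abs(sum(self.availability) - 1.0) > 1e-9 or min(self.availability) < 0:
            raise ValueError("availability probabilities must be non-negative and sum to 1")


# FV/DRE case-positivity ratios for the markers recovered significantly less
# well from first-void urine in the calibration study
_DEFAULT_FV_ATTENUATION = {"AOX1": 0.62, "GFRA2": 0.91, "NEUROG3": 0.59}


def default_params(panel: PanelDefinition | None = None, seed: int = 0, **overrides) -> GeneratorParams:
    """Generator defaults calibrated to the published per-assay DRE proportions.

    Case probabilities are positives/cases; control probabilities are
    1 - negatives/controls.  Marker-level probabilities use the published
    combined rows for the five dual-assay markers.
    """
    panel = panel or default_panel()
    n_ca, n_co = calib.COHORT_SIZES["DRE"]
    counts = calib.ASSAY_COUNTS["DRE"]
    unions = calib.MARKER_UNION_COUNTS["DRE"]
    assay_p_case = {a: counts[a][0] / n_ca for a in panel.assay_ids}
    assay_p_control = {a: 1 - counts[a][1] / n_co for a in panel.assay_ids}
    marker_p_case = {m: unions[m][0] / n_ca for m in panel.marker_ids}
    marker_p_control = {m: 1 - unions[m][1] / n_co for m in panel.marker_ids}
    return GeneratorParams(
        seed=seed,
        assay_p_case=assay_p_case,
        assay_p_control=assay_p_control,
        marker_p_case=marker_p_case,
        marker_p_control=marker_p_control,
        fv_attenuation=dict(_DEFAULT_FV_ATTENUATION),
        **overrides,
    )


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort: raw Cq wells, truth levels, and clinical labels."""

    cq_table: pd.DataFrame  # patient_id, sample_type, assay_id, replicate, cq
    assay_levels: pd.DataFrame  # patient_id, sample_type, assay_id, level (truth)
    clinical: pd.DataFrame  # patient_id, biopsy, capra_group, psa, age, ...
    params: GeneratorParams

    @property
    def labels(self) -> pd.Series:
        return self.clinical.set_index("patient_id")["biopsy"].astype(bool)

    @property
    def capra_groups(self) -> pd.Series:
        return self.clinical.set_index("patient_id")["capra_group"].astype(int)


def _group_probs(p: float, delta: float, w_elev: float) -> tuple[float, float]:
    """Split a case marginal into (low-risk, elevated-risk) probabilities.

    The elevated group sits ``delta`` higher in log-odds; the pair is
    recentered numerically so the weighted marginal equals ``p`` exactly,
    keeping the calibration intact.
    """
    if p <= 0.0:
        return 0.0, 0.0
    if p >= 1.0:
        return 1.0, 1.0
    if delta == 0.0 or w_elev in (0.0, 1.0):
        return p, p

    def f(t: float) -> float:
        return (1 - w_elev) * expit(t) + w_elev * expit(t + delta) - p

    t = brentq(f, logit(p) - abs(delta) - 1, logit(p) + abs(delta) + 1)
    return float(expit(t)), float(expit(t + delta))


def _detection_split(u: float, a1: float, a2: float) -> tuple[float, float]:
    """Per-assay detection probabilities given a positive marker state."""
    if u <= 0.0:
        return 0.0, 0.0
    d1, d2 = min(a1 / u, 1.0), min(a2 / u, 1.0)
    if d1 + d2 < 1.0 - 1e-9:
        raise ValueError(
            f"infeasible dual-assay split: union {u} with assay rates {a1}, {a2} "
            "(detection probabilities must sum to >= 1 for the union to equal the marker state)"
        )
    return d1, max(d2, 1.0 - d1)


def _positive_levels(rng: np.random.Generator, n: int, params: GeneratorParams) -> np.ndarray:
    lo = (0.0 - params.level_mean) / params.level_sd
    hi = (params.level_max - params.level_mean) / params.level_sd
    raw = truncnorm.rvs(lo, hi, loc=params.level_mean, scale=params.level_sd, size=n, random_state=rng)
    return np.maximum(np.round(raw, 1), 0.1)


def generate_cohort(
    params: GeneratorParams, panel: PanelDefinition | None = None
) -> SyntheticCohort:
    """Generate one synthetic cohort, deterministic given ``params.seed``."""
    panel = panel or default_panel()
    rng = np.random.default_rng(params.seed)
    markers = list(panel.marker_ids)
    assays = list(panel.assay_ids)
    n = params.n_cases + params.n_controls
    width = max(3, len(str(max(n, 1))))
    pids = np.array([f"P{i + 1:0{width}d}" for i in range(n)])
    is_case = np.arange(n) < params.n_cases

    # CAPRA risk group: 0 controls, 1 low-risk cases, 2 elevated-risk cases
    group = np.zeros(n, dtype=int)
    group[is_case] = np.where(rng.random(params.n_cases) < params.p_elevated, 2, 1)

    # sample availability per patient
    avail = rng.choice(3, size=n, p=list(params.availability))  # 0 both, 1 DRE only, 2 FV only
    has_dre = avail != 2
    has_fv = avail != 1

    # per-patient marker probabilities, DRE and FV
    def prob_matrix(sample_type: str) -> np.ndarray:
        out = np.empty((n, len(markers)))
        for j, m in enumerate(markers):
            p_case = params.marker_p_case[m]
            if sample_type == "FV":
                p_case = min(1.0, p_case * params.fv_attenuation.get(m, 1.0))
            p1, p2 = _group_probs(p_case, params.capra_effect, params.p_elevated)
            col = np.full(n, params.marker_p_control[m])
            col[group == 1] = p1
            col[group == 2] = p2
            out[:, j] = col
        return out

    state_dre = rng.random((n, len(markers))) < prob_matrix("DRE")
    agree = rng.random((n, len(markers))) < params.dre_fv_agreement
    fresh_fv = rng.random((n, len(markers))) < prob_matrix("FV")
    state_fv = np.where(agree, state_dre, fresh_fv)

    # marker states -> assay indicators
    def assay_matrix(states: np.ndarray) -> np.ndarray:
        out = np.zeros((n, len(assays)), dtype=bool)
        for j, m in enumerate(markers):
            a_ids = panel.assays_for(m)
            if len(a_ids) == 1:
                out[:, assays.index(a_ids[0])] = states[:, j]
                continue
            a1, a2 = a_ids
            d1 = np.empty(n)
            d2 = np.empty(n)
            for stratum, mask in (("case", is_case), ("control", ~is_case)):
                p_a = params.assay_p_case if stratum == "case" else params.assay_p_control
                p_m = params.marker_p_case if stratum == "case" else params.marker_p_control
                s1, s2 = _detection_split(p_m[m], p_a[a1], p_a[a2])
                d1[mask], d2[mask] = s1, s2
            v = rng.random(n)
            only1 = v < 1 - d2
            only2 = (~only1) & (v < (1 - d2) + (1 - d1))
            both = (~only1) & (~only2)
            out[:, assays.index(a1)] = states[:, j] & (only1 | both)
            out[:, assays.index(a2)] = states[:, j] & (only2 | both)
        return out

    pos_dre = assay_matrix(state_dre)
    pos_fv = assay_matrix(state_fv)

    def level_matrix(pos: np.ndarray) -> np.ndarray:
        lv = np.zeros_like(pos, dtype=float)
        k = int(pos.sum())
        if k:
            lv[pos] = _positive_levels(rng, k, params)
        return lv

    lv_dre = level_matrix(pos_dre)
    lv_fv = level_matrix(pos_fv)

    # assemble long tables
    level_rows, cq_rows = [], []
    for st, has, lv in (("DRE", has_dre, lv_dre), ("FV", has_fv, lv_fv)):
        jitter = np.round(rng.uniform(0.1, 0.5, size=lv.shape), 1)
        keep = (
            rng.random(lv.shape) >= params.missing_rate
            if params.missing_rate > 0
            else np.ones(lv.shape, dtype=bool)
        )
        ctl_cq = np.round(np.clip(rng.normal(26.0, 1.5, size=(n, len(panel.control_assay_ids))), 20.0, 31.5), 1)
        for i in np.flatnonzero(has):
            for j, a in enumerate(assays):
                if not keep[i, j]:
                    continue
                level = lv[i, j]
                level_rows.append((pids[i], st, a, level))
                if level > 0:
                    cq1 = round(params.cutoff - level, 1)
                    cq2 = round(cq1 + jitter[i, j], 1)
                    cq_rows.append((pids[i], st, a, 1, cq1))
                    cq_rows.append((pids[i], st, a, 2, cq2 if cq2 < params.cutoff else None))
                else:
                    cq_rows.append((pids[i], st, a, 1, None))
                    cq_rows.append((pids[i], st, a, 2, None))
            for c_idx, c in enumerate(panel.control_assay_ids):
                for rep in (1, 2):
                    cq_rows.append((pids[i], st, c, rep, ctl_cq[i, c_idx]))

    assay_levels = pd.DataFrame(level_rows, columns=["patient_id", "sample_type", "assay_id", "level"])
    cq_table = pd.DataFrame(cq_rows, columns=["patient_id", "sample_type", "assay_id", "replicate", "cq"])

    # clinical covariates
    psa_mu = np.where(is_case, math.log(params.psa_median["case"]), math.log(params.psa_median["control"]))
    psa_sig = np.where(is_case, params.psa_sigma["case"], params.psa_sigma["control"])
    psa = np.round(np.exp(rng.normal(psa_mu, psa_sig)), 2)
    psa = np.where(rng.random(n) < params.psa_missing_rate, np.nan, psa)
    age = np.clip(np.round(rng.normal(np.where(is_case, 67.1, 63.9), np.where(is_case, 7.1, 7.6))), 45, 90).astype(int)
    gleason = np.where(group == 2, rng.choice([7, 8, 9], size=n), np.where(group == 1, 6, 0))
    cores = np.where(
        group == 2, rng.integers(3, 13, size=n), np.where(group == 1, rng.integers(1, 4, size=n), 0)
    )
    clinical = pd.DataFrame(
        {
            "patient_id": pids,
            "biopsy": is_case.astype(int),
            "capra_group": group,
            "psa": psa,
            "age": age,
            "gleason": np.where(is_case, gleason, np.nan),
            "positive_cores": np.where(is_case, cores, np.nan),
            "has_dre": has_dre.astype(int),
            "has_fv": has_fv.astype(int),
        }
    )
    return SyntheticCohort(cq_table=cq_table, assay_levels=assay_levels, clinical=clinical, params=params)


def write_fixture(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write the cohort as ingest-ready TSVs; byte-identical for a given seed."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "cq_table": directory / "cq_table.tsv",
        "clinical": directory / "clinical.tsv",
    }
    cq = cohort.cq_table.copy()
    cq["cq"] = cq["cq"].map(lambda v: "" if v is None or (isinstance(v, float) and math.isnan(v)) else f"{v:.1f}")
    cq.to_csv(paths["cq_table"], sep="\t", index=False)
    cohort.clinical.to_csv(paths["clinical"], sep="\t", index=False, float_format="%.2f")
    return paths
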