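"""Published operating counts for the default 19-marker urine panel.

These are the per-assay and per-threshold 2x2 counts reported by the clinical
study the default panel comes from (94 patients with biopsy outcomes; 87
post-DRE urine samples, 38 biopsy-positive cases / 49 biopsy-negative
controls, and 67 first-void samples, 32 cases / 35 controls; 60 patients had
both).  They serve two purposes:

* worked-example inputs — printed counts can be fed straight into
  :mod:`methpanel.diagnostics` to recompute the published metrics;
* calibration defaults for :mod:`methpanel.synth` — per-assay positivity
  probabilities of the synthetic cohort are the published proportions.

``ASSAY_COUNTS`` maps sample type -> assay id -> (positive_cases,
negative_controls).  ``MARKER_UNION_COUNTS`` holds the combined (either-assay
positive) counts per marker; for single-assay markers it repeats the assay
counts, for the five dual-assay markers it is the published combined row.
``THRESHOLD_COUNTS`` maps sample type -> n-of-19 threshold -> (cases called
positive, controls called negative).
"""

from __future__ import annotations

__all__ = [
    "COHORT_SIZES",
    "ASSAY_COUNTS",
    "MARKER_UNION_COUNTS",
    "THRESHOLD_COUNTS",
    "PAIRED_6OF19",
    "PSA_PARAMS",
    "CAPRA_GROUP_SIZES",
]

# sample type -> (n_cases, n_controls)
COHORT_SIZES: dict[str, tuple[int, int]] = {"DRE": (38, 49), "FV": (32, 35)}

# (positive among cases, negative among controls) per assay
ASSAY_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "DRE": {
        "ADCY4": (23, 38),
        "AOX1rc": (27, 34),
        "APC2": (10, 44),
        "CXCL14": (8, 49),
        "CXCL14rc": (6, 49),
        "EPHX3": (25, 35),
        "KIFC2": (25, 38),
        "KIFC2rc": (20, 42),
        "GFRA2": (17, 41),
        "GSTP1": (18, 40),
        "HEMK1": (15, 46),
        "HOXA7": (32, 39),
        "HOXB5": (29, 40),
        "HOXB5rc": (27, 35),
        "HOXD3a": (19, 45),
        "HOXD3b": (29, 37),
        "HOXD9": (26, 29),
        "HOXD10": (23, 42),
        "MOXD1": (16, 41),
        "NEUROG3": (14, 42),
        "NODAL": (24, 40),
        "NODALrc": (20, 41),
        "RASSF5": (9, 46),
        "RASSF5rc": (10, 43),
    },
    "FV": {
        "ADCY4": (18, 24),
        "AOX1rc": (14, 29),
        "APC2": (4, 32),
        "CXCL14": (9, 34),
        "CXCL14rc": (4, 35),
        "EPHX3": (18, 24),
        "KIFC2": (18, 28),
        "KIFC2rc": (11, 32),
        "GFRA2": (13, 29),
        "GSTP1": (15, 29),
        "HEMK1": (8, 32),
        "HOXA7": (21, 23),
        "HOXB5": (23, 23),
        "HOXB5rc": (22, 23),
        "HOXD3a": (15, 30),
        "HOXD3b": (31, 21),
        "HOXD9": (20, 25),
        "HOXD10": (17, 27),
        "MOXD1": (15, 32),
        "NEUROG3": (7, 33),
        "NODAL": (16, 28),
        "NODALrc": (10, 28),
        "RASSF5": (9, 35),
        "RASSF5rc": (11, 30),
    },
}

# combined either-assay counts for the dual-assay markers (published "Comb." rows)
_DUAL_UNION: dict[str, dict[str, tuple[int, int]]] = {
    "DRE": {
        "CXCL14": (9, 49),
        "KIFC2": (30, 34),
        "HOXB5": (32, 29),
        "NODAL": (30, 35),
        "RASSF5": (17, 40),
    },
    "FV": {
        "CXCL14": (11, 34),
        "KIFC2": (21, 27),
        "HOXB5": (28, 20),
        "NODAL": (19, 24),
        "RASSF5": (19, 30),
    },
}

# assay id -> marker id for the default panel (single-assay markers)
_SINGLE_ASSAY_MARKER = {
    "ADCY4": "ADCY4",
    "AOX1rc": "AOX1",
    "APC2": "APC",
    "EPHX3": "EPHX3",
    "GFRA2": "GFRA2",
    "GSTP1": "GSTP1",
    "HEMK1": "HEMK1",
    "HOXA7": "HOXA7",
    "HOXD3a": "HOXD3a",
    "HOXD3b": "HOXD3b",
    "HOXD9": "HOXD9",
    "HOXD10": "HOXD10",
    "MOXD1": "MOXD1",
    "NEUROG3": "NEUROG3",
}


def _marker_unions() -> dict[str, dict[str, tuple[int, int]]]:
    out: dict[str, dict[str, tuple[int, int]]] = {}
    for st, counts in ASSAY_COUNTS.items():
        per_marker: dict[str, tuple[int, int]] = {}
        for assay, c in counts.items():
            marker = _SINGLE_ASSAY_MARKER.get(assay)
            if marker is not None:
                per_marker[marker] = c
        per_marker.update(_DUAL_UNION[st])
        out[st] = per_marker
    return out


MARKER_UNION_COUNTS: dict[str, dict[str, tuple[int, int]]] = _marker_unions()

# n-of-19 threshold -> (cases test-positive, controls test-negative)
THRESHOLD_COUNTS: dict[str, dict[int, tuple[int, int]]] = {
    "DRE": {
        1: (38, 7),
        2: (38, 15),
        3: (37, 18),
        4: (36, 25),
        5: (36, 30),
        6: (34, 35),
        7: (32, 38),
        8: (30, 43),
        9: (28, 44),
        10: (27, 46),
        11: (22, 47),
        12: (13, 49),
        13: (11, 49),
        14: (9, 49),
        15: (7, 49),
    },
    "FV": {
        1: (32, 4),
        2: (32, 8),
        3: (32, 13),
        4: (31, 19),
        5: (31, 23),
        6: (30, 25),
        7: (26, 27),
        8: (21, 30),
        9: (19, 32),
        10: (16, 33),
        11: (12, 33),
        12: (9, 33),
        13: (7, 35),
        14: (5, 35),
        15: (3, 35),
    },
}

# paired subset (60 patients with both sample types: 28 cases / 32 controls)
# counts of correct calls at the 6-of-19 threshold per test
PAIRED_6OF19 = {
    "n_cases": 28,
    "n_controls": 32,
    "dre_true_positives": 26,  # sensitivity 0.929
    "fv_true_positives": 27,  # sensitivity 0.964
    "dre_true_negatives": 22,  # specificity 0.688
    "fv_true_negatives": 22,
    # among cases exactly one pair is discordant (FV positive, DRE negative);
    # control calls are concordant
    "case_discordants": (0, 1),  # (DRE+/FV-, DRE-/FV+)
    "control_discordants": (0, 0),
}

# serum PSA (ng/ml) summaries per biopsy group: (median, mean, sd)
PSA_PARAMS = {"case": (6.4, 7.1, 3.3), "control": (5.2, 5.6, 2.7)}

# CAPRA risk groups among cases with DRE data: 15 low-risk (scores 1-2),
# 20 elevated-risk (score >= 3)
CAPRA_GROUP_SIZES = {"low": 15, "elevated": 20}
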