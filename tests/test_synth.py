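import pandas as pd
import pytest

from methpanel import (
    default_params,
    generate_cohort,
    profile_table,
    read_cq_table,
    write_fixture,
)
from methpanel.calibration import ASSAY_COUNTS, COHORT_SIZES, MARKER_UNION_COUNTS
from methpanel.synth import GeneratorParams, _detection_split, _group_probs


def _flat_params(panel, seed, p_case, p_control, **kw):
    return GeneratorParams(
        seed=seed,
        assay_p_case={a: p_case for a in panel.assay_ids},
        assay_p_control={a: p_control for a in panel.assay_ids},
        marker_p_case={m: p_case for m in panel.marker_ids},
        marker_p_control={m: p_control for m in panel.marker_ids},
        **kw,
    )


class TestDefaultParams:
    def test_probabilities_are_published_proportions(self, panel):
        params = default_params(panel)
        n_ca, n_co = COHORT_SIZES["DRE"]
        assert params.assay_p_case["ADCY4"] == pytest.approx(23 / 38)
        assert params.assay_p_control["CXCL14rc"] == 0.0  # 49/49 negative controls
        assert params.marker_p_case["KIFC2"] == pytest.approx(30 / 38)  # combined row
        for a, p in params.assay_p_case.items():
            assert 0 <= p <= 1
            assert p == pytest.approx(ASSAY_COUNTS["DRE"][a][0] / n_ca)
        for m, p in params.marker_p_control.items():
            assert p == pytest.approx(1 - MARKER_UNION_COUNTS["DRE"][m][1] / n_co)

    def test_seed_mandatory(self, panel):
        with pytest.raises(ValueError, match="seed"):
            _flat_params(panel, None, 0.5, 0.1)

    def test_invalid_probability_rejected(self, panel):
        with pytest.raises(ValueError, match="outside"):
            _flat_params(panel, 0, 1.5, 0.1)


class TestInternals:
    def test_group_probs_recentered_exactly(self):
        for p in (0.05, 0.3, 0.6, 0.95):
            p1, p2 = _group_probs(p, 0.8, 20 / 35)
            assert p1 < p < p2
            assert (15 / 35) * p1 + (20 / 35) * p2 == pytest.approx(p, abs=1e-12)
        assert _group_probs(0.0, 0.8, 0.5) == (0.0, 0.0)
        assert _group_probs(1.0, 0.8, 0.5) == (1.0, 1.0)

    def test_detection_split_reproduces_marginals(self):
        u, a1, a2 = 30 / 38, 25 / 38, 20 / 38
        d1, d2 = _detection_split(u, a1, a2)
        assert u * d1 == pytest.approx(a1)
        assert u * d2 == pytest.approx(a2)
        # joint on {both, only1, only2} must be a distribution with union 1
        assert d1 + d2 >= 1
        assert _detection_split(0.0, 0.0, 0.0) == (0.0, 0.0)


class TestGenerateCohort:
    def test_no_signal_means_no_positives(self, panel):
        params = _flat_params(panel, 3, 0.0, 0.0, n_cases=5, n_controls=5)
        cohort = generate_cohort(params, panel)
        assert (cohort.assay_levels["level"] == 0).all()

    def test_perfect_signal_perfect_classifier(self, panel):
        params = _flat_params(panel, 3, 1.0, 0.0, n_cases=8, n_controls=8)
        cohort = generate_cohort(params, panel)
        profiles = profile_table(cohort.assay_levels, panel)
        y = cohort.labels.loc[profiles.index.get_level_values(0)]
        assert (profiles.loc[y.to_numpy(), "n_positive"] == 19).all()
        assert (profiles.loc[~y.to_numpy(), "n_positive"] == 0).all()

    def test_deterministic_given_seed(self, panel):
        params = default_params(panel, seed=9, n_cases=6, n_controls=6)
        a = generate_cohort(params, panel)
        b = generate_cohort(params, panel)
        pd.testing.assert_frame_equal(a.cq_table, b.cq_table)
        pd.testing.assert_frame_equal(a.clinical, b.clinical)

    def test_different_seeds_differ(self, panel):
        a = generate_cohort(default_params(panel, seed=1, n_cases=6, n_controls=6), panel)
        b = generate_cohort(default_params(panel, seed=2, n_cases=6, n_controls=6), panel)
        assert not a.cq_table.equals(b.cq_table)

    def test_levels_in_range_and_cq_consistent(self, cohort):
        lv = cohort.assay_levels["level"]
        assert ((lv == 0) | ((lv >= 0.1) & (lv <= 15))).all()
        cq = cohort.cq_table
        rep1 = cq[cq.replicate == 1].dropna(subset=["cq"])
        assert ((rep1["cq"] >= 17.0) & (rep1["cq"] < 32.0)).all()

    def test_capra_groups_shift_burden(self, panel):
        params = default_params(panel, seed=5, n_cases=300, n_controls=50)
        cohort = generate_cohort(params, panel)
        profiles = profile_table(cohort.assay_levels, panel)
        dre = profiles.xs("DRE", level="sample_type")
        g = cohort.capra_groups.loc[dre.index]
        m0 = dre.loc[g == 0, "n_positive"].mean()
        m1 = dre.loc[g == 1, "n_positive"].mean()
        m2 = dre.loc[g == 2, "n_positive"].mean()
        assert m0 < m1 < m2

    def test_dual_assay_union_equals_marker_state(self, panel):
        """With the joint detection draw, a dual marker is positive iff at
        least one of its assays is (checked downstream of the merge)."""
        params = default_params(panel, seed=6, n_cases=200, n_controls=200)
        cohort = generate_cohort(params, panel)
        wide = cohort.assay_levels.pivot_table(
            index=["patient_id", "sample_type"], columns="assay_id", values="level"
        )
        for m in panel.dual_assay_markers:
            a1, a2 = panel.assays_for(m)
            union = (wide[a1] > 0) | (wide[a2] > 0)
            y = cohort.labels.loc[wide.index.get_level_values(0)].to_numpy()
            dre = wide.index.get_level_values(1) == "DRE"
            emp = union[dre & y].mean()
            assert emp == pytest.approx(params.marker_p_case[m], abs=0.08)

    def test_sample_availability(self, panel):
        params = default_params(panel, seed=10, n_cases=400, n_controls=400)
        cohort = generate_cohort(params, panel)
        frac_dre = cohort.clinical["has_dre"].mean()
        frac_fv = cohort.clinical["has_fv"].mean()
        assert frac_dre == pytest.approx(87 / 94, abs=0.05)
        assert frac_fv == pytest.approx(67 / 94, abs=0.05)

    def test_fv_attenuation_lowers_case_recovery(self, panel):
        params = default_params(panel, seed=11, n_cases=600, n_controls=50,
                                dre_fv_agreement=0.0, availability=(1.0, 0.0, 0.0))
        cohort = generate_cohort(params, panel)
        wide = cohort.assay_levels.pivot_table(
            index=["patient_id", "sample_type"], columns="assay_id", values="level"
        )
        y = cohort.labels
        for assay, marker in [("AOX1rc", "AOX1"), ("NEUROG3", "NEUROG3")]:
            dre_rate = (wide.xs("DRE", level=1)[assay] > 0)[y].mean()
            fv_rate = (wide.xs("FV", level=1)[assay] > 0)[y].mean()
            assert fv_rate < dre_rate


class TestFixtureRoundTrip:
    def test_write_read_recovers_levels(self, tmp_path, cohort, panel):
        paths = write_fixture(cohort, tmp_path)
        levels, qc = read_cq_table(paths["cq_table"], panel, sep="\t")
        truth = cohort.assay_levels.sort_values(
            ["patient_id", "sample_type", "assay_id"]
        ).reset_index(drop=True)
        got = levels.sort_values(["patient_id", "sample_type", "assay_id"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(truth, got, check_dtype=False, atol=1e-9)
        assert qc["assays_imputed"].eq(0).all()
        assert qc["control_NSD1_amplified"].all()

    def test_byte_identical_for_same_seed(self, tmp_path, panel):
        params = default_params(panel, seed=4, n_cases=5, n_controls=5)
        p1 = write_fixture(generate_cohort(params, panel), tmp_path / "a")
        p2 = write_fixture(generate_cohort(params, panel), tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_different_seed_different_bytes(self, tmp_path, panel):
        a = generate_cohort(default_params(panel, seed=4, n_cases=5, n_controls=5), panel)
        b = generate_cohort(default_params(panel, seed=5, n_cases=5, n_controls=5), panel)
        pa = write_fixture(a, tmp_path / "a")
        pb = write_fixture(b, tmp_path / "b")
        assert pa["cq_table"].read_bytes() != pb["cq_table"].read_bytes()
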