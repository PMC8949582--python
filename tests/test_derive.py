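"""Parameter-derivation chain: GFR formulas, well-stirred inversion, IVIVE."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from doxopbpk import derive
from doxopbpk.derive import (
    DrugModel,
    EliminationFractions,
    ExtractionExceedsFlowError,
    LiverScalars,
    MetabolicSplit,
    PatientRecord,
    derive_drug_model,
)
from doxopbpk import presets
from doxopbpk.synthdata import make_training_study

LIVER = LiverScalars(liver_weight=1800.0, hpgl=100.0, mppgl=32.0, cppgl=80.7)


class TestRenal:
    def test_age_group_gfr_scales_with_bsa(self):
        table = ((40.0, 60.0, 90.0),)
        assert derive.egfr_davies_shock(50, 1.90, table) == pytest.approx(98.84, abs=0.01)
        # reference surface area returns the tabulated value unchanged
        table = ((40.0, 60.0, 121.0),)
        assert derive.egfr_davies_shock(50, 1.73, table) == pytest.approx(121.0)

    def test_age_outside_table_raises(self):
        with pytest.raises(ValueError, match="outside"):
            derive.egfr_davies_shock(95, 1.8)
        with pytest.raises(ValueError):
            derive.egfr_davies_shock(50, 0.0)

    @pytest.mark.parametrize("sex, expected", [
        ("male", 104.4), ("female", 86.86), ("unknown", 95.63),
    ])
    def test_creatinine_formula(self, sex, expected):
        assert derive.egfr_wright(50, 1.8, 80, sex) == pytest.approx(expected, abs=0.01)

    def test_creatinine_formula_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            derive.egfr_wright(50, 1.8, 0.0, "male")
        with pytest.raises(ValueError):
            derive.egfr_wright(50, 1.8, 80, "other")

    def test_reference_renal_clearance(self):
        assert derive.reference_renal_clearance(5.59, 120, 120) == pytest.approx(5.59)
        assert derive.reference_renal_clearance(5.59, 90, 120) == pytest.approx(7.4533, abs=1e-3)
        # individualising back to the subject recovers the input exactly
        ref = derive.reference_renal_clearance(5.59, 90, 121)
        assert ref * 90 / 121 == pytest.approx(5.59, rel=1e-12)


class TestBloodPlasma:
    def test_fraction_unbound_blood(self):
        assert derive.fraction_unbound_blood(0.25, 1.15) == pytest.approx(0.2174, abs=2e-4)
        assert derive.fraction_unbound_blood(1.0, 1.0) == 1.0
        assert derive.fraction_unbound_blood(0.5, 2.0) == 0.25

    def test_blood_clearance_round_trip(self):
        assert derive.blood_clearance(51.75, 1.15) == pytest.approx(45.0)
        assert derive.blood_clearance(10.0, 1.0) == 10.0
        cb = derive.blood_clearance(37.0, 1.15)
        assert derive.plasma_clearance(cb, 1.15) == pytest.approx(37.0, rel=1e-14)


class TestWellStirred:
    def test_flow_limited_asymptote(self):
        assert derive.well_stirred_clearance(90, 0.2, 1e12) == pytest.approx(90, rel=1e-6)

    def test_clearance_limited_asymptote(self):
        cl = derive.well_stirred_clearance(90, 0.2, 0.01)
        assert cl == pytest.approx(0.2 * 0.01, rel=1e-4)

    def test_worked_inversion_pair(self):
        assert derive.well_stirred_clearance(90, 0.2175, 413.79) == pytest.approx(45.0, abs=1e-3)
        assert derive.intrinsic_from_blood_clearance(90, 45.0, 0.2175) == pytest.approx(413.79, abs=0.01)
        assert derive.intrinsic_from_blood_clearance(90, 0.0, 0.2175) == 0.0

    def test_extraction_at_or_above_flow_rejected(self):
        with pytest.raises(ExtractionExceedsFlowError):
            derive.intrinsic_from_blood_clearance(90, 90, 0.2175)
        with pytest.raises(ExtractionExceedsFlowError):
            derive.intrinsic_from_blood_clearance(90, 95, 0.2175)

    @settings(max_examples=200, derandomize=True)
    @given(
        q_h=st.floats(1.0, 500.0),
        fu_b=st.floats(0.01, 1.0),
        extraction=st.floats(0.01, 0.99),
    )
    def test_inversion_is_exact(self, q_h, fu_b, extraction):
        cl_blood = extraction * q_h
        clint = derive.intrinsic_from_blood_clearance(q_h, cl_blood, fu_b)
        back = derive.well_stirred_clearance(q_h, fu_b, clint)
        assert abs(back - cl_blood) / cl_blood < 1e-10

    @settings(max_examples=100, derandomize=True)
    @given(
        q_h=st.floats(10.0, 300.0),
        fu_b=st.floats(0.05, 1.0),
        clint=st.floats(0.1, 2000.0),
    )
    def test_monotone_and_bounded_by_flow(self, q_h, fu_b, clint):
        cl = derive.well_stirred_clearance(q_h, fu_b, clint)
        assert cl < q_h
        assert derive.well_stirred_clearance(q_h * 1.1, fu_b, clint) >= cl
        assert derive.well_stirred_clearance(q_h, min(fu_b * 1.1, 1.0), clint) >= cl
        assert derive.well_stirred_clearance(q_h, fu_b, clint * 1.1) >= cl


class TestScaling:
    def test_worked_example(self):
        got = derive.scale_intrinsic(186.0, LIVER, "HEP")
        assert got == pytest.approx(17.22, abs=0.01)

    def test_unit_conversion_factor(self):
        tiny = LiverScalars(liver_weight=1.0, hpgl=1.0, mppgl=1.0, cppgl=1.0)
        assert derive.scale_intrinsic(1.0, tiny, "HLM") == pytest.approx(1e6 / 60)

    @settings(max_examples=100, derandomize=True)
    @given(
        cl=st.floats(0.1, 1000.0),
        lw=st.floats(500.0, 3000.0),
        factor=st.floats(10.0, 200.0),
        system=st.sampled_from(["HEP", "HLM", "HLC"]),
    )
    def test_round_trip_identity(self, cl, lw, factor, system):
        liver = LiverScalars(liver_weight=lw, hpgl=factor, mppgl=factor, cppgl=factor)
        per_unit = derive.scale_intrinsic(cl, liver, system)
        assert abs(derive.unscale_intrinsic(per_unit, liver, system) - cl) / cl < 1e-12
        # reciprocal changes of liver weight and per-gram factor cancel
        liver2 = LiverScalars(liver_weight=2 * lw, hpgl=factor / 2,
                              mppgl=factor / 2, cppgl=factor / 2)
        assert derive.scale_intrinsic(cl, liver2, system) == pytest.approx(per_unit, rel=1e-12)

    def test_unknown_system_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            derive.scale_intrinsic(10.0, LIVER, "S9")


class TestMetabolicDistribution:
    def test_assigned_shares(self):
        split = MetabolicSplit()
        out = derive.distribute_metabolic(
            {"hep": 30.38, "hlm": 86.29, "hlc": 38.74}, split)
        assert out["hlm"] == pytest.approx(86.29 * 0.37)
        assert out["hep"] == pytest.approx(30.38 * 0.03)

    def test_degenerate_split(self):
        split = MetabolicSplit(frac_hlm=1.0, frac_hlc=0.0, frac_hep=0.0)
        out = derive.distribute_metabolic({"hep": 30.38, "hlm": 86.29, "hlc": 38.74}, split)
        assert out == {"hlm": pytest.approx(86.29), "hlc": 0.0, "hep": 0.0}

    def test_split_must_sum_to_one(self):
        with pytest.raises(ValueError):
            MetabolicSplit(frac_hlm=0.5, frac_hlc=0.5, frac_hep=0.5)

    def test_hep_and_distributed_modes_agree_on_whole_liver(self):
        """Total metabolic clearance is mode-independent after rescaling."""
        study = make_training_study(n=6, seed=11, noise_cv=0.0)
        common = dict(
            physchem=presets.DOX_PHYSCHEM, fractions=presets.DOX_ELIMINATION,
            vss_minimal=31.923, q_sac=212.0,
        )
        m_hep, _ = derive_drug_model(
            study.cohort, choices={"renal": "A", "metabolic": "C", "distribution": "E"},
            **common)
        m_dist, _ = derive_drug_model(
            study.cohort, choices={"renal": "A", "metabolic": "D", "distribution": "E"},
            **common)
        liver = LiverScalars(1400.0, 99.0, 35.0, 78.0)
        total_hep = m_hep.whole_liver_clint_met(liver)
        total_dist = m_dist.whole_liver_clint_met(liver)
        assert total_dist == pytest.approx(total_hep, rel=1e-9)


class TestMassBalancePartition:
    def test_elimination_routes_reconstruct_unity(self):
        f = presets.DOX_ELIMINATION
        bile_of_hepatic = derive.biliary_fraction_of_hepatic(f.f_bile, f.f_e)
        hepatic_total = 1.0 - f.f_e
        met_route = hepatic_total * (1.0 - bile_of_hepatic)
        bile_route = hepatic_total * bile_of_hepatic
        assert bile_route + met_route + f.f_e == pytest.approx(1.0, abs=1e-12)
        assert bile_of_hepatic == pytest.approx(0.4494, abs=1e-4)

    def test_biliary_fraction_edge_cases(self):
        assert derive.biliary_fraction_of_hepatic(0.0, 0.3) == 0.0
        assert derive.biliary_fraction_of_hepatic(0.5, 0.0) == 0.5
        with pytest.raises(ValueError):
            derive.biliary_fraction_of_hepatic(0.4, 1.0)

    def test_fraction_type_invariants(self):
        with pytest.raises(ValueError):
            EliminationFractions(0.5, 0.5, 0.5)


class TestDeriveDrugModel:
    CHOICES = {"renal": "A", "metabolic": "D", "distribution": "E"}

    def _derive(self, cohort, **kw):
        args = dict(physchem=presets.DOX_PHYSCHEM,
                    fractions=presets.DOX_ELIMINATION,
                    choices=self.CHOICES, vss_minimal=31.923, q_sac=212.0)
        args.update(kw)
        return derive_drug_model(cohort, **args)

    def test_single_patient_equals_cohort_mean(self):
        rec = PatientRecord(id="p1", age=55, bsa=1.75, scr=85,
                            cl_plasma=50.0, cl_renal=5.5, weight=70.0)
        model, report = self._derive([rec])
        assert len(report.per_patient) == 1
        assert model.ref_cl_renal == pytest.approx(
            report.per_patient["ref_cl_renal_L_h"].iloc[0])

    def test_per_patient_chain_inverts_to_input_clearance(self):
        """Forward-simulating each patient's derived values returns CL_P."""
        study = make_training_study(n=6, seed=7, noise_cv=0.0)
        _, report = self._derive(study.cohort)
        fu_b = derive.fraction_unbound_blood(0.25, 1.15)
        for rec in study.cohort:
            row = report.per_patient.loc[rec.id]
            cl_hb = derive.well_stirred_clearance(
                row["q_hepatic_L_h"], fu_b, row["clint_whole_liver_L_h"])
            cl_p = derive.plasma_clearance(cl_hb, 1.15) + rec.cl_renal
            assert cl_p == pytest.approx(rec.cl_plasma, rel=1e-10)

    def test_extraction_outlier_excluded_and_logged(self, caplog):
        study = make_training_study(n=4, seed=7, noise_cv=0.0,
                                    include_extraction_outlier=True)
        with caplog.at_level("WARNING", logger="doxopbpk.derive"):
            model, report = self._derive(study.cohort)
        assert len(report.per_patient) == 4
        assert [pid for pid, _ in report.excluded] == ["outlier"]
        assert "exceeds" in report.excluded[0][1] or ">=" in report.excluded[0][1]
        assert any("outlier" in r.message for r in caplog.records)
        assert model.provenance["n_excluded"] == 1

    def test_summary_reports_cv(self):
        study = make_training_study(n=6, seed=9, noise_cv=0.0)
        _, report = self._derive(study.cohort)
        assert "cv_pct" in report.summary.columns
        assert (report.summary.loc["clint_whole_liver_L_h", "cv_pct"] > 0)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            self._derive([])

    def test_model_json_round_trip(self, tmp_path):
        study = make_training_study(n=3, seed=1, noise_cv=0.0)
        model, _ = self._derive(study.cohort)
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = DrugModel.from_json(path)
        assert loaded.ref_cl_renal == model.ref_cl_renal
        assert loaded.physchem == model.physchem
        assert loaded.v_sac == model.v_sac


def test_cohort_csv_round_trip(tmp_path):
    study = make_training_study(n=4, seed=2, noise_cv=0.0)
    path = tmp_path / "cohort.csv"
    derive.write_cohort_csv(study.cohort, path)
    back = derive.read_cohort_csv(path)
    assert [r.id for r in back] == [r.id for r in study.cohort]
    assert back[0].cl_plasma == pytest.approx(study.cohort[0].cl_plasma)


def test_patient_record_invariants():
    with pytest.raises(ValueError):
        PatientRecord(id="x", age=50, bsa=1.8, scr=80, cl_plasma=40, cl_renal=45)
    with pytest.raises(ValueError):
        PatientRecord(id="x", age=-1, bsa=1.8, scr=80, cl_plasma=40, cl_renal=4)
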