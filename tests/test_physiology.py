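"""Virtual-subject construction, scaling and disease adjustment."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pedmab.drugs import get_drug
from pedmab.exceptions import ConfigError, RangeError, UnsupportedAgeError
from pedmab.physiology import (BodyPhysiology, TISSUES, apply_disease_modifiers,
                               build_adult_physiology, build_pediatric_physiology,
                               reduce_tissues)


class TestAdultBuilder:
    def test_reference_subject_plasma_volume_scale(self):
        body = build_adult_physiology(27.6, 70, "male")
        assert body.V_plasma == pytest.approx(3126.0, rel=0.05)
        assert {t.name for t in body.tissues} == set(TISSUES)

    def test_deterministic(self):
        a = build_adult_physiology(30, 70, "male")
        b = build_adult_physiology(30, 70, "male")
        assert a == b

    def test_heavier_subject_has_strictly_larger_tissues(self):
        light = build_adult_physiology(30, 70, "male")
        heavy = build_adult_physiology(30, 140, "male")
        for tl, th in zip(light.tissues, heavy.tissues):
            assert th.V_total > tl.V_total
            assert th.Q > tl.Q

    @pytest.mark.parametrize("age,weight", [(17, 70), (95, 70), (30, 20), (30, 250)])
    def test_out_of_range_inputs_rejected(self, age, weight):
        with pytest.raises(RangeError):
            build_adult_physiology(age, weight)

    def test_flow_balance_closed_circulation(self):
        body = build_adult_physiology(40, 80)
        # star topology: plasma outflow to tissues = vascular returns + lymph
        q_in = sum(t.Q for t in body.tissues)
        q_back = sum(t.Q - t.L for t in body.tissues)
        assert q_in == pytest.approx(q_back + body.total_lymph_flow, rel=1e-12)
        assert q_in == pytest.approx(body.cardiac_plasma_flow, rel=0.01)

    @given(w=st.floats(30, 200), w2=st.floats(30, 200))
    def test_volumes_and_flows_monotone_in_weight(self, w, w2):
        if w > w2:
            w, w2 = w2, w
        a, b = build_adult_physiology(30, w), build_adult_physiology(30, w2)
        for ta, tb in zip(a.tissues, b.tissues):
            assert tb.V_total >= ta.V_total
            assert tb.Q >= ta.Q
            assert tb.L >= ta.L


class TestPediatricBuilder:
    def test_bev_virtual_patient_demographics(self):
        body = build_pediatric_physiology(13, 53.65, "male")
        assert body.demographics.age == 13
        assert body.demographics.weight == 53.65
        assert body.demographics.sex == "male"

    def test_inf_virtual_patient_demographics(self):
        body = build_pediatric_physiology(13, 42, "male")
        assert body.demographics.weight == 42

    @pytest.mark.parametrize("age,weight", [(13, 53.65), (13, 42), (4, 16.3), (2, 12.5)])
    def test_fcrn_identical_to_adult_everywhere(self, age, weight):
        adult = build_adult_physiology(30, 70)
        child = build_pediatric_physiology(age, weight)
        for ta, tc in zip(adult.tissues, child.tissues):
            assert tc.FcRn_conc == ta.FcRn_conc

    def test_pediatric_smaller_than_reference_adult(self):
        adult = build_adult_physiology(30, 70)
        child = build_pediatric_physiology(13, 42)
        assert child.V_plasma < adult.V_plasma
        assert child.total_tissue_volume < adult.total_tissue_volume

    def test_topology_preserved(self):
        adult = build_adult_physiology(30, 70)
        child = build_pediatric_physiology(8, 26)
        assert [t.name for t in adult.tissues] == [t.name for t in child.tissues]

    def test_neonate_rejected(self):
        with pytest.raises(UnsupportedAgeError):
            build_pediatric_physiology(1.0, 9.0)

    def test_implausible_weight_rejected(self):
        with pytest.raises(RangeError):
            build_pediatric_physiology(4, 60.0)

    def test_json_round_trip(self, tmp_path):
        body = build_pediatric_physiology(10, 32)
        path = tmp_path / "phys.json"
        body.to_json(path)
        back = BodyPhysiology.from_json(str(path))
        assert back == body


class TestReduceTissues:
    def test_subset_kept_in_order(self, adult_phys):
        small = reduce_tissues(adult_phys, ("muscle", "skin", "liver"))
        assert [t.name for t in small.tissues] == ["muscle", "skin", "liver"]

    def test_unknown_tissue_rejected(self, adult_phys):
        with pytest.raises(ConfigError):
            reduce_tissues(adult_phys, ("muscle", "gills"))


class TestDiseaseModifiers:
    def test_inf_kdeg_times_1p5_matches_reported_patient_value(self):
        drug, _ = get_drug("infliximab", "healthy")
        adjusted, _ = apply_disease_modifiers(drug, None, {"kdeg": 1.5})
        assert adjusted.kdeg == pytest.approx(1.34e4 * 1.5)
        # the reported patient value 2.00e4 reflects rounding; within 1%
        assert adjusted.kdeg == pytest.approx(2.00e4, rel=0.01)
        assert drug.kdeg == 1.34e4  # original untouched

    def test_bev_target_expression_doubling(self):
        drug, tmdd = get_drug("bevacizumab", "healthy")
        _, adjusted = apply_disease_modifiers(drug, tmdd, {"target_expression": 2.0})
        assert adjusted.ksyn == pytest.approx(2 * tmdd.ksyn)
        assert adjusted.baseline_conc == pytest.approx(3.92e-6)
        # reported patient expression (3.86e-6) is within 2% of the doubling
        assert adjusted.baseline_conc == pytest.approx(3.86e-6, rel=0.02)

    def test_identity_factor_is_identity(self):
        drug, tmdd = get_drug("bevacizumab", "healthy")
        d2, t2 = apply_disease_modifiers(drug, tmdd, {"kdeg": 1.0, "target_expression": 1.0})
        assert d2 == drug
        assert t2 == tmdd

    def test_unknown_modifier_rejected(self):
        drug, _ = get_drug("infliximab", "healthy")
        with pytest.raises(ConfigError):
            apply_disease_modifiers(drug, None, {"edema": 2.0})

    def test_nonpositive_factor_rejected(self):
        drug, _ = get_drug("infliximab", "healthy")
        with pytest.raises(RangeError):
            apply_disease_modifiers(drug, None, {"kdeg": 0.0})
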