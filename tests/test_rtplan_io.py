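import copy

import numpy as np
import pydicom
import pytest
from hypothesis import given, settings, strategies as st

from vmatadapt.errors import (
    ApertureGuardError,
    PlanFormatError,
    PlanIntegrityError,
    UnsupportedDeviceError,
)
from vmatadapt.rtplan_io import (
    cm_to_mm_string,
    control_point_table,
    format_ds,
    mm_string_to_cm,
    prepare_template,
    read_plan,
    write_plan,
)


def assert_docs_equal(d1, d2):
    assert len(d1.arcs) == len(d2.arcs)
    for a1, a2 in zip(d1.arcs, d2.arcs):
        assert a1.mlc_model == a2.mlc_model
        assert a1.n_control_points == a2.n_control_points
        for c1, c2 in zip(a1.control_points, a2.control_points):
            np.testing.assert_array_equal(c1.bank_a, c2.bank_a)
            np.testing.assert_array_equal(c1.bank_b, c2.bank_b)
            assert c1.cumulative_weight == c2.cumulative_weight
            assert c1.gantry_angle == c2.gantry_angle


class TestConversion:
    @pytest.mark.parametrize("cm,mm", [(1.83, "18.3"), (-0.5, "-5"),
                                       (0.15, "1.5"), (0.0, "0")])
    def test_known_strings(self, cm, mm):
        assert cm_to_mm_string(cm) == mm
        assert mm_string_to_cm(mm) == cm

    @settings(deadline=None, derandomize=True, max_examples=300)
    @given(st.integers(min_value=-200000, max_value=200000))
    def test_round_trip_bit_exact_for_wire_decimals(self, thousandth_cm):
        # values a DICOM export can carry (here 0.001 cm grid) round-trip
        # to the identical double, as do their pairwise averages
        from vmatadapt.adaptation import average_positions

        cm = thousandth_cm / 1000
        assert mm_string_to_cm(cm_to_mm_string(cm)) == cm
        mean = average_positions(cm, (thousandth_cm + 1) / 1000)
        assert mm_string_to_cm(cm_to_mm_string(mean)) == mean

    @settings(deadline=None, derandomize=True, max_examples=300)
    @given(st.integers(min_value=-2000, max_value=2000))
    def test_wire_values_stable(self, tenth_mm):
        # a typical exported value (0.1 mm precision) is read and rewritten
        # to the same decimal
        s = f"{tenth_mm / 10:.1f}"
        assert float(cm_to_mm_string(mm_string_to_cm(s))) == float(s)

    def test_format_ds_within_16_chars(self):
        for v in (1 / 3, 0.1 + 0.2, -123.456789012345):
            s = format_ds(v)
            assert len(s) <= 16
            assert float(s) == pytest.approx(v, rel=1e-9)
        # short decimals stay exact
        assert format_ds(0.123456) == "0.123456"


class TestReadPlan:
    def test_fixture_counts(self, fixture_docs):
        assert fixture_docs["hd_sliding_window"].arcs[0].n_control_points == 178
        assert fixture_docs["hd_single_cp"].arcs[0].n_control_points == 1
        for doc in fixture_docs.values():
            assert doc.arcs[0].mlc_model == "HD120"
            assert doc.machine_name == "HDL-1"

    def test_non_dicom_rejected(self, tmp_path):
        bogus = tmp_path / "notaplan.dcm"
        bogus.write_bytes(b"this is not dicom at all" * 10)
        with pytest.raises(PlanFormatError):
            read_plan(bogus)

    def test_wrong_modality_rejected(self, tmp_path, fixture_paths):
        ds = pydicom.dcmread(str(fixture_paths["hd_single_cp"]))
        ds.SOPClassUID = "1.2.840.10008.5.1.4.1.1.2"  # CT storage
        ds.Modality = "CT"
        out = tmp_path / "ct.dcm"
        ds.save_as(str(out), enforce_file_format=True)
        with pytest.raises(PlanFormatError, match="not an RT Plan"):
            read_plan(out)

    def test_unknown_boundary_pattern_rejected(self, tmp_path, fixture_paths):
        ds = pydicom.dcmread(str(fixture_paths["hd_single_cp"]))
        for bld in ds.BeamSequence[0].BeamLimitingDeviceSequence:
            if bld.RTBeamLimitingDeviceType == "MLCX":
                bld.LeafPositionBoundaries = [
                    str(float(v) + 3.0) for v in bld.LeafPositionBoundaries
                ]
        out = tmp_path / "oddmlc.dcm"
        ds.save_as(str(out), enforce_file_format=True)
        with pytest.raises(UnsupportedDeviceError):
            read_plan(out)

    def test_wrong_leaf_count_rejected(self, tmp_path, fixture_paths):
        ds = pydicom.dcmread(str(fixture_paths["hd_single_cp"]))
        for bld in ds.BeamSequence[0].BeamLimitingDeviceSequence:
            if bld.RTBeamLimitingDeviceType == "MLCX":
                bld.NumberOfLeafJawPairs = 80
        out = tmp_path / "mlc160.dcm"
        ds.save_as(str(out), enforce_file_format=True)
        with pytest.raises(UnsupportedDeviceError, match="160"):
            read_plan(out)

    def test_non_monotone_weights_rejected(self, tmp_path, fixture_paths):
        ds = pydicom.dcmread(str(fixture_paths["hd_ellipse"]))
        cps = ds.BeamSequence[0].ControlPointSequence
        cps[5].CumulativeMetersetWeight = "0.9"
        cps[6].CumulativeMetersetWeight = "0.1"
        out = tmp_path / "nonmono.dcm"
        ds.save_as(str(out), enforce_file_format=True)
        with pytest.raises(PlanIntegrityError, match="decreases"):
            read_plan(out)


class TestWritePlan:
    def test_round_trip_identity(self, tmp_path, fixture_paths):
        doc = read_plan(fixture_paths["hd_random"])
        out = tmp_path / "rt.dcm"
        write_plan(doc, out)
        assert_docs_equal(doc, read_plan(out))

    def test_refuses_overlapping_leaves(self, tmp_path, fixture_docs):
        doc = copy.deepcopy(fixture_docs["hd_ellipse"])
        cp = doc.arcs[0].control_points[3]
        cp.bank_a[30] = cp.bank_b[30] + 1.0
        with pytest.raises(ApertureGuardError, match="leaf pair 31"):
            write_plan(doc, tmp_path / "bad.dcm")

    def test_refuses_decreasing_weights(self, tmp_path, fixture_docs):
        doc = copy.deepcopy(fixture_docs["hd_ellipse"])
        doc.arcs[0].control_points[10].cumulative_weight = 0.01
        with pytest.raises(PlanIntegrityError, match="decreases"):
            write_plan(doc, tmp_path / "bad.dcm")


class TestPrepareTemplate:
    def test_template_structure(self, fixture_docs):
        doc = fixture_docs["hd_sliding_window"]
        tpl = prepare_template(doc, "SDL-2")
        assert tpl.machine_name == "SDL-2"
        arc = tpl.arcs[0]
        src = doc.arcs[0]
        assert arc.mlc_model == "Millennium120"
        assert arc.n_control_points == src.n_control_points
        np.testing.assert_array_equal(arc.weights(), src.weights())
        np.testing.assert_array_equal(arc.gantry_angles(), src.gantry_angles())
        assert np.all(arc.positions() == 0.0)  # leaves closed pending adaptation
        # SD MLC re-declared with 61 boundaries on the wire
        mlc = [b for b in tpl.dataset.BeamSequence[0].BeamLimitingDeviceSequence
               if b.RTBeamLimitingDeviceType == "MLCX"][0]
        assert len(mlc.LeafPositionBoundaries) == 61
        assert mm_string_to_cm(str(mlc.LeafPositionBoundaries[0])) == -20.0

    def test_fresh_identifiers(self, fixture_docs):
        doc = fixture_docs["hd_ellipse"]
        tpl = prepare_template(doc, "SDL-2")
        assert tpl.dataset.SOPInstanceUID != doc.dataset.SOPInstanceUID
        # deterministic: preparing twice yields the same fresh UID
        tpl2 = prepare_template(doc, "SDL-2")
        assert tpl.dataset.SOPInstanceUID == tpl2.dataset.SOPInstanceUID

    def test_template_writable_and_readable(self, tmp_path, fixture_docs):
        tpl = prepare_template(fixture_docs["hd_ellipse"], "SDL-2")
        out = tmp_path / "template.dcm"
        write_plan(tpl, out)
        back = read_plan(out)
        assert back.machine_name == "SDL-2"
        assert back.arcs[0].mlc_model == "Millennium120"


def test_control_point_table_shape(fixture_docs):
    df = control_point_table(fixture_docs["hd_single_cp"])
    assert len(df) == 60
    assert set(df.columns) >= {"beam", "control_point", "leaf_pair",
                               "bank_a_cm", "bank_b_cm"}
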