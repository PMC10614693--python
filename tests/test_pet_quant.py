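"""PET quantification: %ID/cc conversion, ROI statistics, blood subtraction,
fold changes, %ID/g, dynamic framing, ΔΔCt and R²."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sonopet import pet_quant as pq
from sonopet import synthetic
from sonopet.exceptions import (
    EmptyRoiError,
    GeometryError,
    IncompleteTableError,
    InvalidParameterError,
    MetadataError,
)


def make_volume(data, units="Bq/cc", **meta):
    return pq.PETVolume(data=np.asarray(data, dtype=float),
                        voxel_size_mm=(0.4, 0.4, 0.4), units=units, **meta)


class TestPercentIdConversion:
    def test_definition_at_injection_time(self):
        """1 MBq injected, 0.01 MBq/cc voxel, scan at injection -> 1 %ID/cc."""
        vol = make_volume(np.full((2, 2, 2), 0.01e6), isotope="Cu-64",
                          acquisition_time_h=0.0, injected_dose_bq=1e6)
        out = pq.to_percent_id_per_cc(vol)
        assert out.units == "%ID/cc"
        assert np.allclose(out.data, 1.0)

    def test_zero_activity_stays_zero(self):
        vol = make_volume(np.zeros((2, 2, 2)), isotope="F-18",
                          acquisition_time_h=0.5, injected_dose_bq=1e6)
        assert not pq.to_percent_id_per_cc(vol).data.any()

    def test_cu64_decay_correction_factor_at_21h(self):
        """At 21 h post injection the Cu-64 correction is 2**(21/12.701),
        checked against an independent half-life computation."""
        conc = 50.0
        vol = make_volume(np.full((1, 1, 1), conc), isotope="Cu-64",
                          acquisition_time_h=21.0, injected_dose_bq=1e4)
        out = pq.to_percent_id_per_cc(vol)
        expected = 100.0 * conc * 2.0 ** (21.0 / 12.701) / 1e4
        assert out.data[0, 0, 0] == pytest.approx(expected, rel=1e-12)

    def test_missing_metadata_rejected(self):
        with pytest.raises(MetadataError):
            pq.to_percent_id_per_cc(make_volume(np.ones((1, 1, 1)), injected_dose_bq=1e6))
        with pytest.raises(MetadataError):
            pq.to_percent_id_per_cc(make_volume(np.ones((1, 1, 1)), isotope="Cu-64"))
        already = make_volume(np.ones((1, 1, 1)), units="%ID/cc")
        with pytest.raises(MetadataError):
            pq.to_percent_id_per_cc(already)


class TestRoiStatistics:
    def test_uniform_volume(self):
        vol = make_volume(np.full((4, 4, 4), 2.7), units="%ID/cc")
        roi = pq.ROIMask(np.ones((4, 4, 4), dtype=bool), (0.4, 0.4, 0.4), "treated")
        stats = pq.roi_statistics(vol, roi)
        assert stats.mean == pytest.approx(2.7)
        assert stats.max == pytest.approx(2.7)
        assert stats.volume_mm3 == pytest.approx(64 * 0.4**3)

    def test_single_voxel_mask(self):
        data = np.zeros((3, 3, 3))
        data[1, 2, 0] = 5.5
        vol = make_volume(data, units="%ID/cc")
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 2, 0] = True
        stats = pq.roi_statistics(vol, pq.ROIMask(mask, (0.4, 0.4, 0.4)))
        assert stats.mean == stats.max == 5.5

    def test_noise_free_phantom_matches_truth(self):
        spec = synthetic.PhantomSpec(noise_scale=0.0)
        data, masks, truth = synthetic.make_pet_phantom(spec)
        vol = pq.PETVolume(data, spec.voxel_mm, units="%ID/cc")
        for label in ("treated", "contralateral"):
            stats = pq.roi_statistics(vol, pq.ROIMask(masks[label], spec.voxel_mm, label))
            assert stats.mean == pytest.approx(truth.roi_mean_post[label], rel=1e-12)
            assert stats.max == pytest.approx(truth.roi_max_post[label], rel=1e-12)

    def test_empty_mask_and_lattice_mismatch_rejected(self):
        vol = make_volume(np.ones((3, 3, 3)), units="%ID/cc")
        with pytest.raises(EmptyRoiError):
            pq.roi_statistics(vol, pq.ROIMask(np.zeros((3, 3, 3), bool), (0.4, 0.4, 0.4)))
        with pytest.raises(GeometryError):
            pq.roi_statistics(vol, pq.ROIMask(np.ones((2, 2, 2), bool), (0.4, 0.4, 0.4)))
        with pytest.raises(GeometryError):
            pq.roi_statistics(vol, pq.ROIMask(np.ones((3, 3, 3), bool), (0.5, 0.4, 0.4)))


class TestBloodSubtraction:
    def test_forced_arithmetic(self):
        assert pq.blood_subtract(1.00, 5.00, 0.04) == pytest.approx(0.80)

    def test_zero_blood_is_identity(self):
        assert pq.blood_subtract(2.5, 0.0) == 2.5

    def test_exact_cancellation(self):
        assert pq.blood_subtract(0.04 * 5.0, 5.0, 0.04) == pytest.approx(0.0)

    def test_invalid_vascular_fraction(self):
        with pytest.raises(InvalidParameterError):
            pq.blood_subtract(1.0, 1.0, v_b=1.0)

    @settings(max_examples=50, derandomize=True)
    @given(
        roi=st.floats(0, 10),
        b1=st.floats(0, 10),
        b2=st.floats(0, 10),
        s=st.floats(0.1, 5),
    )
    def test_monotone_decreasing_and_linear(self, roi, b1, b2, s):
        if b1 <= b2:
            assert pq.blood_subtract(roi, b1) >= pq.blood_subtract(roi, b2)
        lhs = pq.blood_subtract(s * roi, s * b1)
        assert lhs == pytest.approx(s * pq.blood_subtract(roi, b1), abs=1e-9)

    def test_quantify_flags_negative_results(self):
        data = np.full((3, 3, 3), 0.1)
        data[0, 0, 0] = 10.0  # hot blood pool voxel
        vol = make_volume(data, units="%ID/cc")
        roi_mask = np.zeros((3, 3, 3), bool)
        roi_mask[1, 1, 1] = True
        blood_mask = np.zeros((3, 3, 3), bool)
        blood_mask[0, 0, 0] = True
        res = pq.quantify(
            vol,
            pq.ROIMask(roi_mask, (0.4, 0.4, 0.4), "treated"),
            blood_roi=pq.ROIMask(blood_mask, (0.4, 0.4, 0.4), "cardiac_blood"),
        )
        assert res.mean_blood_subtracted == pytest.approx(0.1 - 0.04 * 10.0)
        assert res.negative_flag


class TestFoldChange:
    def test_reporter_uptake_fold_change(self):
        """Treated-mean 5.0 over no-FUS 0.67 %ID/cc reports as 7.5-fold."""
        assert pq.fold_change(5.0, 0.67) == 7.5

    def test_identity_and_simple_ratio(self):
        assert pq.fold_change(3.3, 3.3) == 1.0
        assert pq.fold_change(4.5, 1.5) == 3.0

    def test_invalid_reference(self):
        with pytest.raises(InvalidParameterError):
            pq.fold_change(1.0, 0.0)


class TestPercentIdPerGram:
    def test_zero_counts(self):
        assert pq.percent_id_per_g(0.0, 1e4, 0.5) == 0.0

    def test_doubling_mass_halves_value(self):
        v1 = pq.percent_id_per_g(5e4, 1e4, 0.5)
        v2 = pq.percent_id_per_g(5e4, 1e4, 1.0)
        assert v1 == pytest.approx(2 * v2)

    def test_zero_mass_rejected(self):
        with pytest.raises(InvalidParameterError):
            pq.percent_id_per_g(1.0, 1e4, 0.0)

    def test_biodist_table_round_trip(self):
        truth = {"liver": 18.3, "lungs": 7.1}
        table = synthetic.make_biodist_table(
            list(truth), truth, {"liver": 1.0, "lungs": 0.15}, counts_per_pct_id=5e3
        )
        out = pq.biodist_percent_id_per_g(table, 5e3)
        assert np.allclose(out["pct_id_per_g"], out["true_pct_id_per_g"])


class TestFrameScheme:
    def test_dynamic_30min_protocol(self):
        """15 s x 8, 60 s x 8, 300 s x 4 -> 20 frames, 1800 s total."""
        scheme = pq.build_frame_scheme([(15, 8), (60, 8), (300, 4)])
        assert scheme.n_frames == 20
        assert scheme.total_duration_s == 1800.0
        assert scheme.boundaries_s[1] == 15.0
        assert scheme.boundaries_s[8] == 120.0

    def test_single_frame(self):
        scheme = pq.build_frame_scheme([(10, 1)])
        assert scheme.n_frames == 1
        assert np.allclose(scheme.boundaries_s, [0.0, 10.0])

    def test_boundaries_strictly_increasing(self):
        scheme = pq.build_frame_scheme([(1, 3), (7, 2), (0.5, 4)])
        assert (np.diff(scheme.boundaries_s) > 0).all()

    def test_invalid_spec(self):
        with pytest.raises(InvalidParameterError):
            pq.build_frame_scheme([(0, 5)])


class TestDeltaDeltaCt:
    def test_identical_groups_give_unity(self):
        table = synthetic.make_qpcr_ct({"a": 1.0, "b": 1.0})
        assert pq.delta_delta_ct(table, "b", "a") == pytest.approx(1.0)

    def test_one_cycle_shift_doubles(self):
        table = synthetic.make_qpcr_ct({"ctl": 1.0, "fus": 2.0})
        assert pq.delta_delta_ct(table, "fus", "ctl") == pytest.approx(2.0)

    def test_102_fold_design_recovered_exactly(self):
        table = synthetic.make_qpcr_ct({"ctl": 1.0, "fus": 102.0}, noise_sd=0.0)
        assert pq.delta_delta_ct(table, "fus", "ctl") == pytest.approx(102.0, rel=1e-9)

    def test_constant_ct_shift_invariance(self):
        table = synthetic.make_qpcr_ct({"ctl": 1.0, "fus": 12.5}, noise_sd=0.3, seed=2)
        fold = pq.delta_delta_ct(table, "fus", "ctl")
        shifted = table.assign(ct=table["ct"] + 3.7)
        assert pq.delta_delta_ct(shifted, "fus", "ctl") == pytest.approx(fold, rel=1e-12)

    def test_missing_group_or_gene_rejected(self):
        table = synthetic.make_qpcr_ct({"ctl": 1.0, "fus": 2.0})
        with pytest.raises(IncompleteTableError):
            pq.delta_delta_ct(table, "nope", "ctl")
        broken = table[table["gene"] == "target"]
        with pytest.raises(IncompleteTableError):
            pq.delta_delta_ct(broken, "fus", "ctl")


class TestLinearR2:
    def test_exact_line(self):
        pairs = [(x, 2 * x + 1) for x in range(5)]
        assert pq.linear_r2(pairs) == pytest.approx(1.0)

    def test_constant_y(self):
        assert pq.linear_r2([(0, 3.0), (1, 3.0), (2, 3.0)]) == 0.0

    def test_hand_computed_ols(self):
        # x = [0,1,2], y = [0,1,1]: r^2 = 3/4 by direct OLS arithmetic
        assert pq.linear_r2([(0, 0), (1, 1), (2, 1)]) == pytest.approx(0.75)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            pq.linear_r2([(0, 1), (1, 2)])
        with pytest.raises(InvalidParameterError):
            pq.linear_r2([(1, 0), (1, 1), (1, 2)])


def test_run_config_defaults(tmp_path):
    path = tmp_path / "run.yaml"
    path.write_text("injected_dose_bq: 2.0e+6\nv_b: 0.05\n")
    cfg = pq.load_run_config(path)
    assert cfg["injected_dose_bq"] == 2.0e6
    assert cfg["v_b"] == 0.05
    assert cfg["isotope"] == "Cu-64" and cfg["decimals"] == 1
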