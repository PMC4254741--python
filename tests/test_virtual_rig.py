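import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from axobot.errors import CalibrationError, ParameterError, RangeError
from axobot.focus_metrics import focus_variance, log_filter
from axobot.virtual_rig import (DEFAULT_OPTICS, NOISELESS, OpticsConfig,
                                PhantomParams, PiezoModel, RigState,
                                StageModel, calibrate_z_offset, empty_phantom,
                                fire_ablation, make_phantom, render_frame,
                                world_to_px)

from _oracles import backlash_hand_simulation, binomial_ci
from conftest import rig_focused_at, soma_only_phantom, soma_with_axon_phantom


class TestOptics:
    def test_pixel_size_law(self):
        for mag in DEFAULT_OPTICS.magnifications:
            assert DEFAULT_OPTICS.pixel_size(mag.name) == 6.45 / mag.magnification

    def test_63x_pixel_size_is_102nm(self):
        assert DEFAULT_OPTICS.pixel_size("63x") == pytest.approx(0.102, abs=5e-4)

    def test_5x_pixel_size(self):
        assert DEFAULT_OPTICS.pixel_size("5x") == pytest.approx(1.29)

    def test_default_sensor_dimensions(self):
        assert DEFAULT_OPTICS.sensor_width_px == 1392
        assert DEFAULT_OPTICS.sensor_height_px == 1040

    def test_resolution_at_500nm(self):
        assert round(DEFAULT_OPTICS.resolution_nm("63x")) == 214
        # The 5x figure printed alongside (1.88 um) follows the same formula.
        assert DEFAULT_OPTICS.resolution_nm("5x") == pytest.approx(1875.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            OpticsConfig(camera_pixel_pitch=0.0)
        with pytest.raises(ParameterError):
            OpticsConfig(sensor_width_px=-1)
        with pytest.raises(ParameterError):
            DEFAULT_OPTICS.magnification("40x")


class TestMakePhantom:
    def test_default_construction(self):
        p = make_phantom(seed=1)
        labels = sorted(s.label for s in p.somas)
        assert labels == ["ALML", "ALMR", "AVM"]
        assert np.linalg.norm(p.orientation) == pytest.approx(1.0)
        # Each ALM soma has an anterior process extending toward the head.
        for soma in p.alm_somas:
            axon = next(a for a in p.axons if a.label == soma.label)
            head_dot = np.dot(axon.path[-1, :2] - soma.center[:2], p.orientation)
            assert head_dot > 0
        # AVM has no process at all.
        assert not any(a.label.startswith("AVM") for a in p.axons)

    def test_determinism(self):
        a, b = make_phantom(seed=42), make_phantom(seed=42)
        np.testing.assert_array_equal(a.body_spline, b.body_spline)
        for sa, sb in zip(a.somas, b.somas):
            np.testing.assert_array_equal(sa.center, sb.center)
        assert a.flags == b.flags

    def test_folded_fraction_within_binomial_ci(self):
        params = PhantomParams(folded_prob=0.05)
        rng = np.random.default_rng(123)
        n = 10_000
        folded = sum(make_phantom(params, rng).folded for _ in range(n))
        lo, hi = binomial_ci(n, 0.05, level=0.99)
        assert lo <= folded <= hi

    def test_invalid_range_rejected(self):
        with pytest.raises(ParameterError):
            PhantomParams(soma_depth_range=(9.0, 4.0))
        with pytest.raises(ParameterError):
            PhantomParams(folded_prob=1.5)

    def test_degenerate_flags_set(self):
        params = PhantomParams(missing_soma_prob=1.0)
        p = make_phantom(params, seed=0)
        assert p.flags["missing_soma"] and not p.somas


class TestRenderFrame:
    def test_empty_phantom_is_pure_background(self, small_optics):
        rig = RigState(objective="63x")
        frame = render_frame(empty_phantom(), rig, "fluorescence",
                             small_optics, NOISELESS)
        assert np.all(frame.raster == frame.raster.flat[0])
        noisy = render_frame(empty_phantom(), rig, "fluorescence",
                             small_optics, rng=np.random.default_rng(0))
        bg = 22.0
        assert abs(noisy.raster.mean() - bg) < 0.5
        # nothing above an 8x-mean soma threshold in pure noise
        assert not (noisy.raster > 8 * noisy.raster.mean()).any()

    def test_defocus_lowers_log_variance(self, small_optics):
        phantom = soma_only_phantom(depth=5.0)
        sharp = render_frame(phantom, rig_focused_at(5.0), "fluorescence",
                             small_optics, NOISELESS)
        blurred = render_frame(phantom, rig_focused_at(10.0), "fluorescence",
                               small_optics, NOISELESS)
        assert focus_variance(log_filter(sharp.raster)) > \
            focus_variance(log_filter(blurred.raster))

    def test_frame_metadata(self, small_optics):
        frame = render_frame(empty_phantom(), RigState(objective="63x"),
                             "fluorescence", small_optics)
        assert frame.pixel_size == pytest.approx(6.45 / 63)
        assert frame.shape == (256, 256)
        assert np.all(frame.raster >= 0)

    def test_render_determinism(self, small_optics):
        phantom = make_phantom(seed=5)
        frames = [
            render_frame(phantom, RigState(objective="63x"), "fluorescence",
                         small_optics, rng=np.random.default_rng(99))
            for _ in range(2)
        ]
        np.testing.assert_array_equal(frames[0].raster, frames[1].raster)

    def test_brightfield_worm_is_dark_on_light(self, mid_optics):
        phantom = make_phantom(seed=2)
        rig = RigState(objective="5x")
        frame = render_frame(phantom, rig, "brightfield", mid_optics, NOISELESS)
        baseline = render_frame(empty_phantom(), rig, "brightfield",
                                mid_optics, NOISELESS)
        row, col = world_to_px(phantom.centroid, rig, mid_optics)
        assert frame.raster[int(row), int(col)] < baseline.raster[int(row), int(col)]

    def test_severed_axon_renders_gap(self, mid_optics):
        phantom = soma_with_axon_phantom(depth=5.0)
        rig = rig_focused_at(5.0)
        cut_x_um = 15.0
        before = render_frame(phantom, rig, "fluorescence", mid_optics, NOISELESS)
        phantom.axons[0].severed_at = cut_x_um
        after = render_frame(phantom, rig, "fluorescence", mid_optics, NOISELESS)
        row, col = world_to_px((cut_x_um, 0.0), rig, mid_optics)
        r, c = int(round(row)), int(round(col))
        assert before.raster[r, c] > 2 * after.raster[r, c]
        # Away from the gap the axon is unchanged.
        _, col_far = world_to_px((cut_x_um + 8.0, 0.0), rig, mid_optics)
        assert after.raster[r, int(round(col_far))] == pytest.approx(
            before.raster[r, int(round(col_far))])

    def test_unknown_channel_rejected(self, small_optics):
        with pytest.raises(ParameterError):
            render_frame(empty_phantom(), RigState(), "darkfield", small_optics)


class TestStage:
    def test_moves_quantized_to_min_step(self):
        stage = StageModel()
        stage.move((0.234, 0.0, 0.0))
        assert stage.position[0] == pytest.approx(0.2)

    def test_zero_move_identity(self):
        stage = StageModel()
        stage.move((0.0, 0.0, 0.0))
        np.testing.assert_array_equal(stage.position, np.zeros(3))


class TestPiezoBacklash:
    def test_first_move_pays_deadband(self):
        piezo = PiezoModel(backlash_deadband=0.1)
        net = piezo.move((1.0, 0.0, 0.0))
        assert net[0] == pytest.approx(0.9)
        net = piezo.move((1.0, 0.0, 0.0))
        assert net[0] == pytest.approx(1.0)

    def test_reversal_pays_deadband_again(self):
        piezo = PiezoModel(backlash_deadband=0.1)
        piezo.move((1.0, 0.0, 0.0))
        net = piezo.move((-1.0, 0.0, 0.0))
        assert net[0] == pytest.approx(-0.9)

    def test_zero_delta_identity(self):
        piezo = PiezoModel()
        piezo.move((0.5, 0.0, 0.0))
        before = piezo.position.copy()
        piezo.move((0.0, 0.0, 0.0))
        np.testing.assert_array_equal(piezo.position, before)

    def test_out_of_range_command_rejected(self):
        piezo = PiezoModel()
        with pytest.raises(RangeError):
            piezo.move((10.2, 0.0, 0.0))
        np.testing.assert_array_equal(piezo.position, np.zeros(3))

    @given(st.lists(st.integers(min_value=-10, max_value=10).filter(lambda v: v != 0),
                    min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_backlash_conservation_against_hand_simulation(self, tenths):
        # commands in multiples of 0.1 um keep the oracle arithmetic exact
        deltas, total = [], 0.0
        for v in tenths:
            d = v / 10.0
            if abs(total + d) <= 10.0:     # stay inside the piezo range
                deltas.append(d)
                total += d
        if not deltas:
            return
        expected, _ = backlash_hand_simulation(deltas, deadband=0.1)
        piezo = PiezoModel(backlash_deadband=0.1)
        for d in deltas:
            piezo.move((d, 0.0, 0.0))
        assert piezo.position[0] == pytest.approx(expected[-1], abs=1e-9)
        # conservation: achieved = commanded - signed deadband per reversal
        signs = np.sign(deltas)
        is_change = [True] + list(signs[1:] != signs[:-1])
        signed_loss = sum(0.1 * s for s, ch in zip(signs, is_change) if ch)
        assert piezo.position[0] == pytest.approx(sum(deltas) - signed_loss,
                                                  abs=1e-9)

    def test_total_displacement_identity(self):
        # achieved = commanded - (number of direction changes) * deadband
        deltas = [0.5, 0.5, -0.3, 0.4, 0.4, -0.2]
        piezo = PiezoModel(backlash_deadband=0.1)
        for d in deltas:
            piezo.move((0.0, d, 0.0))
        signs = np.sign(deltas)
        changes = 1 + int(np.sum(signs[1:] != signs[:-1]))  # rest counts once
        signed_loss = sum(
            0.1 * s for s, is_change in zip(
                signs, [True] + list(signs[1:] != signs[:-1])) if is_change
        )
        assert piezo.position[1] == pytest.approx(sum(deltas) - signed_loss)


class TestFireAblation:
    def test_on_target_hit_and_sever(self):
        phantom = soma_with_axon_phantom(depth=5.0)
        rig = rig_focused_at(5.0)
        rig.laser_focus_offset_z = 0.7
        outcome = fire_ablation(phantom, rig, target=(30.0, 0.0))
        assert outcome.fired and outcome.hit
        assert phantom.axons[0].severed_at == pytest.approx(30.0, abs=1e-6)

    def test_far_miss(self):
        phantom = soma_with_axon_phantom()
        rig = rig_focused_at(5.0)
        rig.laser_focus_offset_z = 0.7
        outcome = fire_ablation(phantom, rig, target=(30.0, 5.0))
        assert outcome.fired and not outcome.hit
        assert phantom.axons[0].severed_at is None

    def test_no_defocus_means_no_cut(self):
        phantom = soma_with_axon_phantom()
        rig = rig_focused_at(5.0)
        rig.laser_focus_offset_z = 0.0
        outcome = fire_ablation(phantom, rig, target=(30.0, 0.0))
        assert not outcome.hit

    @pytest.mark.parametrize("offset,expected", [(0.5, True), (0.7, True),
                                                 (0.9, True), (0.4, False),
                                                 (1.0, False)])
    def test_z_offset_window(self, offset, expected):
        phantom = soma_with_axon_phantom()
        rig = rig_focused_at(5.0)
        rig.laser_focus_offset_z = offset
        assert fire_ablation(phantom, rig, target=(30.0, 0.0)).hit is expected

    def test_hit_monotone_in_lateral_error(self):
        rig = rig_focused_at(5.0)
        rig.laser_focus_offset_z = 0.7
        last_hit = True
        for dy in np.linspace(0.0, 1.0, 21):
            phantom = soma_with_axon_phantom()
            hit = fire_ablation(phantom, rig, target=(30.0, dy)).hit
            assert not (hit and not last_hit), "hit flipped back on larger error"
            last_hit = hit

    def test_default_pulse_train_recorded(self):
        phantom = soma_with_axon_phantom()
        rig = rig_focused_at(5.0)
        outcome = fire_ablation(phantom, rig, target=(30.0, 0.0))
        assert outcome.pulses == 300
        assert outcome.pulse_energy == pytest.approx(4.0)


class TestCalibrateZOffset:
    def test_waist_half_micron_below(self):
        offset = calibrate_z_offset(RigState(), waist_offset=0.5)
        assert offset == pytest.approx(0.5, abs=0.25)

    def test_waist_aligned(self):
        assert calibrate_z_offset(RigState(), waist_offset=0.0) == pytest.approx(0.0)

    def test_scan_excluding_waist_errors(self):
        with pytest.raises(CalibrationError):
            calibrate_z_offset(RigState(), waist_offset=0.5,
                               scan_range=(1.0, 3.0))

    def test_off_grid_waist_within_step(self):
        offset = calibrate_z_offset(RigState(), waist_offset=0.6)
        assert abs(offset - 0.6) <= 0.25
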