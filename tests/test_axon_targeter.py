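import numpy as np
import pytest

from axobot.axon_targeter import (ControlConfig, TargetLock, align_axon,
                                  anterior_offset_move, axon_profile_center,
                                  execute_axotomy, focus_on_axon)
from axobot.errors import (ContractViolation, NoAxonError, ParameterError)
from axobot.neuron_verifier import EdgeEvidence, NeuronID
from axobot.virtual_rig import (NOISELESS, PiezoModel, RigState, move_piezo,
                                move_stage, render_frame, world_to_px)

from _oracles import proportional_loop_hand_simulation
from conftest import soma_with_axon_phantom


def _alm(direction="right"):
    ev = EdgeEvidence(True, 50.0, 0.0, 10.0)
    return NeuronID("ALM", direction, (ev, ev))


def _aligned_rig(phantom, optics, y_offset_um=0.0):
    """Rig focused on the axon with the spot on (or offset from) the line."""
    soma = phantom.somas[0]
    rig = RigState(objective="63x")
    move_stage(rig, (0.0, 0.0, soma.center[2]))
    spot = optics.laser_spot_px()
    ps = optics.pixel_size("63x")
    # put the axon point x=+50 um under the spot column, offset in y
    dx = (spot[1] - (optics.sensor_width_px - 1) / 2) * ps - 50.0
    dy = (spot[0] - (optics.sensor_height_px - 1) / 2) * ps - y_offset_um
    move_stage(rig, (dx, dy, 0.0))
    return rig


class TestControlConfig:
    def test_gain_bounds(self):
        with pytest.raises(ParameterError):
            ControlConfig(gain_kp=0.0)
        with pytest.raises(ParameterError):
            ControlConfig(gain_kp=2.0)
        with pytest.raises(ParameterError):
            ControlConfig(tolerance_px=0.0)

    def test_defaults(self):
        cfg = ControlConfig()
        assert cfg.gain_kp == 0.9
        assert cfg.tolerance_px == 1.0
        assert cfg.max_iterations == 10
        assert cfg.anterior_offset == 50.0


class TestAnteriorOffsetMove:
    def test_zero_offset_identity(self):
        rig = RigState(objective="63x")
        anterior_offset_move(rig, _alm("left"), 0.0)
        np.testing.assert_array_equal(rig.stage.position, np.zeros(3))

    def test_unknown_direction_contract(self):
        with pytest.raises(ContractViolation):
            anterior_offset_move(RigState(), NeuronID("not_target", "unknown"))

    def test_moves_50um_along_head_direction(self):
        rig = RigState(objective="63x")
        anterior_offset_move(rig, _alm("right"), 50.0)
        assert abs(rig.stage.position[0]) == pytest.approx(50.0)
        rig2 = RigState(objective="63x")
        anterior_offset_move(rig2, _alm("left"), 50.0)
        assert rig2.stage.position[0] == pytest.approx(-rig.stage.position[0])

    def test_closed_loop_axon_lands_near_spot(self, mid_optics):
        # after the move the anterior axon crosses the FOV near the spot col
        phantom = soma_with_axon_phantom(depth=5.0, head_sign=1.0)
        soma = phantom.somas[0]
        rig = RigState(objective="63x")
        move_stage(rig, (0.0, 0.0, soma.center[2]))
        spot = mid_optics.laser_spot_px()
        ps = mid_optics.pixel_size("63x")
        # centre the soma on the spot first
        dx = (spot[1] - (mid_optics.sensor_width_px - 1) / 2) * ps
        dy = (spot[0] - (mid_optics.sensor_height_px - 1) / 2) * ps
        move_stage(rig, (dx, dy, 0.0))
        anterior_offset_move(rig, _alm("right"), 50.0)
        frame = render_frame(phantom, rig, "fluorescence", mid_optics, NOISELESS)
        row, col = world_to_px((50.0, 0.0), rig, mid_optics)
        assert abs(col - spot[1]) < 2.0
        assert frame.raster[int(round(row)), spot[1]] > 30.0


class TestAxonProfileCenter:
    def test_symmetric_profile_exact(self):
        img = np.zeros((201, 21))
        img[98:103, :] = [[1.0], [3.0], [5.0], [3.0], [1.0]]
        assert axon_profile_center(img, 10, window=100) == pytest.approx(100.0)

    def test_gaussian_subpixel_center(self):
        rows = np.arange(201)
        profile = 60.0 * np.exp(-0.5 * ((rows - 100.37) / 2.0) ** 2)
        img = np.tile(profile[:, None], (1, 21)) + 5.0
        assert axon_profile_center(img, 10, window=120) == pytest.approx(
            100.37, abs=0.05)

    def test_monte_carlo_snr10_mae(self):
        rows = np.arange(201)
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            true_center = 100.0 + rng.uniform(-5, 5)
            profile = 50.0 * np.exp(-0.5 * ((rows - true_center) / 2.0) ** 2)
            img = np.tile(profile[:, None], (1, 11))
            img = img + rng.normal(0, 5.0, img.shape)   # SNR 10
            est = axon_profile_center(img, 5, window=120)
            errs.append(abs(est - true_center))
        assert np.mean(errs) <= 0.5

    def test_flat_profile_raises(self):
        img = np.random.default_rng(0).normal(10.0, 1.0, (201, 21))
        with pytest.raises(NoAxonError):
            axon_profile_center(img, 10, window=100)


class TestAlignAxon:
    def test_already_aligned_zero_iterations(self, mid_optics):
        phantom = soma_with_axon_phantom(depth=5.0)
        rig = _aligned_rig(phantom, mid_optics, y_offset_um=0.0)
        lock = align_axon(rig, phantom, optics=mid_optics, noise=NOISELESS)
        assert lock.converged
        assert lock.iterations == 0
        assert abs(lock.final_error_px) <= 1.0

    def test_5um_offset_converges_within_10(self, mid_optics):
        phantom = soma_with_axon_phantom(depth=5.0)
        rig = _aligned_rig(phantom, mid_optics, y_offset_um=5.0)
        lock = align_axon(rig, phantom, optics=mid_optics,
                          rng=np.random.default_rng(3))
        assert lock.converged
        assert lock.iterations <= 10
        assert abs(lock.final_error_px) <= 1.0
        # initial error ~ 49 px at 63x
        assert abs(lock.error_trajectory[0]) == pytest.approx(
            5.0 / mid_optics.pixel_size("63x"), abs=2.0)

    def test_contraction_matches_hand_simulation(self, mid_optics):
        # zero backlash + noiseless: |e_{k+1}| = |1-Kp| |e_k| up to the
        # 25 nm piezo quantization (~0.25 px)
        phantom = soma_with_axon_phantom(depth=5.0)
        rig = _aligned_rig(phantom, mid_optics, y_offset_um=4.0)
        rig.piezo = PiezoModel(backlash_deadband=0.0)
        lock = align_axon(rig, phantom, optics=mid_optics, noise=NOISELESS)
        assert lock.converged
        e0 = lock.error_trajectory[0]
        oracle = proportional_loop_hand_simulation(e0, kp=0.9)
        for measured, predicted in zip(lock.error_trajectory, oracle):
            assert measured == pytest.approx(predicted, abs=0.45)

    def test_backlash_consumes_first_move(self, mid_optics):
        phantom = soma_with_axon_phantom(depth=5.0)
        rig = _aligned_rig(phantom, mid_optics, y_offset_um=4.0)
        lock = align_axon(rig, phantom, optics=mid_optics, noise=NOISELESS)
        assert lock.converged
        e0, e1 = lock.error_trajectory[:2]
        # e1 = (1 - Kp) e0 plus the deadband lost on the first move
        deadband_px = 0.1 / mid_optics.pixel_size("63x")
        predicted = (1 - 0.9) * e0 + np.sign(e0) * deadband_px
        assert e1 == pytest.approx(predicted, abs=0.6)

    def test_correction_beyond_piezo_range_fails(self, mid_optics):
        phantom = soma_with_axon_phantom(depth=5.0)
        rig = _aligned_rig(phantom, mid_optics, y_offset_um=12.0)
        cfg = ControlConfig(profile_window=300)
        lock = align_axon(rig, phantom, cfg, optics=mid_optics, noise=NOISELESS)
        assert not lock.converged

    def test_convergence_grid_zero_backlash(self, mid_optics):
        ps = mid_optics.pixel_size("63x")
        for e0_px in (5, 20, 40, 60, 80, 90):
            phantom = soma_with_axon_phantom(depth=5.0)
            rig = _aligned_rig(phantom, mid_optics, y_offset_um=e0_px * ps)
            rig.piezo = PiezoModel(backlash_deadband=0.0)
            cfg = ControlConfig(profile_window=220)
            lock = align_axon(rig, phantom, cfg, optics=mid_optics,
                              noise=NOISELESS)
            assert lock.converged, f"no convergence from {e0_px} px"
            assert lock.iterations <= 10

    def test_pixel_bookkeeping(self, mid_optics):
        assert mid_optics.pixel_size("63x") == 6.45 / 63


class TestExecuteAxotomy:
    def _converged(self, mid_optics, y_offset=0.0):
        phantom = soma_with_axon_phantom(depth=5.0)
        rig = _aligned_rig(phantom, mid_optics, y_offset_um=y_offset)
        lock = align_axon(rig, phantom, optics=mid_optics,
                          rng=np.random.default_rng(1))
        return phantom, rig, lock

    def test_converged_lock_hits(self, mid_optics):
        phantom, rig, lock = self._converged(mid_optics, y_offset=3.0)
        assert lock.converged
        rig.laser_focus_offset_z = 0.7
        outcome = execute_axotomy(rig, phantom, lock, optics=mid_optics)
        assert outcome.hit
        assert phantom.axons[0].severed_at is not None
        assert outcome.pulses == 300 and outcome.pulse_energy == 4.0

    def test_forced_4px_error_misses(self, mid_optics):
        phantom = soma_with_axon_phantom(depth=5.0)
        rig = _aligned_rig(phantom, mid_optics, y_offset_um=4 * 0.1024)
        rig.laser_focus_offset_z = 0.7
        lock = TargetLock(True, 1, 4.0)   # pretend convergence at 4 px
        outcome = execute_axotomy(rig, phantom, lock, optics=mid_optics)
        assert not outcome.hit
        assert outcome.lateral_error > 0.31

    def test_non_converged_lock_is_contract_violation(self, mid_optics):
        phantom, rig, _ = self._converged(mid_optics)
        with pytest.raises(ContractViolation):
            execute_axotomy(rig, phantom, TargetLock(False, 10, 5.0),
                            optics=mid_optics)


class TestFocusOnAxon:
    def test_refocuses_to_axon_plane(self, mid_optics):
        phantom = soma_with_axon_phantom(depth=5.0)
        rig = _aligned_rig(phantom, mid_optics)
        move_piezo(rig, (0.0, 0.0, 1.4))     # start 1.4 um off focus
        focus_on_axon(rig, phantom, optics=mid_optics,
                      rng=np.random.default_rng(2))
        assert abs(rig.focus_z - 5.0) <= 0.71
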