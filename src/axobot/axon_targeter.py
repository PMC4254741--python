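"""Step 4: anterior translation, axon fine-focus, sub-pixel alignment, cut.

After the neuron is verified, the coarse stage translates 50 um from the
soma toward the head, the piezo fine-focuses on the axon by comparing mean
intensities in a band around the ablation spot, and a proportional control
loop drives the piezo y-axis until the axon's sub-pixel centre lies within
about one pixel of the spot.  The loop error is the pixel distance between
the measured axon centre and the spot row; each iteration commands
``-gain_kp * error * pixel_size`` um.  Ten failed iterations flush the worm.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractViolation, NoAxonError, ParameterError, RangeError
from .focus_metrics import ZStack, axon_focus
from .neuron_verifier import NeuronID
from .virtual_rig.ablation import (AblationOutcome, fire_ablation,
                                   DEFAULT_PULSES, DEFAULT_PULSE_ENERGY_NJ)
from .virtual_rig.motion import RigState, move_piezo, move_stage
from .virtual_rig.optics import DEFAULT_OPTICS, OpticsConfig
from .virtual_rig.phantom import WormPhantom
from .virtual_rig.render import (NoiseConfig, DEFAULT_NOISE, px_to_world,
                                 render_frame)

__all__ = ["ControlConfig", "TargetLock", "anterior_offset_move",
           "axon_profile_center", "focus_on_axon", "align_axon",
           "execute_axotomy"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ControlConfig:
    gain_kp: float = 0.9
    tolerance_px: float = 1.0
    max_iterations: int = 10
    anterior_offset: float = 50.0      # um toward the head
    profile_window: int = 120          # rows sampled around the spot
    profile_avg_cols: int = 5          # +/- columns averaged
    detection_sigmas: float = 5.0      # axon-presence floor in noise sigmas
    refocus_retries: int = 2
    focus_halfspan_um: float = 1.4
    focus_band_rows: int = 21          # axon-focus ROI height
    focus_band_cols: int = 200

    def __post_init__(self) -> None:
        if not 0.0 < self.gain_kp <= 1.5:
            raise ParameterError(f"gain_kp must be in (0, 1.5], got {self.gain_kp}")
        if self.tolerance_px <= 0:
            raise ParameterError("tolerance_px must be > 0")


@dataclass
class TargetLock:
    converged: bool
    iterations: int
    final_error_px: float
    y_trajectory: list[float] = field(default_factory=list)  # piezo y, um
    error_trajectory: list[float] = field(default_factory=list)
    z_best: float = 0.0


def anterior_offset_move(rig: RigState, neuron: NeuronID,
                         offset: float = 50.0) -> RigState:
    """Translate the coarse stage ``offset`` um from the soma toward the head.

    With the sample-frame stage convention (+x command shifts image content
    right), viewing the anterior region on the image-left side requires a +x
    command, and vice versa.
    """
    if neuron.classification != "ALM" or neuron.head_direction == "unknown":
        raise ContractViolation("anterior move requires a verified ALM with "
                                "known head direction")
    sign = 1.0 if neuron.head_direction == "left" else -1.0
    move_stage(rig, (sign * offset, 0.0, 0.0))
    return rig


def axon_profile_center(image: np.ndarray, spot_col: int, window: int = 80,
                        spot_row: int | None = None, avg_cols: int = 5,
                        detection_sigmas: float = 5.0) -> float:
    """Sub-pixel row of the axon at ``spot_col``.

    The column profile at the spot (averaged over +/-``avg_cols`` columns)
    is background-subtracted; the intensity-weighted centroid of samples
    above a quarter of the peak gives the centre.  Raises
    :class:`NoAxonError` when no sample clears the noise floor.
    """
    img = np.asarray(image, dtype=float)
    H, W = img.shape
    if spot_row is None:
        spot_row = H // 2
    c_lo, c_hi = max(spot_col - avg_cols, 0), min(spot_col + avg_cols + 1, W)
    r_lo = max(spot_row - window // 2, 0)
    r_hi = min(spot_row + window // 2 + 1, H)
    profile = img[r_lo:r_hi, c_lo:c_hi].mean(axis=1)

    background = float(np.median(profile))
    p = profile - background
    sigma = 1.4826 * float(np.median(np.abs(p)))   # robust profile noise
    peak = float(p.max())
    if peak <= 0 or (sigma > 0 and peak < detection_sigmas * sigma):
        raise NoAxonError("no axon signal above background in the profile")

    # Soft threshold at a quarter of the peak: keeps the estimator symmetric
    # while suppressing noise tails (a hard cut biases off-grid centres).
    weights = np.clip(p - 0.25 * peak, 0.0, None)
    rows = np.arange(r_lo, r_hi, dtype=float)
    return float((weights * rows).sum() / weights.sum())


def focus_on_axon(rig: RigState, phantom: WormPhantom,
                  config: ControlConfig | None = None,
                  optics: OpticsConfig | None = None,
                  noise: NoiseConfig | None = None,
                  rng: np.random.Generator | None = None) -> float:
    """Piezo z-scan comparing mean intensity in a band around the spot.

    Returns the best piezo z offset (um, relative to the scan start) after
    moving there.
    """
    config = config or ControlConfig()
    optics = optics or DEFAULT_OPTICS
    noise = noise or DEFAULT_NOISE
    rng = rng if rng is not None else np.random.default_rng(0)
    spot_row, spot_col = optics.laser_spot_px()

    step = 0.7
    offsets = np.arange(-config.focus_halfspan_um,
                        config.focus_halfspan_um + step / 2, step)
    frames = []
    z_now = 0.0
    for z in offsets:
        move_piezo(rig, (0.0, 0.0, z - z_now))
        z_now = z
        frames.append(render_frame(phantom, rig, "fluorescence", optics, noise, rng))
    roi = (max(spot_row - config.focus_band_rows // 2, 0),
           max(spot_col - config.focus_band_cols // 2, 0),
           config.focus_band_rows, config.focus_band_cols)
    best = axon_focus(ZStack(frames), roi)
    move_piezo(rig, (0.0, 0.0, offsets[best] - z_now))
    return float(offsets[best])


def align_axon(rig: RigState, phantom: WormPhantom,
               config: ControlConfig | None = None,
               optics: OpticsConfig | None = None,
               noise: NoiseConfig | None = None,
               rng: np.random.Generator | None = None) -> TargetLock:
    """Close the proportional loop on the piezo y-axis.

    Iterates render -> measure pixel error -> command ``-Kp * e * ps`` until
    |e| <= tolerance (converged) or the iteration/retry budget is exhausted.
    A piezo range violation fails the lock immediately.
    """
    config = config or ControlConfig()
    optics = optics or DEFAULT_OPTICS
    noise = noise or DEFAULT_NOISE
    rng = rng if rng is not None else np.random.default_rng(0)
    ps = optics.pixel_size(rig.objective)
    spot_row, spot_col = optics.laser_spot_px()

    y_traj = [float(rig.piezo.position[1])]
    errors: list[float] = []
    retries = config.refocus_retries
    iterations = 0
    while True:
        frame = render_frame(phantom, rig, "fluorescence", optics, noise, rng)
        try:
            center = axon_profile_center(frame.raster, spot_col,
                                         config.profile_window, spot_row,
                                         config.profile_avg_cols,
                                         config.detection_sigmas)
        except NoAxonError:
            if retries > 0:
                retries -= 1
                focus_on_axon(rig, phantom, config, optics, noise, rng)
                continue
            return TargetLock(False, iterations,
                              float("nan"), y_traj, errors, rig.focus_z)
        error_px = center - spot_row
        errors.append(float(error_px))
        if abs(error_px) <= config.tolerance_px:
            return TargetLock(True, iterations, float(error_px), y_traj,
                              errors, rig.focus_z)
        if iterations >= config.max_iterations:
            log.info("align_axon: no convergence in %d iterations", iterations)
            return TargetLock(False, iterations, float(error_px), y_traj,
                              errors, rig.focus_z)
        try:
            move_piezo(rig, (0.0, -config.gain_kp * error_px * ps, 0.0))
        except RangeError:
            log.info("align_axon: piezo range exceeded")
            return TargetLock(False, iterations, float(error_px), y_traj,
                              errors, rig.focus_z)
        iterations += 1
        y_traj.append(float(rig.piezo.position[1]))


def execute_axotomy(rig: RigState, phantom: WormPhantom, lock: TargetLock,
                    pulses: int = DEFAULT_PULSES,
                    energy_nj: float = DEFAULT_PULSE_ENERGY_NJ,
                    optics: OpticsConfig | None = None) -> AblationOutcome:
    """Fire the pulse train at the ablation spot; requires a converged lock."""
    if not lock.converged:
        raise ContractViolation("refusing to fire with a non-converged lock")
    optics = optics or DEFAULT_OPTICS
    target = px_to_world(optics.laser_spot_px(), rig, optics)
    return fire_ablation(phantom, rig, target, pulses, energy_nj)
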