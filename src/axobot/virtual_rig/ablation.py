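"""Geometric laser ablation model and the z-offset calibration routine."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import CalibrationError
from .motion import RigState
from .phantom import WormPhantom

__all__ = ["AblationOutcome", "fire_ablation", "calibrate_z_offset",
           "HIT_TOLERANCE_UM", "Z_OFFSET_WINDOW_UM",
           "DEFAULT_PULSES", "DEFAULT_PULSE_ENERGY_NJ"]

# Half of the 620 nm 1/e^2 focal spot: the cut must land under the beam centre.
HIT_TOLERANCE_UM = 0.31
# The beam waist must sit this far below the visible focal plane.
Z_OFFSET_WINDOW_UM = (0.5, 0.9)
DEFAULT_PULSES = 300
DEFAULT_PULSE_ENERGY_NJ = 4.0


@dataclass
class AblationOutcome:
    fired: bool
    hit: bool
    lateral_error: float      # um to the nearest axon centreline
    axial_offset: float       # um below visible focus when fired
    pulses: int
    pulse_energy: float       # nJ

    def __post_init__(self) -> None:
        if self.hit and not self.fired:
            raise ValueError("hit implies fired")


def fire_ablation(phantom: WormPhantom, rig: RigState, target,
                  pulses: int = DEFAULT_PULSES,
                  energy_nj: float = DEFAULT_PULSE_ENERGY_NJ,
                  hit_tolerance: float = HIT_TOLERANCE_UM,
                  z_window: tuple[float, float] = Z_OFFSET_WINDOW_UM) -> AblationOutcome:
    """Fire a pulse train at world position ``target`` (x, y) um.

    The shot severs the nearest axon iff the lateral distance from target to
    its centreline is within ``hit_tolerance`` and the rig's laser focus
    offset lies inside ``z_window`` um below the visible focal plane.
    """
    axon, arc, dist = phantom.nearest_axon(np.asarray(target, dtype=float))
    lateral_error = float(dist) if axon is not None else float("inf")
    offset = rig.laser_focus_offset_z
    hit = (
        axon is not None
        and lateral_error <= hit_tolerance
        and z_window[0] <= offset <= z_window[1]
    )
    if hit:
        axon.severed_at = float(arc)
    return AblationOutcome(
        fired=True,
        hit=bool(hit),
        lateral_error=lateral_error,
        axial_offset=float(offset),
        pulses=int(pulses),
        pulse_energy=float(energy_nj),
    )


def _mark_diameter(dz_from_waist: float, waist_diameter: float,
                   rayleigh: float) -> float:
    """Apparent 2-D ablation-mark size for a Gaussian beam profile."""
    return waist_diameter * np.sqrt(1.0 + (dz_from_waist / rayleigh) ** 2)


def calibrate_z_offset(rig: RigState, glass_surface_z: float = 0.0,
                       waist_offset: float = 0.5,
                       waist_diameter: float = 0.62,
                       rayleigh: float = 0.8,
                       scan_range: tuple[float, float] = (-1.0, 3.0),
                       step: float = 0.25) -> float:
    """Locate the beam waist below the camera focus on a simulated glass mark.

    A surface ablation mark is imaged while the objective steps through
    ``scan_range`` (um relative to the camera-focused glass surface) in
    ``step`` increments; the offset at which the simulated 2-D mark profile
    is smallest is returned (positive = below the visible focal plane).

    Raises
    ------
    CalibrationError
        If the scan does not bracket a minimum (smallest mark at a scan
        boundary), i.e. the waist lies outside the scanned range.
    """
    offsets = np.arange(scan_range[0], scan_range[1] + step / 2, step)
    if len(offsets) < 3:
        raise CalibrationError("scan range too short to bracket a minimum")
    sizes = _mark_diameter(offsets - waist_offset, waist_diameter, rayleigh)
    i = int(np.argmin(sizes))
    if i == 0 or i == len(offsets) - 1:
        raise CalibrationError(
            f"no interior minimum of the ablation profile in {scan_range}"
        )
    return float(offsets[i])
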