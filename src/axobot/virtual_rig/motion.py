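"""Coarse stage and piezo actuator models, including piezo hysteresis.

The coarse stage quantizes every commanded move to its minimal incremental
motion (0.1 um) and is assumed backlash-compensated.  The piezo actuator has
a 25 nm step, a +/-10 um travel range per axis, and an open-loop hysteresis
modelled as a fixed deadband consumed whenever an axis changes direction
(the first move from rest also pays the deadband).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import RangeError

__all__ = ["StageModel", "PiezoModel", "RigState", "move_stage", "move_piezo"]


def _as_xyz(value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.shape != (3,):
        raise ValueError("expected an (x, y, z) triple")
    return arr.copy()


@dataclass
class StageModel:
    """Three-axis coarse translation stage."""

    min_step: float = 0.1           # um
    max_speed: float = 5.0          # mm/s, annotation only
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.position = _as_xyz(self.position)

    def move(self, delta) -> np.ndarray:
        """Apply a relative move quantized to ``min_step``; returns net motion."""
        delta = _as_xyz(delta)
        net = np.round(delta / self.min_step) * self.min_step
        self.position += net
        return net


@dataclass
class PiezoModel:
    """Three-axis open-loop piezo with range limit and backlash deadband."""

    min_step: float = 0.025         # um
    range_um: float = 10.0          # +/- per axis
    backlash_deadband: float = 0.1  # um lost on direction reversal
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    last_direction: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.position = _as_xyz(self.position)
        self.last_direction = _as_xyz(self.last_direction)

    def move(self, delta) -> np.ndarray:
        """Apply a relative move; returns the net (achieved) motion.

        The commanded end position of every axis must stay within
        +/-``range_um`` or :class:`RangeError` is raised and no axis moves.
        A direction reversal (including the first move of an axis) consumes
        ``backlash_deadband`` um before producing net motion.
        """
        delta = _as_xyz(delta)
        target = self.position + delta
        if np.any(np.abs(target) > self.range_um + 1e-9):
            raise RangeError(
                f"commanded piezo position {target} exceeds +/-{self.range_um} um"
            )
        net = np.zeros(3)
        for axis in range(3):
            d = delta[axis]
            if d == 0.0:
                continue
            sign = 1.0 if d > 0 else -1.0
            achieved = d
            if sign != self.last_direction[axis]:
                achieved -= sign * min(self.backlash_deadband, abs(d))
            achieved = np.round(achieved / self.min_step) * self.min_step
            self.position[axis] += achieved
            self.last_direction[axis] = sign
            net[axis] = achieved
        return net


@dataclass
class RigState:
    """Mutable state of the virtual rig.

    The sample-frame convention: commanding the stage (or piezo) by +d um in
    x shifts rendered image content by +d/pixel_size pixels to the right, so
    a feature seen e pixels right of a reference pixel is centred on it by
    commanding -e * pixel_size.
    """

    stage: StageModel = field(default_factory=StageModel)
    piezo: PiezoModel = field(default_factory=PiezoModel)
    objective: str = "5x"
    valve_states: dict = field(default_factory=dict)
    laser_focus_offset_z: float = 0.0   # um below visible focus

    @property
    def view_shift(self) -> np.ndarray:
        """Combined lateral (x, y) shift applied to image content, um."""
        return (self.stage.position + self.piezo.position)[:2]

    @property
    def focus_z(self) -> float:
        """Current focal-plane height above the cover glass, um."""
        return float(self.stage.position[2] + self.piezo.position[2])

    def set_objective(self, name: str) -> None:
        self.objective = name

    def set_valve(self, valve_id: str, open_: bool) -> None:
        self.valve_states[valve_id] = "open" if open_ else "closed"


def move_stage(rig: RigState, delta) -> RigState:
    """Relative coarse-stage move (quantized); returns the same rig."""
    rig.stage.move(delta)
    return rig


def move_piezo(rig: RigState, delta) -> RigState:
    """Relative piezo move with backlash; raises RangeError when out of range."""
    rig.piezo.move(delta)
    return rig
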