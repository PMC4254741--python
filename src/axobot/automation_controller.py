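"""Orchestration of the full per-worm cycle and population bookkeeping.

A worm passes through the symbolic valve program (stage, inject, cyclic
trap) and the four image-processing steps; any failure flushes it with the
failing step recorded as the flush reason, and per-step rejections are
bookkept as fractions of all processed worms.

Two execution modes exist.  ``imaging="full"`` runs the four steps
closed-loop against rendered frames; ``imaging="fast"`` decides step
outcomes directly from the phantom's degenerate-case flags, which is exact
for attrition statistics and cheap enough for large populations.  Simulated
step durations are drawn from configured distributions in both modes and
are labelled simulated: the package makes no wall-clock throughput claims.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .axon_targeter import (ControlConfig, TargetLock, align_axon,
                            anterior_offset_move, execute_axotomy,
                            focus_on_axon)
from .errors import AxobotError, InputError, ParameterError
from .neuron_verifier import RoiClippedError, VerifierConfig, verify_neuron
from .soma_finder import (SomaDetectionConfig, center_on_laser_spot,
                          coarse_focus_scan)
from .stats_reporting import AttritionSummary, attrition_summary
from .virtual_rig.ablation import (AblationOutcome, DEFAULT_PULSES,
                                   DEFAULT_PULSE_ENERGY_NJ)
from .virtual_rig.motion import RigState, move_stage
from .virtual_rig.optics import DEFAULT_OPTICS, OpticsConfig
from .virtual_rig.phantom import (PhantomParams, WormPhantom, empty_phantom,
                                  make_phantom)
from .virtual_rig.render import NoiseConfig, DEFAULT_NOISE, render_frame
from .worm_locator import LocatorConfig, locate_worm

__all__ = ["ValveStep", "ValveProgram", "default_valve_program",
           "StepDurationModel", "ControllerConfig", "AutomationRecord",
           "RunSummary", "conditional_flaw_probs", "run_worm_cycle",
           "run_population"]

log = logging.getLogger(__name__)

RunSummary = AttritionSummary

# Default per-step rejection fractions of all processed worms.
DEFAULT_REJECTION_FRACTIONS = (0.10, 0.10, 0.091, 0.035)
LOADING_HEAD_PRESSURE_KPA = 15.0


@dataclass(frozen=True)
class ValveStep:
    name: str
    open_valves: tuple[str, ...] = ()
    close_valves: tuple[str, ...] = ()
    head_pressure_kpa: float = LOADING_HEAD_PRESSURE_KPA
    duration_ms: float = 100.0
    flow_direction: str = "forward"    # forward | reverse | none

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ParameterError("valve step duration must be > 0")


@dataclass(frozen=True)
class ValveProgram:
    steps: tuple[ValveStep, ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ParameterError("valve program has no steps")
        terminal = self.steps[-1].name
        if terminal not in ("eject", "flush"):
            raise ParameterError("program must end in a terminal eject or flush step")

    @property
    def terminal(self) -> str:
        return self.steps[-1].name

    def step(self, name: str) -> ValveStep:
        for s in self.steps:
            if s.name == name:
                return s
        raise KeyError(name)


def default_valve_program(terminal: str = "eject",
                          inject_ms: float = 1100.0) -> ValveProgram:
    """The seven-phase staging/trapping/ejection program.

    Fill the loading chamber, stage one worm between the gate valves, close
    the gate, inject into the trap for 1000-1200 ms at ~65 kPa, immobilize
    with a cyclic close-open-close of the trapping membrane, axotomize, then
    eject (success) or flush (failure) at ~135 kPa.
    """
    if not 1000.0 <= inject_ms <= 1200.0:
        raise ParameterError("injection duration must lie in [1000, 1200] ms")
    if terminal not in ("eject", "flush"):
        raise ParameterError("terminal step must be 'eject' or 'flush'")
    steps = (
        ValveStep("fill", open_valves=("side_exits",),
                  close_valves=("V1", "V2", "V3", "V4", "V5"),
                  duration_ms=2000.0),
        ValveStep("stage", open_valves=("V1",), close_valves=("V2",),
                  duration_ms=500.0),
        ValveStep("gate_close", close_valves=("V1",), duration_ms=100.0),
        ValveStep("inject", open_valves=("V1", "V2", "V3"),
                  head_pressure_kpa=65.0, duration_ms=inject_ms,
                  flow_direction="reverse"),
        ValveStep("trap_cycle", close_valves=("V3",), duration_ms=600.0,
                  flow_direction="none"),
        ValveStep("axotomize", duration_ms=100.0, flow_direction="none"),
        ValveStep(terminal,
                  open_valves=("V3", "V5" if terminal == "eject" else "V4"),
                  head_pressure_kpa=135.0, duration_ms=400.0,
                  flow_direction="reverse"),
    )
    return ValveProgram(steps)


# The cyclic trapping actuation encoded on the trap_cycle step.
TRAP_CYCLE_PATTERN = ("close", "open", "close")


@dataclass(frozen=True)
class StepDurationModel:
    """Normal (mean, sd) seconds per step, truncated at ``floor_s``."""

    means: dict = field(default_factory=lambda: {
        "trap": 4.8, "coarse_focus": 3.5, "verify": 2.0, "axotomy": 5.7})
    sds: dict = field(default_factory=lambda: {
        "trap": 1.2, "coarse_focus": 1.5, "verify": 0.8, "axotomy": 2.1})
    floor_s: float = 0.2

    def draw(self, step: str, rng: np.random.Generator) -> float:
        return float(max(rng.normal(self.means[step], self.sds[step]),
                         self.floor_s))


@dataclass(frozen=True)
class ControllerConfig:
    rejection_fractions: tuple[float, float, float, float] = DEFAULT_REJECTION_FRACTIONS
    imaging: str = "fast"                     # "fast" | "full"
    phantom: PhantomParams = field(default_factory=PhantomParams)
    optics: OpticsConfig = field(default_factory=lambda: DEFAULT_OPTICS)
    noise: NoiseConfig = field(default_factory=lambda: DEFAULT_NOISE)
    locator: LocatorConfig = field(default_factory=LocatorConfig)
    soma: SomaDetectionConfig = field(default_factory=SomaDetectionConfig)
    verifier: VerifierConfig = field(default_factory=VerifierConfig)
    control: ControlConfig = field(default_factory=ControlConfig)
    durations: StepDurationModel = field(default_factory=StepDurationModel)
    valve_program: ValveProgram = field(default_factory=default_valve_program)
    laser_focus_offset_z: float = 0.7         # um below focus when firing
    pulses: int = DEFAULT_PULSES
    pulse_energy_nj: float = DEFAULT_PULSE_ENERGY_NJ

    def __post_init__(self) -> None:
        if self.imaging not in ("fast", "full"):
            raise ParameterError("imaging mode must be 'fast' or 'full'")
        f = self.rejection_fractions
        if len(f) != 4 or any(x < 0 for x in f) or sum(f) >= 1.0:
            raise ParameterError(
                "rejection fractions must be four non-negative values summing below 1")

    def trap_roi(self) -> tuple[int, int, int, int]:
        """Trapping-area ROI in the 5x frame (centred, ~72% x 77%)."""
        H, W = self.optics.sensor_height_px, self.optics.sensor_width_px
        rows, cols = int(0.77 * H), int(0.72 * W)
        return ((H - rows) // 2, (W - cols) // 2, rows, cols)

    def phantom_params(self) -> PhantomParams:
        """Phantom distribution with flaw probabilities matching attrition."""
        probs = conditional_flaw_probs(self.rejection_fractions)
        return replace(self.phantom, **probs)


def conditional_flaw_probs(fractions) -> dict[str, float]:
    """Convert rejection fractions of *total* into per-draw probabilities.

    Degenerate flags are drawn independently; conditioning on surviving the
    earlier steps means the draw probability for step k is
    ``f_k / (1 - sum(f_1..f_{k-1}))`` so that expected rejections per step,
    as fractions of all processed worms, equal the requested values.
    """
    f1, f2, f3, f4 = fractions
    q1 = f1
    q2 = f2 / (1.0 - f1) if f1 < 1 else 0.0
    q3 = f3 / (1.0 - f1 - f2)
    q4 = f4 / (1.0 - f1 - f2 - f3)
    for q in (q1, q2, q3, q4):
        if not 0.0 <= q <= 1.0:
            raise ParameterError(f"fractions {fractions} are not realisable")
    # Step-1 failures split between a folded worm and an off-centre trap.
    folded = q1 / 2.0
    off_center = (q1 - folded) / (1.0 - folded) if folded < 1 else 0.0
    return {
        "folded_prob": folded,
        "off_center_prob": off_center,
        "missing_soma_prob": q2,
        "weak_axon_prob": q3,
        "misaligned_axon_prob": q4,
    }


@dataclass
class AutomationRecord:
    worm_id: int
    step_reached: str                     # trap|coarse_focus|verify|axotomy|done
    outcome: str                          # success | flushed
    flush_reason: str | None = None
    step_durations_s: dict = field(default_factory=dict)
    target_lock: TargetLock | None = None
    ablation: AblationOutcome | None = None
    valve_terminal: str = "flush"

    def __post_init__(self) -> None:
        success = self.outcome == "success"
        done_and_hit = (self.step_reached == "done"
                        and self.ablation is not None and self.ablation.hit)
        if success != done_and_hit:
            raise InputError("outcome=success iff step_reached=done and ablation.hit")


def _flush(worm_id, reason, durations) -> AutomationRecord:
    log.info("worm %d flushed at %s", worm_id, reason)
    return AutomationRecord(worm_id, reason, "flushed", reason, durations,
                            valve_terminal="flush")


def run_worm_cycle(rig: RigState | None, phantom: WormPhantom,
                   config: ControllerConfig | None = None,
                   rng: np.random.Generator | None = None,
                   worm_id: int = 0) -> AutomationRecord:
    """Process one staged worm through the valve program and Steps 1-4."""
    config = config or ControllerConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    durations: dict[str, float] = {}

    def spend(step: str) -> None:
        durations[step] = config.durations.draw(step, rng)

    if config.imaging == "fast":
        spend("trap")
        if phantom.folded or phantom.flags.get("off_center"):
            return _flush(worm_id, "trap", durations)
        spend("coarse_focus")
        if phantom.flags.get("missing_soma"):
            return _flush(worm_id, "coarse_focus", durations)
        spend("verify")
        if phantom.flags.get("weak_axon"):
            return _flush(worm_id, "verify", durations)
        spend("axotomy")
        if phantom.flags.get("misaligned_axon"):
            return _flush(worm_id, "axotomy", durations)
        lock = TargetLock(True, int(rng.integers(1, 6)),
                          float(rng.uniform(0.0, 0.9)))
        ablation = AblationOutcome(True, True,
                                   float(rng.uniform(0.0, 0.1)),
                                   config.laser_focus_offset_z,
                                   config.pulses, config.pulse_energy_nj)
        return AutomationRecord(worm_id, "done", "success", None, durations,
                                lock, ablation, valve_terminal="eject")

    # ---- full closed-loop imaging mode -----------------------------------
    rig = rig if rig is not None else RigState()
    optics, noise = config.optics, config.noise
    try:
        # Step 1: bright-field worm localization at 5x.
        rig.set_objective("5x")
        spend("trap")
        baseline = render_frame(empty_phantom(), rig, "brightfield",
                                optics, noise, rng)
        frame = render_frame(phantom, rig, "brightfield", optics, noise, rng)
        location = locate_worm(frame, baseline, config.trap_roi(), config.locator)
        if location.status != "accepted":
            return _flush(worm_id, "trap", durations)
        move_stage(rig, (*location.stage_correction_um, 0.0))

        # Step 2: coarse fluorescence z-scan at 63x from the cover glass.
        rig.set_objective("63x")
        spend("coarse_focus")
        scan = coarse_focus_scan(rig, phantom, config.soma, optics, noise, rng)
        if not scan.found:
            return _flush(worm_id, "coarse_focus", durations)
        try:
            center_on_laser_spot(rig, scan.detection, None, optics)
        except AxobotError:
            return _flush(worm_id, "coarse_focus", durations)

        # Step 3: fine focus + flanking straight-edge verification.
        spend("verify")
        try:
            neuron = verify_neuron(phantom, rig, scan.detection,
                                   config.verifier, None, optics, noise, rng)
        except RoiClippedError:
            return _flush(worm_id, "verify", durations)
        if neuron.classification != "ALM":
            return _flush(worm_id, "verify", durations)

        # Step 4: anterior move, axon focus, proportional lock, fire.
        spend("axotomy")
        anterior_offset_move(rig, neuron, config.control.anterior_offset)
        focus_on_axon(rig, phantom, config.control, optics, noise, rng)
        lock = align_axon(rig, phantom, config.control, optics, noise, rng)
        if not lock.converged:
            return _flush(worm_id, "axotomy", durations)
        rig.laser_focus_offset_z = config.laser_focus_offset_z
        ablation = execute_axotomy(rig, phantom, lock, config.pulses,
                                   config.pulse_energy_nj, optics)
        if not ablation.hit:
            rec = _flush(worm_id, "axotomy", durations)
            rec.target_lock = lock
            rec.ablation = ablation
            return rec
        return AutomationRecord(worm_id, "done", "success", None, durations,
                                lock, ablation, valve_terminal="eject")
    except AxobotError as exc:                      # simulator fault
        log.warning("worm %d: rig error %s", worm_id, exc)
        reason = "trap" if not durations else list(durations)[-1]
        return _flush(worm_id, reason, durations)


def run_population(n: int, config: ControllerConfig | None = None,
                   seed: int = 0) -> tuple[RunSummary, list[AutomationRecord]]:
    """Run ``n`` independent worm cycles; deterministic for a fixed seed."""
    if n < 1:
        raise ParameterError("population size must be >= 1")
    config = config or ControllerConfig()
    params = config.phantom_params()
    records = []
    for worm_id in range(n):
        rng = np.random.default_rng([seed, worm_id])
        phantom = make_phantom(params, rng)
        records.append(run_worm_cycle(None, phantom, config, rng, worm_id))
    return attrition_summary(records), records
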