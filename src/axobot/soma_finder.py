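"""Step 2: coarse z-scan for a neuronal cell body in the small FOV.

Fluorescence frames are thresholded at 8x their mean intensity while the
focal plane advances in 2.5 um steps from the cover glass into the worm.
The scan stops at the first connected component whose equivalent diameter
lies inside the 2-6 um gate and whose circularity (4*pi*A/P^2) passes; after
ten fruitless iterations the worm is rejected.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label, regionprops

from .errors import TargetingError
from .focus_metrics import ZStack
from .virtual_rig.motion import RigState, move_stage
from .virtual_rig.optics import DEFAULT_OPTICS, OpticsConfig
from .virtual_rig.phantom import WormPhantom
from .virtual_rig.render import (CameraFrame, NoiseConfig, DEFAULT_NOISE,
                                 render_frame)

__all__ = ["SomaDetectionConfig", "SomaDetection", "SomaScanResult",
           "detect_circular_feature", "coarse_focus_scan",
           "center_on_laser_spot"]


@dataclass(frozen=True)
class SomaDetectionConfig:
    threshold_factor: float = 8.0              # x mean frame intensity
    diameter_gate_um: tuple[float, float] = (2.0, 6.0)
    min_circularity: float = 0.6
    coarse_step_um: float = 2.5
    max_iterations: int = 10


@dataclass
class SomaDetection:
    center_px: tuple[float, float]     # (row, col), intensity-weighted
    equivalent_diameter_um: float
    z_found_um: float
    iterations_used: int
    circularity: float
    mean_intensity: float


@dataclass
class SomaScanResult:
    status: str                        # "found" | "rejected"
    detection: SomaDetection | None
    iterations_used: int

    @property
    def found(self) -> bool:
        return self.status == "found"


def detect_circular_feature(frame: CameraFrame,
                            config: SomaDetectionConfig | None = None) -> SomaDetection | None:
    """Find a soma-like blob in one fluorescence frame, or None.

    The frame is binarized at ``threshold_factor`` times its mean intensity;
    among the 8-connected components, those inside the diameter gate with
    circularity >= ``min_circularity`` qualify, and the brightest (highest
    mean intensity) wins.
    """
    config = config or SomaDetectionConfig()
    img = frame.raster
    threshold = config.threshold_factor * float(img.mean())
    bw = img > threshold
    if not bw.any():
        return None
    lo, hi = config.diameter_gate_um
    best: SomaDetection | None = None
    for region in regionprops(label(bw, connectivity=2), intensity_image=img):
        diam_um = region.equivalent_diameter_area * frame.pixel_size
        if not (lo <= diam_um <= hi):
            continue
        perimeter = region.perimeter
        circ = 1.0 if perimeter == 0 else min(1.0, 4.0 * np.pi * region.area / perimeter**2)
        if circ < config.min_circularity:
            continue
        if best is None or region.intensity_mean > best.mean_intensity:
            r, c = region.centroid_weighted
            best = SomaDetection(
                center_px=(float(r), float(c)),
                equivalent_diameter_um=float(diam_um),
                z_found_um=frame.z_position,
                iterations_used=0,
                circularity=float(circ),
                mean_intensity=float(region.intensity_mean),
            )
    return best


def coarse_focus_scan(rig: RigState, phantom_or_stack,
                      config: SomaDetectionConfig | None = None,
                      optics: OpticsConfig | None = None,
                      noise: NoiseConfig | None = None,
                      rng: np.random.Generator | None = None) -> SomaScanResult:
    """Advance the focal plane in coarse steps until a soma appears.

    ``phantom_or_stack`` is either a :class:`WormPhantom` (frames are
    acquired closed-loop through the rig, starting at the current focus and
    stepping ``coarse_step_um`` deeper each iteration) or a pre-recorded
    :class:`ZStack` for offline analysis.  Rejection after
    ``max_iterations`` fruitless frames is a value, not an exception.
    """
    config = config or SomaDetectionConfig()
    optics = optics or DEFAULT_OPTICS
    noise = noise or DEFAULT_NOISE
    rng = rng if rng is not None else np.random.default_rng(0)

    if isinstance(phantom_or_stack, ZStack):
        frames = list(phantom_or_stack.frames)[: config.max_iterations]
        for i, frame in enumerate(frames, start=1):
            det = detect_circular_feature(frame, config)
            if det is not None:
                det.iterations_used = i
                return SomaScanResult("found", det, i)
        return SomaScanResult("rejected", None, len(frames))

    phantom: WormPhantom = phantom_or_stack
    for i in range(1, config.max_iterations + 1):
        frame = render_frame(phantom, rig, "fluorescence", optics, noise, rng)
        det = detect_circular_feature(frame, config)
        if det is not None:
            det.iterations_used = i
            return SomaScanResult("found", det, i)
        if i < config.max_iterations:
            move_stage(rig, (0.0, 0.0, config.coarse_step_um))
    return SomaScanResult("rejected", None, config.max_iterations)


def center_on_laser_spot(rig: RigState, det: SomaDetection,
                         laser_spot_px: tuple[int, int] | None = None,
                         optics: OpticsConfig | None = None,
                         max_translation_um: float = 250.0) -> RigState:
    """Translate the coarse stage so the soma lands on the laser-spot pixel.

    Raises :class:`TargetingError` when the required translation exceeds
    ``max_translation_um`` (the worm cannot be that far off inside the trap).
    """
    optics = optics or DEFAULT_OPTICS
    spot = laser_spot_px or optics.laser_spot_px()
    ps = optics.pixel_size(rig.objective)
    err_row = det.center_px[0] - spot[0]
    err_col = det.center_px[1] - spot[1]
    dx, dy = -err_col * ps, -err_row * ps
    if np.hypot(dx, dy) > max_translation_um:
        raise TargetingError(
            f"required centering move ({dx:.1f}, {dy:.1f}) um exceeds trap extent"
        )
    move_stage(rig, (dx, dy, 0.0))
    return rig
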