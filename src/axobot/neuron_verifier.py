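"""Step 3: verify the detected soma is an ALM and find worm orientation.

Two 150x200-pixel regions flanking the soma are searched for a straight,
near-horizontal axonal feature with a rotate-and-project line accumulator
(a Radon-style search restricted to +/-30 degrees).  Presence of a straight
edge on either side identifies the ALM; the brighter side points toward the
head.  The AVM soma has no straight process in the small FOV and fails the
search, so the worm is flushed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import TargetingError
from .focus_metrics import FocusMetricConfig, ZStack, fine_focus
from .soma_finder import SomaDetection
from .virtual_rig.motion import RigState, move_piezo
from .virtual_rig.optics import DEFAULT_OPTICS, OpticsConfig
from .virtual_rig.phantom import WormPhantom
from .virtual_rig.render import NoiseConfig, DEFAULT_NOISE, render_frame

__all__ = ["VerifierConfig", "EdgeEvidence", "NeuronID", "RoiClippedError",
           "flanking_rois", "detect_straight_edge", "classify_neuron",
           "verify_neuron"]

Rect = tuple[int, int, int, int]   # (row0, col0, rows, cols), half-open


class RoiClippedError(TargetingError):
    """A flanking ROI clipped below half its nominal area (flush)."""


@dataclass(frozen=True)
class VerifierConfig:
    roi_rows: int = 150
    roi_cols: int = 200
    max_angle_deg: float = 30.0
    angle_step_deg: float = 3.0
    strength_sigmas: float = 6.0       # line strength in noise sigmas
    min_coverage: float = 0.5          # fraction of columns lit along the line
    min_roi_area_frac: float = 0.5
    fine_focus_halfspan_um: float = 2.1


@dataclass
class EdgeEvidence:
    present: bool
    strength: float                    # peak projection in noise sigmas
    angle: float                       # degrees from ROI horizontal
    mean_intensity_on_line: float
    coverage: float = 0.0


@dataclass
class NeuronID:
    classification: str                # "ALM" | "not_target"
    head_direction: str                # "left" | "right" | "unknown"
    evidence: tuple[EdgeEvidence, EdgeEvidence] | None = None

    def __post_init__(self) -> None:
        if self.classification == "ALM" and self.head_direction == "unknown":
            raise ValueError("ALM classification requires a head direction")


def flanking_rois(soma_center_px: tuple[float, float],
                  frame_dims: tuple[int, int],
                  soma_radius_px: float = 25.0,
                  config: VerifierConfig | None = None) -> tuple[Rect, Rect]:
    """Two rectangles abutting the soma's bounding circle, left and right.

    Raises :class:`RoiClippedError` if either ROI retains less than half its
    nominal area after clipping to the frame.
    """
    config = config or VerifierConfig()
    H, W = frame_dims
    row, col = soma_center_px
    nominal = config.roi_rows * config.roi_cols

    def clip(rect: Rect) -> Rect:
        r0, c0, nr, nc = rect
        r1, c1 = r0 + nr, c0 + nc
        r0c, c0c = max(r0, 0), max(c0, 0)
        r1c, c1c = min(r1, H), min(c1, W)
        nrc, ncc = max(r1c - r0c, 0), max(c1c - c0c, 0)
        if nrc * ncc < config.min_roi_area_frac * nominal:
            raise RoiClippedError(
                f"flanking ROI {rect} clips below "
                f"{config.min_roi_area_frac:.0%} of its area"
            )
        return (r0c, c0c, nrc, ncc)

    r0 = int(round(row)) - config.roi_rows // 2
    left = clip((r0, int(round(col - soma_radius_px)) - config.roi_cols,
                 config.roi_rows, config.roi_cols))
    right = clip((r0, int(round(col + soma_radius_px)),
                  config.roi_rows, config.roi_cols))
    return left, right


def detect_straight_edge(roi_image: np.ndarray,
                         config: VerifierConfig | None = None) -> EdgeEvidence:
    """Search a fluorescence ROI for a straight near-horizontal feature.

    The background-subtracted ROI is rotated through the angular window and
    projected onto rows; a genuine axon produces a narrow projection peak
    many noise-sigmas high that spans most of the ROI width, whereas a
    compact blob fails the coverage test and noise fails the strength test.
    """
    config = config or VerifierConfig()
    img = np.asarray(roi_image, dtype=float)
    img = img - np.median(img)
    noise_sigma = 1.4826 * float(np.median(np.abs(img))) or 1.0

    angles = np.arange(-config.max_angle_deg, config.max_angle_deg + 1e-9,
                       config.angle_step_deg)
    n_cols = img.shape[1]
    c_lo, c_hi = int(0.15 * n_cols), int(0.85 * n_cols)
    best = (-np.inf, 0.0, None, 0)     # strength, angle, rotated, peak row

    for theta in angles:
        rot = ndimage.rotate(img, theta, reshape=False, order=1,
                             mode="constant", cval=0.0)
        central = rot[:, c_lo:c_hi]
        profile = central.mean(axis=1)
        peak = int(np.argmax(profile))
        sigma_mean = noise_sigma / np.sqrt(central.shape[1])
        strength = (profile[peak] - float(np.median(profile))) / sigma_mean
        if strength > best[0]:
            best = (strength, float(theta), central, peak)

    strength, angle, central, peak = best
    band = central[max(peak - 1, 0):peak + 2, :]
    line = band.max(axis=0)
    coverage = float(np.mean(line > 2.0 * noise_sigma))
    mean_on_line = float(central[peak, :].mean())
    present = strength >= config.strength_sigmas and coverage >= config.min_coverage
    return EdgeEvidence(bool(present), float(strength), angle, mean_on_line,
                        coverage)


def classify_neuron(left: EdgeEvidence, right: EdgeEvidence) -> NeuronID:
    """Combine flanking evidence into a neuron identity.

    No straight edge on either side means the soma is not the target (the
    worm is flushed).  With one edge, the head lies on that side; with two,
    the brighter line marks the main (anterior) process.
    """
    if not left.present and not right.present:
        return NeuronID("not_target", "unknown", (left, right))
    if left.present and not right.present:
        head = "left"
    elif right.present and not left.present:
        head = "right"
    else:
        head = "left" if left.mean_intensity_on_line > right.mean_intensity_on_line else "right"
    return NeuronID("ALM", head, (left, right))


def verify_neuron(phantom: WormPhantom, rig: RigState, det: SomaDetection,
                  config: VerifierConfig | None = None,
                  focus_config: FocusMetricConfig | None = None,
                  optics: OpticsConfig | None = None,
                  noise: NoiseConfig | None = None,
                  rng: np.random.Generator | None = None) -> NeuronID:
    """Closed-loop Step 3: piezo fine-focus on the soma, then edge search.

    Raises :class:`RoiClippedError` when the soma sits too close to a frame
    edge to place both flanking ROIs.
    """
    config = config or VerifierConfig()
    focus_config = focus_config or FocusMetricConfig()
    optics = optics or DEFAULT_OPTICS
    noise = noise or DEFAULT_NOISE
    rng = rng if rng is not None else np.random.default_rng(0)

    # Acquire a piezo z-stack about the current plane and pick best focus.
    half = config.fine_focus_halfspan_um
    step = focus_config.fine_step_z
    offsets = np.arange(-half, half + step / 2, step)
    frames = []
    z_now = 0.0
    for z in offsets:
        move_piezo(rig, (0.0, 0.0, z - z_now))
        z_now = z
        frames.append(render_frame(phantom, rig, "fluorescence", optics, noise, rng))
    stack = ZStack(frames)
    best = fine_focus(stack, focus_config)
    move_piezo(rig, (0.0, 0.0, offsets[best] - z_now))
    frame = render_frame(phantom, rig, "fluorescence", optics, noise, rng)

    spot = optics.laser_spot_px()
    ps = optics.pixel_size(rig.objective)
    soma_radius_px = max(det.equivalent_diameter_um / 2.0 / ps, 10.0) + 5.0
    left_rect, right_rect = flanking_rois(spot, frame.shape, soma_radius_px, config)

    def crop(rect: Rect) -> np.ndarray:
        r0, c0, nr, nc = rect
        return frame.raster[r0:r0 + nr, c0:c0 + nc]

    left = detect_straight_edge(crop(left_rect), config)
    right = detect_straight_edge(crop(right_rect), config)
    return classify_neuron(left, right)
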