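"""Step 1: locate the trapped worm in a low-magnification bright-field frame.

The baseline image of the empty (membrane-deflected) trap is subtracted from
the snapshot, the absolute difference is thresholded inside the trapping-area
region of interest, small particles are filtered out, and the area centroid
of the surviving components gives the worm location.  A centroid near the
ROI edge triggers rejection (the controller flushes the worm).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label

from .errors import InputError
from .virtual_rig.render import CameraFrame

__all__ = ["LocatorConfig", "WormLocation", "subtract_background",
           "segment_worm", "locate_worm"]

Roi = tuple[int, int, int, int]   # (row0, col0, rows, cols), 0-based, half-open


@dataclass(frozen=True)
class LocatorConfig:
    min_particle_area: int = 300      # px; smaller components are removed
    edge_margin_frac: float = 0.05    # of each ROI dimension
    threshold: float | None = None    # fixed threshold override (else Otsu)
    noise_floor_sigmas: float = 4.0   # robust floor under the Otsu threshold


@dataclass
class WormLocation:
    centroid_px: tuple[float, float] | None   # (row, col), frame coordinates
    centroid_um: tuple[float, float] | None   # relative to the frame centre
    mask_area_px: int
    status: str                               # accepted | no_worm | reject_near_edge
    stage_correction_um: tuple[float, float] | None = None


def _check_roi(roi: Roi, shape: tuple[int, int]) -> Roi:
    r0, c0, nr, nc = roi
    if nr <= 0 or nc <= 0:
        raise InputError(f"empty roi {roi}")
    if r0 < 0 or c0 < 0 or r0 + nr > shape[0] or c0 + nc > shape[1]:
        raise InputError(f"roi {roi} outside frame of shape {shape}")
    return roi


def _raster(frame) -> np.ndarray:
    return frame.raster if isinstance(frame, CameraFrame) else np.asarray(frame, dtype=float)


def subtract_background(frame, baseline) -> np.ndarray:
    """Absolute difference |frame - baseline| (the worm is dark on bright)."""
    f = _raster(frame)
    b = _raster(baseline)
    if f.shape != b.shape:
        raise InputError(f"shape mismatch: {f.shape} vs {b.shape}")
    if isinstance(frame, CameraFrame) and isinstance(baseline, CameraFrame):
        if frame.magnification_name != baseline.magnification_name:
            raise InputError("frame and baseline magnifications differ")
    return np.abs(f - b)


def segment_worm(diff: np.ndarray, roi: Roi, min_particle_area: int = 300,
                 threshold: float | None = None,
                 noise_floor_sigmas: float = 4.0) -> np.ndarray:
    """Threshold the difference image inside ``roi`` and particle-filter it.

    Components (8-connected) smaller than ``min_particle_area`` pixels are
    removed.  The returned boolean mask has the full frame shape and is zero
    outside the ROI.
    """
    diff = np.asarray(diff, dtype=float)
    r0, c0, nr, nc = _check_roi(roi, diff.shape)
    sub = diff[r0:r0 + nr, c0:c0 + nc]

    mask = np.zeros(diff.shape, dtype=bool)
    if sub.max() == sub.min():
        return mask
    if threshold is None:
        t = float(threshold_otsu(sub))
        # Guard against splitting pure noise: require a robust floor too.
        med = float(np.median(sub))
        mad = float(np.median(np.abs(sub - med)))
        t = max(t, med + noise_floor_sigmas * 1.4826 * mad)
    else:
        t = threshold
    bw = sub > t
    if min_particle_area > 1:
        labels = label(bw, connectivity=2)
        counts = np.bincount(labels.ravel())
        keep = counts >= min_particle_area
        keep[0] = False
        bw = keep[labels]
    mask[r0:r0 + nr, c0:c0 + nc] = bw
    return mask


def locate_worm(frame, baseline, roi: Roi,
                config: LocatorConfig | None = None) -> WormLocation:
    """Run Step 1 on a bright-field frame; see :class:`WormLocation`.

    The returned ``stage_correction_um`` is the (x, y) stage move that
    centres the detected centroid in the field of view.
    """
    config = config or LocatorConfig()
    diff = subtract_background(frame, baseline)
    mask = segment_worm(diff, roi, config.min_particle_area,
                        config.threshold, config.noise_floor_sigmas)
    area = int(mask.sum())
    if area == 0:
        return WormLocation(None, None, 0, "no_worm")

    rows, cols = np.nonzero(mask)
    centroid = (float(rows.mean()), float(cols.mean()))

    r0, c0, nr, nc = roi
    margin_r = config.edge_margin_frac * nr
    margin_c = config.edge_margin_frac * nc
    near_edge = (
        centroid[0] < r0 + margin_r or centroid[0] > r0 + nr - margin_r
        or centroid[1] < c0 + margin_c or centroid[1] > c0 + nc - margin_c
    )

    ps = frame.pixel_size if isinstance(frame, CameraFrame) else 1.0
    H, W = diff.shape
    err_row = centroid[0] - (H - 1) / 2.0
    err_col = centroid[1] - (W - 1) / 2.0
    centroid_um = (err_col * ps, err_row * ps)
    # Commanding -error * pixel_size shifts the content onto the centre.
    correction = (-err_col * ps, -err_row * ps)

    status = "reject_near_edge" if near_edge else "accepted"
    return WormLocation(centroid, centroid_um, area, status, correction)
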