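"""Focus metrics: LoG bandpass filtering and the variance-of-intensity score.

The autofocus statistic is the population variance of pixel intensity,
computed after convolving each frame with a zero-sum Laplacian-of-Gaussian
kernel (sigma defaults to 2 pixels).  The frame maximizing the statistic is
taken as in focus; axon fine-focus instead compares plain mean intensities
inside a region flanking the expected axon.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InputError, ParameterError
from .virtual_rig.render import CameraFrame

__all__ = ["FocusMetricConfig", "ZStack", "log_kernel", "log_filter",
           "focus_variance", "fine_focus", "axon_focus"]

log = logging.getLogger(__name__)

FINE_STEP_Z_UM = 0.7


@dataclass(frozen=True)
class FocusMetricConfig:
    log_sigma: float = 2.0            # px
    fine_step_z: float = FINE_STEP_Z_UM
    kernel_truncation: float = 4.0    # multiples of sigma

    def __post_init__(self) -> None:
        if self.log_sigma <= 0:
            raise ParameterError("log_sigma must be > 0")
        if self.fine_step_z <= 0:
            raise ParameterError("fine_step_z must be > 0")


@dataclass
class ZStack:
    """Ordered frames with strictly monotone z positions."""

    frames: list[CameraFrame]
    z_positions: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.z_positions is None:
            self.z_positions = np.array([f.z_position for f in self.frames])
        self.z_positions = np.asarray(self.z_positions, dtype=float)
        if len(self.frames) != len(self.z_positions):
            raise InputError("frame count and z count differ")
        if len(self.frames) > 1:
            dz = np.diff(self.z_positions)
            if not (np.all(dz > 0) or np.all(dz < 0)):
                raise InputError("z_positions must be strictly monotone")

    def __len__(self) -> int:
        return len(self.frames)

    def rasters(self) -> list[np.ndarray]:
        return [f.raster for f in self.frames]


def log_kernel(sigma: float, truncation: float = 4.0) -> np.ndarray:
    """The 2-D LoG kernel, truncated and mean-corrected to sum exactly to 0."""
    if sigma <= 0:
        raise ParameterError("sigma must be > 0")
    radius = int(np.ceil(truncation * sigma))
    t = np.arange(-radius, radius + 1, dtype=float)
    x = t[None, :]
    y = t[:, None]
    r2 = x * x + y * y
    h = (r2 - 2.0 * sigma**2) / (2.0 * np.pi * sigma**6) * np.exp(-r2 / (2.0 * sigma**2))
    return h - h.mean()


def log_filter(image: np.ndarray, sigma: float = 2.0,
               truncation: float = 4.0) -> np.ndarray:
    """Convolve ``image`` with the zero-sum LoG kernel (reflected borders).

    Implemented with separable 1-D passes; the result is numerically
    identical to a direct 2-D convolution with :func:`log_kernel` because
    the truncated kernel decomposes as A(x)B(y) + B(x)A(y) minus its mean.
    """
    if sigma <= 0:
        raise ParameterError("sigma must be > 0")
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise InputError("image must be a nonempty 2-D array")

    radius = int(np.ceil(truncation * sigma))
    t = np.arange(-radius, radius + 1, dtype=float)
    g = np.exp(-(t * t) / (2.0 * sigma**2))
    a = (t * t - sigma**2) * g / (2.0 * np.pi * sigma**6)

    def sep(krow, kcol):
        tmp = ndimage.convolve1d(image, kcol, axis=1, mode="reflect")
        return ndimage.convolve1d(tmp, krow, axis=0, mode="reflect")

    out = sep(g, a) + sep(a, g)
    # Zero-sum correction: the raw kernel a(x)g(y) + g(x)a(y) has mean
    # 2*mean(a)*mean(g); subtracting mean * (box sum of the image) equals
    # convolving with the mean-corrected kernel.
    raw_mean = 2.0 * float(a.mean()) * float(g.mean())
    ones = np.ones(2 * radius + 1)
    box = ndimage.convolve1d(
        ndimage.convolve1d(image, ones, axis=1, mode="reflect"),
        ones, axis=0, mode="reflect",
    )
    return out - raw_mean * box


def focus_variance(image: np.ndarray) -> float:
    """Population variance of pixel intensity, (1/MN) * sum (I - mean)^2."""
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise InputError("empty image")
    return float(np.var(image))


def fine_focus(stack: ZStack, config: FocusMetricConfig | None = None) -> int:
    """Index of the most in-focus frame: argmax of variance after LoG.

    Ties break toward the lowest index.
    """
    config = config or FocusMetricConfig()
    if len(stack) == 0:
        raise InputError("empty stack")
    scores = [
        focus_variance(log_filter(r, config.log_sigma, config.kernel_truncation))
        for r in stack.rasters()
    ]
    return int(np.argmax(scores))


def axon_focus(stack: ZStack, axon_roi: tuple[int, int, int, int]) -> int:
    """Index of the frame with the highest mean intensity inside ``axon_roi``.

    ``axon_roi`` is (row0, col0, rows, cols), 0-based, half-open.  Ties break
    toward the lowest index.
    """
    if len(stack) == 0:
        raise InputError("empty stack")
    r0, c0, nr, nc = axon_roi
    shape = stack.frames[0].raster.shape
    if nr <= 0 or nc <= 0 or r0 < 0 or c0 < 0 or r0 + nr > shape[0] or c0 + nc > shape[1]:
        raise InputError(f"axon_roi {axon_roi} outside frame of shape {shape}")
    means = [float(r[r0:r0 + nr, c0:c0 + nc].mean()) for r in stack.rasters()]
    if np.ptp(means) == 0:
        log.warning("axon_focus: ROI content identical in all slices; returning 0")
    return int(np.argmax(means))
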