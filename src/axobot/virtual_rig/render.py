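"""Frame rendering for the virtual microscope.

Bright-field frames show the worm body dark on a bright chamber background;
fluorescence frames show somas and axons convolved with a defocus-dependent
Gaussian blur.  Sensor noise is Poisson shot noise (photon_gain electrons
per count) plus additive Gaussian read noise.

Pixel convention: raster[row, col], pixel (0, 0) top-left, x rightward
(columns), y downward (rows).  Commanding the rig by +d um in x shifts the
imaged content +d/pixel_size columns (see :class:`~.motion.RigState`).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..errors import ParameterError
from .motion import RigState
from .optics import DEFAULT_OPTICS, OpticsConfig
from .phantom import Axon, WormPhantom

__all__ = ["CameraFrame", "NoiseConfig", "DEFAULT_NOISE", "NOISELESS",
           "render_frame", "world_to_px", "px_to_world"]

GAP_HALF_UM = 0.8    # rendered half-width of a severed-axon gap


@dataclass
class CameraFrame:
    """A rendered 2-D intensity raster plus acquisition metadata."""

    raster: np.ndarray
    magnification_name: str
    pixel_size: float          # um / pixel in the object plane
    z_position: float          # focal-plane height above the glass, um
    channel: str               # "brightfield" | "fluorescence"

    def __post_init__(self) -> None:
        if self.channel not in ("brightfield", "fluorescence"):
            raise ParameterError(f"unknown channel {self.channel!r}")
        self.raster = np.asarray(self.raster, dtype=float)
        if self.raster.ndim != 2:
            raise ParameterError("raster must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.raster.shape


@dataclass(frozen=True)
class NoiseConfig:
    """Sensor noise amplitudes; set ``enable=False`` for noiseless renders."""

    photon_gain: float = 2.0        # photons per intensity count
    read_sigma_brightfield: float = 4.0
    read_sigma_fluorescence: float = 2.0
    brightfield_background: float = 1000.0
    fluorescence_background: float = 22.0
    worm_absorbance: float = 0.35   # bright-field body attenuation
    enable: bool = True


DEFAULT_NOISE = NoiseConfig()
NOISELESS = NoiseConfig(enable=False)


def world_to_px(xy, rig: RigState, optics: OpticsConfig) -> tuple[float, float]:
    """World (x, y) um -> sub-pixel (row, col) for the current objective."""
    ps = optics.pixel_size(rig.objective)
    sx, sy = rig.view_shift
    x, y = float(xy[0]), float(xy[1])
    col = (x + sx) / ps + (optics.sensor_width_px - 1) / 2.0
    row = (y + sy) / ps + (optics.sensor_height_px - 1) / 2.0
    return row, col


def px_to_world(row_col, rig: RigState, optics: OpticsConfig) -> tuple[float, float]:
    """Sub-pixel (row, col) -> world (x, y) um."""
    ps = optics.pixel_size(rig.objective)
    sx, sy = rig.view_shift
    row, col = float(row_col[0]), float(row_col[1])
    x = (col - (optics.sensor_width_px - 1) / 2.0) * ps - sx
    y = (row - (optics.sensor_height_px - 1) / 2.0) * ps - sy
    return x, y


def render_frame(phantom: WormPhantom, rig: RigState, channel: str,
                 optics: OpticsConfig | None = None,
                 noise: NoiseConfig | None = None,
                 rng: np.random.Generator | None = None) -> CameraFrame:
    """Render one frame of the phantom as seen by the rig.

    Deterministic for a fixed (phantom, rig, rng state); pass ``rng=None``
    for a fresh seed-0 generator.
    """
    optics = optics or DEFAULT_OPTICS
    noise = noise or DEFAULT_NOISE
    rng = rng if rng is not None else np.random.default_rng(0)

    if channel == "brightfield":
        img = _render_brightfield(phantom, rig, optics, noise)
        read_sigma = noise.read_sigma_brightfield
    elif channel == "fluorescence":
        img = _render_fluorescence(phantom, rig, optics, noise)
        read_sigma = noise.read_sigma_fluorescence
    else:
        raise ParameterError(f"unknown channel {channel!r}")

    if noise.enable:
        img = rng.poisson(np.maximum(img, 0.0) * noise.photon_gain) / noise.photon_gain
        img = img + rng.normal(0.0, read_sigma, size=img.shape)
        img = np.maximum(img, 0.0)

    return CameraFrame(
        raster=img,
        magnification_name=rig.objective,
        pixel_size=optics.pixel_size(rig.objective),
        z_position=rig.focus_z,
        channel=channel,
    )


# ---------------------------------------------------------------------------
# channel renderers

def _render_brightfield(phantom, rig, optics, noise) -> np.ndarray:
    H, W = optics.sensor_height_px, optics.sensor_width_px
    ps = optics.pixel_size(rig.objective)
    rows = np.arange(H)[:, None]
    cols = np.arange(W)[None, :]
    # Mild, smooth illumination falloff toward the corners.
    r2 = ((rows - (H - 1) / 2) / H) ** 2 + ((cols - (W - 1) / 2) / W) ** 2
    img = noise.brightfield_background * (1.0 - 0.08 * r2)

    if phantom.body_half_width > 0:
        att = np.zeros((H, W))
        hw_px = phantom.body_half_width / ps
        edge_px = max(2.0, 2.5 / ps)
        pts_px = np.array([world_to_px(p, rig, optics) for p in phantom.body_spline])
        for (r0, c0), (r1, c1) in zip(pts_px[:-1], pts_px[1:]):
            _accumulate_capsule(
                att, (r0, c0), (r1, c1), hw_px + edge_px,
                lambda d: noise.worm_absorbance
                * np.clip((hw_px + edge_px / 2 - d) / edge_px, 0.0, 1.0),
                mode="max",
            )
        img = img * (1.0 - att)
    return img


def _render_fluorescence(phantom, rig, optics, noise) -> np.ndarray:
    H, W = optics.sensor_height_px, optics.sensor_width_px
    ps = optics.pixel_size(rig.objective)
    z_cam = rig.focus_z
    img = np.full((H, W), noise.fluorescence_background, dtype=float)

    for soma in phantom.somas:
        _add_soma(img, soma, rig, optics, z_cam, ps)
    for axon in phantom.axons:
        _add_axon(img, axon, rig, optics, z_cam, ps)
    return img


def _blur_sigma_um(dz: float, optics: OpticsConfig) -> float:
    return optics.base_blur_sigma + optics.defocus_blur_scale * abs(dz)


def _add_soma(img, soma, rig, optics, z_cam, ps) -> None:
    H, W = img.shape
    sigma_px = _blur_sigma_um(soma.center[2] - z_cam, optics) / ps
    r_px = soma.radius / ps
    extent = int(np.ceil(1.8 * r_px + 4.0 * sigma_px)) + 2
    row, col = world_to_px(soma.center[:2], rig, optics)
    r_lo, r_hi = int(np.floor(row)) - extent, int(np.ceil(row)) + extent + 1
    c_lo, c_hi = int(np.floor(col)) - extent, int(np.ceil(col)) + extent + 1
    r_lo, r_hi = max(r_lo, 0), min(r_hi, H)
    c_lo, c_hi = max(c_lo, 0), min(c_hi, W)
    if r_lo >= r_hi or c_lo >= c_hi:
        return
    rr = np.arange(r_lo, r_hi)[:, None] - row
    cc = np.arange(c_lo, c_hi)[None, :] - col
    d = np.hypot(rr, cc)
    # Soft-edged disc (super-Gaussian), then defocus blur of the patch.
    patch = soma.peak_intensity * np.exp(-((d / r_px) ** 4))
    if sigma_px > 0.05:
        patch = ndimage.gaussian_filter(patch, sigma_px, mode="constant")
    img[r_lo:r_hi, c_lo:c_hi] += patch


def _axon_visible_spans(axon: Axon) -> list[np.ndarray]:
    """Polyline pieces excluding the severed gap (if any)."""
    if axon.severed_at is None:
        return [axon.path]
    lo, hi = axon.severed_at - GAP_HALF_UM, axon.severed_at + GAP_HALF_UM
    arcs = axon.arclengths
    spans = []
    for bounds in ((0.0, max(lo, 0.0)), (min(hi, arcs[-1]), arcs[-1])):
        if bounds[1] - bounds[0] < 1e-6:
            continue
        spans.append(_slice_polyline(axon.path, arcs, *bounds))
    return spans


def _slice_polyline(path, arcs, a0, a1) -> np.ndarray:
    pts = [_point_at(path, arcs, a0)]
    inner = (arcs > a0) & (arcs < a1)
    pts.extend(path[inner])
    pts.append(_point_at(path, arcs, a1))
    return np.asarray(pts)


def _point_at(path, arcs, a) -> np.ndarray:
    i = int(np.clip(np.searchsorted(arcs, a) - 1, 0, len(path) - 2))
    seg = arcs[i + 1] - arcs[i]
    t = 0.0 if seg == 0 else (a - arcs[i]) / seg
    return path[i] + t * (path[i + 1] - path[i])


def _add_axon(img, axon, rig, optics, z_cam, ps) -> None:
    if axon.intensity <= 0 or axon.width <= 0:
        return
    sigma_w_px = (axon.width / 2.355) / ps
    # Segments max-combine in a scratch layer so polyline joints are not
    # double-counted, then the layer adds onto the frame.
    layer = np.zeros_like(img)
    for piece in _axon_visible_spans(axon):
        z_mid = piece[:, 2].mean()
        sigma_blur_px = _blur_sigma_um(z_mid - z_cam, optics) / ps
        sigma_tot = float(np.hypot(sigma_w_px, sigma_blur_px))
        # A Gaussian line blurred by a Gaussian stays Gaussian; amplitude
        # scales with sigma_w / sigma_tot (1-D energy conservation).
        amp = axon.intensity * sigma_w_px / sigma_tot
        extent = 4.0 * sigma_tot
        pts_px = np.array([world_to_px(p[:2], rig, optics) for p in piece])
        for (r0, c0), (r1, c1) in zip(pts_px[:-1], pts_px[1:]):
            _accumulate_capsule(
                layer, (r0, c0), (r1, c1), extent,
                lambda d: amp * np.exp(-0.5 * (d / sigma_tot) ** 2),
                mode="max",
            )
    img += layer


def _accumulate_capsule(img, p0, p1, extent, profile, mode="add") -> None:
    """Evaluate ``profile(distance-to-segment)`` on a bounding box of img.

    mode "max" max-combines the profile into the box; "add" accumulates.
    """
    H, W = img.shape
    r0, c0 = p0
    r1, c1 = p1
    r_lo = int(np.floor(min(r0, r1) - extent))
    r_hi = int(np.ceil(max(r0, r1) + extent)) + 1
    c_lo = int(np.floor(min(c0, c1) - extent))
    c_hi = int(np.ceil(max(c0, c1) + extent)) + 1
    r_lo, r_hi = max(r_lo, 0), min(r_hi, H)
    c_lo, c_hi = max(c_lo, 0), min(c_hi, W)
    if r_lo >= r_hi or c_lo >= c_hi:
        return
    rr = np.arange(r_lo, r_hi)[:, None]
    cc = np.arange(c_lo, c_hi)[None, :]
    vr, vc = r1 - r0, c1 - c0
    denom = vr * vr + vc * vc
    if denom == 0:
        d = np.hypot(rr - r0, cc - c0)
    else:
        t = np.clip(((rr - r0) * vr + (cc - c0) * vc) / denom, 0.0, 1.0)
        d = np.hypot(rr - (r0 + t * vr), cc - (c0 + t * vc))
    vals = profile(d)
    box = img[r_lo:r_hi, c_lo:c_hi]
    if mode == "max":
        np.maximum(box, vals, out=box)
    else:
        box += vals
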