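"""Camera and objective constants for the virtual microscope.

The defaults mirror a 1392x1040 CCD with a 6.45 um pixel pitch behind a 5x
air objective (NA 0.16) and a 63x oil-immersion objective (NA 1.4).  All
object-plane quantities are micrometres unless noted otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

from ..errors import ParameterError

__all__ = ["Magnification", "OpticsConfig", "DEFAULT_OPTICS"]


@dataclass(frozen=True)
class Magnification:
    """One selectable objective."""

    name: str
    magnification: float
    numerical_aperture: float

    def __post_init__(self) -> None:
        if self.magnification <= 0:
            raise ParameterError(f"magnification must be > 0, got {self.magnification}")
        if self.numerical_aperture <= 0:
            raise ParameterError("numerical aperture must be > 0")


def _default_magnifications() -> tuple[Magnification, ...]:
    return (
        Magnification("5x", 5.0, 0.16),
        Magnification("63x", 63.0, 1.4),
    )


@dataclass(frozen=True)
class OpticsConfig:
    """Sensor geometry, objectives and the defocus blur law.

    Attributes
    ----------
    sensor_width_px, sensor_height_px:
        Raster dimensions (columns, rows) of every rendered frame.
    camera_pixel_pitch:
        Physical pixel size on the sensor, um.
    magnifications:
        Available objectives; the object-plane pixel size for each is
        ``camera_pixel_pitch / magnification``.
    emission_wavelength:
        Fluorescence emission wavelength in nm, used by :meth:`resolution_nm`.
    defocus_blur_scale:
        Growth of the Gaussian blur sigma (um of sigma per um of defocus).
    base_blur_sigma:
        In-focus blur sigma, um.
    """

    sensor_width_px: int = 1392
    sensor_height_px: int = 1040
    camera_pixel_pitch: float = 6.45
    magnifications: tuple[Magnification, ...] = field(default_factory=_default_magnifications)
    emission_wavelength: float = 500.0
    defocus_blur_scale: float = 0.55
    base_blur_sigma: float = 0.2

    def __post_init__(self) -> None:
        if self.sensor_width_px <= 0 or self.sensor_height_px <= 0:
            raise ParameterError("sensor dimensions must be positive")
        if self.camera_pixel_pitch <= 0:
            raise ParameterError("camera_pixel_pitch must be > 0")
        if self.defocus_blur_scale < 0 or self.base_blur_sigma < 0:
            raise ParameterError("blur parameters must be >= 0")
        if not self.magnifications:
            raise ParameterError("at least one magnification is required")

    def magnification(self, name: str) -> Magnification:
        for mag in self.magnifications:
            if mag.name == name:
                return mag
        raise ParameterError(f"unknown magnification {name!r}")

    def pixel_size(self, name: str) -> float:
        """Object-plane pixel size in um for the named objective."""
        return self.camera_pixel_pitch / self.magnification(name).magnification

    def field_of_view_um(self, name: str) -> tuple[float, float]:
        """(width, height) of the imaged area in um."""
        ps = self.pixel_size(name)
        return self.sensor_width_px * ps, self.sensor_height_px * ps

    def resolution_nm(self, name: str = "63x", wavelength_nm: float | None = None) -> float:
        """Lateral resolution 0.6 * lambda / NA in nm."""
        lam = self.emission_wavelength if wavelength_nm is None else wavelength_nm
        return 0.6 * lam / self.magnification(name).numerical_aperture

    def laser_spot_px(self) -> tuple[int, int]:
        """Pixel (row, col) of the fixed ablation spot, near the frame centre."""
        return self.sensor_height_px // 2, self.sensor_width_px // 2

    def with_sensor(self, width_px: int, height_px: int) -> "OpticsConfig":
        """A copy with a different raster size (used to scale simulations)."""
        return replace(self, sensor_width_px=width_px, sensor_height_px=height_px)


DEFAULT_OPTICS = OpticsConfig()
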