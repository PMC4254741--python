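"""Ground-truth worm phantoms.

A phantom is the geometric/intensity model of one trapped L4 worm: a body
polyline with half-width (dark in bright-field), two ALM somas with axons
running anteriorly, and one AVM soma with no straight process in the small
field of view.  Phantoms carry explicit degenerate-case flags so the
automation controller can be exercised against known failure modes.

Coordinates are object-plane micrometres with the origin at the centre of
the trapping area; x runs along the (straightened) worm body, y across it,
z into the worm from the cover glass.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ..errors import ParameterError

__all__ = ["Soma", "Axon", "WormPhantom", "PhantomParams", "make_phantom", "empty_phantom"]

ALM_LABELS = ("ALML", "ALMR")


@dataclass
class Soma:
    label: str
    center: np.ndarray          # (x, y, z) um
    radius: float               # um
    peak_intensity: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise ParameterError("soma radius must be > 0")


@dataclass
class Axon:
    label: str
    path: np.ndarray            # (N, 3) polyline, um
    width: float = 0.3          # um (FWHM of the fluorescent cross-section)
    intensity: float = 150.0
    severed_at: float | None = None   # arclength um from path[0]

    def __post_init__(self) -> None:
        self.path = np.asarray(self.path, dtype=float)
        if self.path.ndim != 2 or self.path.shape[1] != 3 or len(self.path) < 2:
            raise ParameterError("axon path must be an (N>=2, 3) polyline")
        if self.width < 0:
            raise ParameterError("axon width must be >= 0")
        if self.severed_at is not None and not (0.0 <= self.severed_at <= self.length):
            raise ParameterError("severed_at outside the path arclength")

    @property
    def seg_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.path, axis=0), axis=1)

    @property
    def arclengths(self) -> np.ndarray:
        """Cumulative arclength at each vertex."""
        return np.concatenate([[0.0], np.cumsum(self.seg_lengths)])

    @property
    def length(self) -> float:
        return float(self.seg_lengths.sum())

    def point_at(self, arclength: float) -> np.ndarray:
        """(x, y, z) of the centreline point at the given arclength."""
        arcs = self.arclengths
        i = int(np.clip(np.searchsorted(arcs, arclength) - 1, 0, len(self.path) - 2))
        seg = arcs[i + 1] - arcs[i]
        t = 0.0 if seg == 0 else (arclength - arcs[i]) / seg
        return self.path[i] + t * (self.path[i + 1] - self.path[i])

    def nearest_point(self, xy) -> tuple[float, float]:
        """(arclength, lateral xy-distance) of the closest centreline point."""
        p = np.asarray(xy, dtype=float)
        verts = self.path[:, :2]
        a, b = verts[:-1], verts[1:]
        ab = b - a
        denom = np.einsum("ij,ij->i", ab, ab)
        denom[denom == 0] = 1.0
        t = np.clip(np.einsum("ij,ij->i", p - a, ab) / denom, 0.0, 1.0)
        proj = a + t[:, None] * ab
        d = np.linalg.norm(proj - p, axis=1)
        i = int(np.argmin(d))
        arc = self.arclengths[i] + t[i] * self.seg_lengths[i]
        return float(arc), float(d[i])


@dataclass
class WormPhantom:
    """Full ground truth for one worm."""

    body_spline: np.ndarray               # (N, 2) polyline, um
    body_half_width: float                # um
    centroid: np.ndarray                  # (x, y) um
    orientation: np.ndarray               # head-direction unit vector (x, y)
    somas: list[Soma] = field(default_factory=list)
    axons: list[Axon] = field(default_factory=list)
    folded: bool = False
    flags: dict = field(default_factory=dict)   # off_center, missing_soma, ...

    def __post_init__(self) -> None:
        self.body_spline = np.asarray(self.body_spline, dtype=float)
        self.centroid = np.asarray(self.centroid, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)

    @property
    def alm_somas(self) -> list[Soma]:
        return [s for s in self.somas if s.label in ALM_LABELS]

    def nearest_axon(self, xy) -> tuple[Axon | None, float, float]:
        """(axon, arclength, distance) of the closest axon centreline point."""
        best: tuple[Axon | None, float, float] = (None, 0.0, np.inf)
        for axon in self.axons:
            arc, d = axon.nearest_point(xy)
            if d < best[2]:
                best = (axon, arc, d)
        return best

    def to_json_dict(self) -> dict:
        d = asdict(self)
        return json.loads(json.dumps(d, default=_jsonify))

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


@dataclass(frozen=True)
class PhantomParams:
    """Distribution settings for random phantoms.

    The degenerate-case probabilities are independent Bernoulli draws; the
    automation controller converts desired rejection fractions of all
    processed worms into these conditional probabilities.
    """

    body_length_range: tuple[float, float] = (550.0, 680.0)
    body_half_width_range: tuple[float, float] = (12.0, 16.0)
    centroid_jitter: float = 20.0            # um, lateral placement spread
    soma_depth_range: tuple[float, float] = (4.0, 9.0)
    soma_radius_range: tuple[float, float] = (1.7, 2.3)
    soma_peak_intensity: float = 450.0
    axon_intensity: float = 150.0
    axon_width: float = 0.3
    axon_length: float = 260.0
    axon_drift_max: float = 0.05             # |dy/dx| of the anterior process
    posterior_process_prob: float = 0.15
    folded_prob: float = 0.0
    off_center_prob: float = 0.0
    missing_soma_prob: float = 0.0
    weak_axon_prob: float = 0.0
    misaligned_axon_prob: float = 0.0
    weak_axon_factor: float = 0.01
    off_center_shift: float = 880.0          # um, pushes the worm past the ROI edge

    def __post_init__(self) -> None:
        for name in ("body_length_range", "body_half_width_range",
                     "soma_depth_range", "soma_radius_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ParameterError(f"{name}: min {lo} > max {hi}")
            if lo < 0:
                raise ParameterError(f"{name}: negative bound {lo}")
        for name in ("folded_prob", "off_center_prob", "missing_soma_prob",
                     "weak_axon_prob", "misaligned_axon_prob",
                     "posterior_process_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name} must be a probability, got {p}")


def empty_phantom() -> WormPhantom:
    """A phantom with no worm at all (used for baseline frames)."""
    return WormPhantom(
        body_spline=np.zeros((2, 2)),
        body_half_width=0.0,
        centroid=np.zeros(2),
        orientation=np.array([1.0, 0.0]),
        somas=[],
        axons=[],
        flags={"empty": True},
    )


def make_phantom(params: PhantomParams | None = None, seed: int | np.random.Generator = 0) -> WormPhantom:
    """Draw one worm phantom. Deterministic for a fixed integer seed."""
    params = params or PhantomParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    folded = bool(rng.random() < params.folded_prob)
    off_center = bool(rng.random() < params.off_center_prob)
    missing_soma = bool(rng.random() < params.missing_soma_prob)
    weak_axon = bool(rng.random() < params.weak_axon_prob)
    misaligned = bool(rng.random() < params.misaligned_axon_prob)

    length = rng.uniform(*params.body_length_range)
    half_width = rng.uniform(*params.body_half_width_range)
    head_sign = 1.0 if rng.random() < 0.5 else -1.0    # +1: head toward +x
    centroid = rng.uniform(-params.centroid_jitter, params.centroid_jitter, size=2)
    centroid[1] *= 0.5
    if folded or off_center:
        # Park the worm mostly outside the trapping-area ROI so the detected
        # (clipped-mask) centroid falls inside the edge margin.
        centroid[0] += np.sign(rng.random() - 0.5) * params.off_center_shift

    n_pts = 25
    xs = np.linspace(-length / 2, length / 2, n_pts)
    ys = 3.0 * np.sin(xs / length * 2 * np.pi + rng.uniform(0, 2 * np.pi))
    if folded:
        # Hairpin: fold the posterior half back over the anterior half.
        fold = length / 4
        xs = np.where(xs > fold, 2 * fold - xs, xs)
        ys = ys + np.where(np.linspace(0, 1, n_pts) > 0.5, 2.2 * half_width, 0.0)
    body = np.column_stack([xs + centroid[0], ys + centroid[1]])

    somas: list[Soma] = []
    axons: list[Axon] = []
    if not missing_soma:
        soma_x = centroid[0] + rng.uniform(-8.0, 8.0)
        depth_lo, depth_hi = params.soma_depth_range
        z_near = rng.uniform(depth_lo, depth_hi)
        z_far = z_near + rng.uniform(4.0, 7.0)
        lateral = rng.uniform(5.0, 9.0)
        intensity = params.axon_intensity * (params.weak_axon_factor if weak_axon else 1.0)
        for label, y_side, z in (("ALML", +lateral, z_near), ("ALMR", -lateral, z_far)):
            radius = rng.uniform(*params.soma_radius_range)
            center = np.array([soma_x, centroid[1] + y_side, z])
            somas.append(Soma(label, center, radius, params.soma_peak_intensity))
            axons.append(_alm_axon(label, center, head_sign, params, intensity,
                                   misaligned, rng))
            if rng.random() < params.posterior_process_prob:
                axons.append(_posterior_process(label, center, head_sign, params,
                                                intensity, rng))
        # AVM: ventral soma, no straight process within the small FOV.
        avm_center = np.array([soma_x + rng.uniform(15.0, 30.0),
                               centroid[1] + rng.uniform(-3.0, 3.0),
                               z_far + rng.uniform(2.0, 5.0)])
        somas.append(Soma("AVM", avm_center, rng.uniform(*params.soma_radius_range),
                          params.soma_peak_intensity * 0.8))

    return WormPhantom(
        body_spline=body,
        body_half_width=half_width,
        centroid=centroid,
        orientation=np.array([head_sign, 0.0]),
        somas=somas,
        axons=axons,
        folded=folded,
        flags={
            "off_center": off_center,
            "missing_soma": missing_soma,
            "weak_axon": weak_axon,
            "misaligned_axon": misaligned,
        },
    )


def _alm_axon(label: str, soma_center: np.ndarray, head_sign: float,
              params: PhantomParams, intensity: float, misaligned: bool,
              rng: np.random.Generator) -> Axon:
    """Anterior process: runs from the soma toward the head, nearly straight."""
    n = 20
    t = np.linspace(0.0, 1.0, n)
    xs = soma_center[0] + head_sign * t * params.axon_length
    drift = rng.uniform(-params.axon_drift_max, params.axon_drift_max)
    ys = soma_center[1] + drift * t * params.axon_length
    if misaligned:
        # Bend the process beyond the piezo range once clear of the soma.
        bend = np.clip((t * params.axon_length - 20.0) / 40.0, 0.0, 1.0)
        ys = ys + np.sign(rng.random() - 0.5) * 13.0 * bend
    zs = soma_center[2] + rng.uniform(-0.01, 0.01) * t * params.axon_length
    return Axon(label, np.column_stack([xs, ys, zs]),
                width=params.axon_width, intensity=intensity)


def _posterior_process(label: str, soma_center: np.ndarray, head_sign: float,
                       params: PhantomParams, intensity: float,
                       rng: np.random.Generator) -> Axon:
    """Short, dimmer process extending toward the tail."""
    n = 8
    t = np.linspace(0.0, 1.0, n)
    length = rng.uniform(40.0, 90.0)
    xs = soma_center[0] - head_sign * t * length
    ys = soma_center[1] + rng.uniform(-0.05, 0.05) * t * length
    zs = np.full(n, soma_center[2])
    return Axon(label + "_post", np.column_stack([xs, ys, zs]),
                width=params.axon_width, intensity=0.5 * intensity)
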