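import numpy as np
import pytest

from axobot.virtual_rig import (DEFAULT_OPTICS, RigState, Soma, Axon,
                                empty_phantom, move_stage)


@pytest.fixture
def small_optics():
    """256x256 sensor: fast fluorescence unit tests, same pixel size."""
    return DEFAULT_OPTICS.with_sensor(256, 256)


@pytest.fixture
def mid_optics():
    """512x384 sensor: wide enough for flanking ROIs and anterior moves."""
    return DEFAULT_OPTICS.with_sensor(512, 384)


@pytest.fixture
def full_optics():
    return DEFAULT_OPTICS


def soma_only_phantom(depth, radius=2.0, peak=450.0, xy=(0.0, 0.0)):
    """A phantom containing a single ALM-like soma and nothing else."""
    p = empty_phantom()
    p.somas = [Soma("ALML", np.array([xy[0], xy[1], depth]), radius, peak)]
    return p


def soma_with_axon_phantom(depth=5.0, axon_y_slope=0.0, axon_intensity=150.0,
                           head_sign=1.0, radius=2.0):
    """Soma at the origin plus a straight anterior axon at the same depth."""
    p = soma_only_phantom(depth, radius=radius)
    t = np.linspace(0.0, 1.0, 20)
    xs = head_sign * t * 260.0
    ys = axon_y_slope * t * 260.0
    zs = np.full_like(xs, depth)
    p.axons = [Axon("ALML", np.column_stack([xs, ys, zs]),
                    intensity=axon_intensity)]
    p.orientation = np.array([head_sign, 0.0])
    return p


@pytest.fixture
def rig63():
    return RigState(objective="63x")


@pytest.fixture
def rig5():
    return RigState(objective="5x")


def rig_focused_at(z, objective="63x"):
    rig = RigState(objective=objective)
    move_stage(rig, (0.0, 0.0, z))
    return rig
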