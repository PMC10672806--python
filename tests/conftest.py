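import numpy as np
import pytest

from motility3d.io import Track, TrackSet


def make_track(xyz, dt=90.0, cell_id="c0", frame_id="f0", tissue="LN", t=None):
    xyz = np.asarray(xyz, dtype=float)
    if t is None:
        t = np.arange(len(xyz), dtype=float) * dt
    return Track(cell_id=cell_id, frame_id=frame_id, tissue=tissue, t=np.asarray(t, float), xyz=xyz)


@pytest.fixture
def straight_track():
    """Cell moving 9 µm per 90 s step along x: cell speed 6 µm/min."""
    return make_track([[0, 0, 0], [9, 0, 0], [18, 0, 0]])


@pytest.fixture
def out_and_back_track():
    """Cell going out 9 µm and returning: displacement speed 0."""
    return make_track([[0, 0, 0], [9, 0, 0], [0, 0, 0]])


@pytest.fixture
def l_track():
    """Two equal 9 µm legs at a right angle over 3 min."""
    return make_track([[0, 0, 0], [9, 0, 0], [9, 9, 0]])


@pytest.fixture
def small_trackset(straight_track):
    tracks = [
        make_track([[0, 0, 0], [9, 0, 0], [18, 0, 0], [18, 9, 0]], cell_id="a", frame_id="f0"),
        make_track([[0, 0, 0], [0, 5, 0], [5, 5, 0]], cell_id="b", frame_id="f0"),
        make_track([[1, 1, 1], [4, 5, 1], [4, 5, 13]], cell_id="a", frame_id="f1", tissue="villi"),
    ]
    return TrackSet(tracks, metadata={"source": "fixture"})


def random_walk_track(rng, n_points=10, step_scale=5.0, dt=90.0, **kw):
    """Unstructured random 3D track for property tests."""
    xyz = np.cumsum(rng.normal(scale=step_scale, size=(n_points, 3)), axis=0)
    return make_track(xyz, dt=dt, **kw)
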