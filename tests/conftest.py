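import numpy as np
import pytest

from metquant.detect import Detection
from metquant.linker import Track
from metquant.synthio import MovieSimParams, simulate_movie


def make_track(positions, track_id=0, start_frame=0, diameter_um=3.0, cell_type="PMEC"):
    """Build a Track from an (n, 3) array of (z, y, x) µm positions."""
    positions = np.asarray(positions, dtype=float)
    dets = [
        Detection(start_frame + i, *p, quality=1.0, radius_um=diameter_um / 2.0)
        for i, p in enumerate(positions)
    ]
    return Track(track_id, dets, cell_type)


@pytest.fixture(scope="session")
def small_movie():
    """A compact ground-truthed movie used across detection/linking tests."""
    params = MovieSimParams(
        image_shape_voxels=(8, 12, 128, 128),
        n_pmec=4,
        n_icp=4,
        seed=5,
    )
    return simulate_movie(params)


@pytest.fixture(scope="session")
def default_movie():
    """The full default study-condition movie (15+15 nuclei, 31 frames)."""
    return simulate_movie(MovieSimParams(seed=11))
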