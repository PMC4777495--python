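import numpy as np
import pytest

from stickmotion import LandmarkSeries, MotionTrace, SkeletonTopology


def make_series(trajectories: dict, stimulus_id: str = "fixture") -> LandmarkSeries:
    """Build a LandmarkSeries from name -> (n, 2) arrays (or a single point)."""
    names = tuple(sorted(trajectories))
    arrays = {}
    n = None
    for name, arr in trajectories.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 1:
            arr = arr[None, :]
        arrays[name] = arr
        n = arr.shape[0] if n is None else n
    positions = np.stack([np.broadcast_to(arrays[m], (n, 2)) for m in names], axis=1)
    return LandmarkSeries(stimulus_id, np.arange(n), names, positions.copy())


SAWTOOTH_X = np.array([0.0, 1.0, 2.0, 3.0, 2.0, 1.0, 2.0])


@pytest.fixture
def sawtooth_trace() -> MotionTrace:
    """1D excursion with two reversals and an unfinished final excursion."""
    return MotionTrace("sawtooth", np.column_stack((SAWTOOTH_X, np.zeros(7))))


@pytest.fixture
def single_landmark_topology() -> SkeletonTopology:
    return SkeletonTopology(chains=(), aggregation_set=("forehead",))


@pytest.fixture
def sawtooth_series() -> LandmarkSeries:
    """Sawtooth motion carried by the forehead landmark alone."""
    return make_series(
        {"forehead": np.column_stack((SAWTOOTH_X, np.zeros(7)))}, "sawtooth"
    )


def full_figure_sawtooth() -> LandmarkSeries:
    """All 13 landmarks; the forehead performs the sawtooth, the rest hold still.

    The aggregation sum then equals the sawtooth plus a constant, so the
    motion measures match the bare sawtooth trace exactly.
    """
    static = {
        "throat": (500.0, 300.0),
        "left_ear": (475.0, 245.0),
        "right_ear": (525.0, 245.0),
        "left_shoulder": (460.0, 300.0),
        "right_shoulder": (540.0, 300.0),
        "left_elbow": (415.0, 300.0),
        "right_elbow": (585.0, 300.0),
        "left_hand": (375.0, 300.0),
        "right_hand": (625.0, 300.0),
        "navel": (500.0, 380.0),
        "lectern_left": (320.0, 560.0),
        "lectern_right": (680.0, 560.0),
    }
    traj = {name: np.tile(np.asarray(p), (7, 1)) for name, p in static.items()}
    traj["forehead"] = np.column_stack((500.0 + SAWTOOTH_X, np.full(7, 240.0)))
    return make_series(traj, "sawtooth_figure")


def random_trace(rng: np.random.Generator, max_len: int = 200) -> MotionTrace:
    """A random-walk trace with occasional repeats to exercise distance ties."""
    n = int(rng.integers(2, max_len + 1))
    steps = rng.normal(0.0, 3.0, (n - 1, 2))
    # zero out some steps so consecutive identical points (ties) occur
    steps[rng.random(n - 1) < 0.15] = 0.0
    pts = np.vstack(([0.0, 0.0], np.cumsum(steps, axis=0)))
    if rng.random() < 0.3:
        pts = np.round(pts)  # integer grids create exact distance ties
    return MotionTrace("random", pts)
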