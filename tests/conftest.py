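import numpy as np
import pytest

from replidyn import SynthParams, TimeGrid
from replidyn.cohort import CellTrajectory, Cohort
from replidyn.simulate import gen_cohort


@pytest.fixture
def tiny_cohort():
    """Three hand-built cells on a short grid (known divisions and values)."""
    grid = TimeGrid(frame_interval_min=20.0, n_frames=12)
    cells = []
    for i, (rls_frames, scale) in enumerate(
        [(np.array([3, 6, 9]), 1.0), (np.array([2, 5]), 2.0), (np.array([4]), 0.5)]
    ):
        n = int(rls_frames.max()) + 1
        t = np.arange(n, dtype=float)
        cells.append(
            CellTrajectory(
                cell_id=f"c{i}",
                frames=np.arange(n),
                cell_area=100.0 * scale + 2.0 * t,
                nuc_area=15.0 * scale + 0.3 * t,
                i_nuc=50.0 * scale - t,
                i_cyt=np.full(n, 10.0 * scale),
                division_frames=rls_frames,
            )
        )
    return Cohort(grid=grid, cells=cells)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (n = 300 cells) shared across tests."""
    cohort, truth = gen_cohort(SynthParams(seed=1))
    return cohort, truth


@pytest.fixture(scope="session")
def noiseless_params():
    return SynthParams(
        seed=7,
        noise_cv_cell_area=0.0,
        noise_cv_nuc_area=0.0,
        noise_cv_i_nuc=0.0,
        noise_cv_i_cyt=0.0,
    )
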