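import numpy as np
import pytest

from thermofda import SimConfig, ThermogramSet, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """60+60 subjects on a coarse 45-90 °C grid (101 points)."""
    cfg = SimConfig(n_cases=60, n_controls=60, n_raoa_controls=5,
                    grid_step=0.45, seed=424242)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size default cohort (300+300, 451 grid points)."""
    return generate_cohort(SimConfig())


@pytest.fixture
def tiny_set():
    """Two flat curves on a 3-point grid, one case and one control."""
    grid = np.array([60.0, 61.0, 62.0])
    values = np.array([[1.0, 2.0, 3.0], [2.0, 2.0, 2.0]])
    return ThermogramSet(grid=grid, values=values,
                         subject_ids=np.array(["a", "b"]),
                         status=np.array([1, 0]))


def count_peaks(curve, prominence):
    """Local maxima with at least the given prominence."""
    from scipy.signal import find_peaks
    peaks, _ = find_peaks(np.asarray(curve), prominence=prominence)
    return len(peaks)
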