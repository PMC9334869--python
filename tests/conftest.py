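import numpy as np
import pytest

from sagcn import SimulationSpec, SubjectRecord, simulate_cohort
from sagcn.windowing import WindowSeries


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_window(series, subject_id="s1", window_index=1, label=0) -> WindowSeries:
    return WindowSeries(subject_id=subject_id, window_index=window_index,
                        series=np.asarray(series, dtype=float), label=label)


@pytest.fixture
def random_window(rng):
    return make_window(rng.standard_normal((40, 8)))


@pytest.fixture(scope="session")
def tiny_cohort():
    """8 subjects, 12 ROIs, 60 timepoints, strong 4-ROI module difference."""
    spec = SimulationSpec(n_per_group=4, n_rois=12, n_timepoints=60,
                          rho_background=0.05, module=(0, 1, 2, 3),
                          rho_module_a=0.8, rho_module_b=0.1, seed=11)
    records, truth = simulate_cohort(spec)
    return records, truth


@pytest.fixture(scope="session")
def small_cohort():
    """20 subjects, 14 ROIs — big enough for a quick but non-trivial CV."""
    spec = SimulationSpec(n_per_group=10, n_rois=14, n_timepoints=80,
                          rho_background=0.05, module=(0, 1, 2, 3, 4),
                          rho_module_a=0.75, rho_module_b=0.1, seed=23)
    records, truth = simulate_cohort(spec)
    return records, truth
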