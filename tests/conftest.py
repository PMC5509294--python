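import numpy as np
import pytest

from petmvpa import Cohort, CohortSpec, GridSpec, SubjectScan
from petmvpa.cohort import make_template
from petmvpa.pipeline import default_grid


@pytest.fixture
def small_grid() -> GridSpec:
    return default_grid((16, 18, 16))


def random_cohort(rng: np.random.Generator, n_disease: int = 5, n_healthy: int = 5,
                  shape=(3, 4, 3), with_ages: bool = True) -> Cohort:
    """A tiny cohort of pure-noise scans for oracle comparisons."""
    grid = GridSpec(shape)
    mask = np.ones(shape, dtype=bool)
    subjects = []
    for i in range(n_disease):
        age = float(rng.uniform(30, 70)) if with_ages else 50.0
        subjects.append(SubjectScan(f"d{i}", "disease", age,
                                    rng.normal(100, 10, size=shape)))
    for i in range(n_healthy):
        age = float(rng.uniform(30, 70)) if with_ages else 50.0
        subjects.append(SubjectScan(f"h{i}", "healthy", age,
                                    rng.normal(100, 10, size=shape)))
    return Cohort(grid=grid, subjects=subjects, brain_mask=mask)


@pytest.fixture
def template_16(small_grid):
    template, mask = make_template(small_grid, baseline=100.0)
    return small_grid, template, mask
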