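import numpy as np
import pytest

from covnet import CohortConfig, ThicknessTable


def random_adjacency(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """Erdos-Renyi style symmetric binary matrix, zero diagonal."""
    upper = rng.random((n, n)) < p
    a = np.triu(upper, 1)
    return (a | a.T).astype(np.int8)


def toy_table(values, group="G", mean_thickness=None) -> ThicknessTable:
    """Build a small ThicknessTable from a (subjects x regions) array."""
    values = np.asarray(values, dtype=float)
    n, r = values.shape
    if mean_thickness is None:
        mean_thickness = values.mean(axis=1)
    return ThicknessTable(
        group_label=group,
        subject_ids=[f"{group}{i}" for i in range(n)],
        region_labels=[f"r{j:02d}" for j in range(r)],
        values=values,
        mean_thickness=np.asarray(mean_thickness, dtype=float),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_cohort_config():
    """16-region, 10-subject two-group design used by pipeline tests."""
    return CohortConfig(
        n_subjects_per_group=10,
        n_regions=16,
        region_labels=tuple(f"r{j:02d}" for j in range(16)),
        group_effects={"A": 1.0, "B": 1.0},
        seed=7,
    )
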