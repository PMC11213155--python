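import numpy as np
import pytest

from msnpipe import (
    CohortConfig,
    GridSpec,
    ROISpec,
    build_msn,
    generate_cohort,
    generate_subject_thickness,
)

# small vertex samples keep the KDE stage fast in fixtures
FAST_ROI_SPEC = ROISpec(vertex_counts=120)


@pytest.fixture(scope="session")
def roi_spec():
    return FAST_ROI_SPEC


@pytest.fixture(scope="session")
def subject(roi_spec):
    return generate_subject_thickness(roi_spec, adi=0, subject_seed=42, subject_id="S0000")


@pytest.fixture(scope="session")
def msn(subject):
    return build_msn(subject, GridSpec())


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortConfig(n_low_adi=30, n_high_adi=12, seed=7))


def path_graph(n):
    adj = np.zeros((n, n), dtype=int)
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = 1
    return adj


def star_graph(n_leaves):
    adj = np.zeros((n_leaves + 1, n_leaves + 1), dtype=int)
    adj[0, 1:] = adj[1:, 0] = 1
    return adj


def complete_graph(n):
    return np.ones((n, n), dtype=int) - np.eye(n, dtype=int)


def cycle_graph(n):
    adj = path_graph(n)
    adj[0, n - 1] = adj[n - 1, 0] = 1
    return adj
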