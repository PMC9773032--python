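import numpy as np
import pytest

from mips.cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def planted_spec():
    """Claims-like planted cohort: K=4 blocks, p_in=0.4, p_out=0.05."""
    return CohortSpec(
        n_cases=2000,
        n_controls=500,
        n_comorbidities=30,
        n_subgroups=4,
        p_in=0.4,
        p_out=0.05,
        subgroup_risks=(0.12, 0.15, 0.17, 0.20),
        seed=20260401,
    )


@pytest.fixture(scope="session")
def planted_cohort(planted_spec):
    return generate_cohort(planted_spec)


@pytest.fixture(scope="session")
def noisefree_cohort():
    """Deterministic block structure: p_in=1, p_out=0."""
    spec = CohortSpec(
        n_cases=400,
        n_controls=400,
        n_comorbidities=20,
        n_subgroups=4,
        p_in=1.0,
        p_out=0.0,
        subgroup_risks=(0.2, 0.3, 0.4, 0.5),
        seed=5,
    )
    return generate_cohort(spec)


def all_set_partitions(items):
    """Enumerate every partition of a sequence (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in all_set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1 :]
        yield [[first]] + smaller


def partition_to_labels(partition, n):
    labels = np.empty(n, dtype=int)
    for lab, block in enumerate(partition, start=1):
        for item in block:
            labels[item] = lab
    return labels
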