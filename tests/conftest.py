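import numpy as np
import pytest

from epidense.density import DensityTable, MarkerRegion
from epidense.synthetic import CohortSpec, generate_cohort


def labels_from_ids(tables):
    return {s: ("case" if s.startswith(("case", "tumor")) else "control")
            for s in tables}


@pytest.fixture
def region():
    return MarkerRegion.from_string("chr19:58220000-58220800")


@pytest.fixture
def two_read_table():
    """The worked example: one half-methylated and one fully methylated
    4-CpG read."""
    return DensityTable("s", {(2, 4): 1, (4, 4): 1})


@pytest.fixture
def small_cohort():
    tables, truth = generate_cohort(
        CohortSpec(n_cases=8, n_controls=8, reads_per_sample=150,
                   tumor_fraction=0.05, seed=42))
    return tables, labels_from_ids(tables), truth


def random_micro_cohort(rng, max_samples=8, max_reads=20):
    """A tiny random cohort for oracle comparisons (no generative signal)."""
    n_cases = int(rng.integers(1, max_samples // 2 + 1))
    n_ctrls = int(rng.integers(1, max_samples // 2 + 1))
    tables = {}
    for i in range(n_cases + n_ctrls):
        sid = f"case_{i}" if i < n_cases else f"control_{i}"
        t = DensityTable(sid)
        for _ in range(int(rng.integers(1, max_reads + 1))):
            n = int(rng.integers(1, 15))
            m = int(rng.integers(0, n + 1))
            t.add(m, n)
        tables[sid] = t
    return tables, labels_from_ids(tables)
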