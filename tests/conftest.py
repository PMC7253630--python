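import numpy as np
import pytest

from ylineage.markers import Locus, SampleRecord
from ylineage.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def small_panel():
    """Three markers: one single-copy (AMELY-like), two multi-copy."""
    return [
        Locus("AMELY", ("T", "C")),
        Locus("9", ("G", "A"), multi_copy=True, cn_ladder=(1, 2, 5, 10, 20)),
        Locus("17", ("G", "A"), multi_copy=True, cn_ladder=(1, 2, 5, 10, 20)),
    ]


@pytest.fixture(scope="session")
def small_records(small_panel):
    def rec(sid, pop, group, amely, l9, l17):
        return SampleRecord(sid, pop, group, {"AMELY": amely, "9": l9, "17": l17})

    return [
        rec("s1", "DB", "SC", "T", "G", "G"),
        rec("s2", "DB", "SC", "T", "G", "G"),
        rec("s3", "YN", "SC", "T", "G/A", "G"),
        rec("s4", "YN", "SC", "C", "G", "A"),
        rec("s5", "IMG", "NC", "T", "G", "G"),
    ]


@pytest.fixture(scope="session")
def default_sim():
    """One default-world synthetic dataset shared by the expensive tests."""
    return simulate(SimConfig(seed=20260918))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
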