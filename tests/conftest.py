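from __future__ import annotations

import itertools
from collections import Counter

import pytest

from lincnome import (
    EvidenceCounts,
    PoolSizes,
    SimulationConfig,
)

# printed evidence-count columns of the published ORF-threshold table
TABLE1 = {
    "<90": EvidenceCounts(2961, 2806, 1655, 1947, 130),
    "<120": EvidenceCounts(3603, 3332, 2030, 2308, 155),
    "<150": EvidenceCounts(3989, 3644, 2249, 2531, 170),
    "none": EvidenceCounts(4662, 4156, 2641, 2888, 196),
}

TABLE1_POINTS = {
    "<90": (44_346, 35_722, 24_786),
    "<120": (53_649, 43_638, 30_227),
    "<150": (59_389, 48_207, 33_483),
    "none": (68_693, 55_999, 38_914),
}

TABLE1_CONSERVATION = {
    "<90": (56, 69),
    "<120": (56, 69),
    "<150": (56, 69),
    "none": (57, 69),
}


@pytest.fixture(scope="session")
def table1_counts():
    return TABLE1


@pytest.fixture
def counts_120():
    return TABLE1["<120"]


def enumerate_outcome_frequencies(
    nh: int, nm: int, nb: int, lh: int, lm: int
) -> dict[tuple[int, int, int], float]:
    """Exhaustive oracle: empirical distribution of (Kh, Km, Kb) over
    every equally likely (human-sample, mouse-sample) pair.

    Shared pool members carry ids 0..nb-1 in both species.
    """
    freq: Counter = Counter()
    total = 0
    for sample_h in itertools.combinations(range(nh), lh):
        shared_h = frozenset(i for i in sample_h if i < nb)
        for sample_m in itertools.combinations(range(nm), lm):
            shared_m = frozenset(i for i in sample_m if i < nb)
            key = (len(shared_h), len(shared_m), len(shared_h & shared_m))
            freq[key] += 1
            total += 1
    return {k: v / total for k, v in freq.items()}


@pytest.fixture
def tiny_sim_config():
    return SimulationConfig(
        true_pools=PoolSizes(40, 30, 20),
        sample_sizes=(25, 20),
        ortholog_detection_prob=1.0,
        seed=11,
    )
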