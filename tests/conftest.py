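import numpy as np
import pytest

from gcircuits import (CnaConfig, ProbeMap, SegmentedProfile,
                       SimulationConfig, call_cohort, generate_cohort)


@pytest.fixture(scope="session")
def config() -> CnaConfig:
    return CnaConfig()


@pytest.fixture(scope="session")
def small_map() -> ProbeMap:
    """100 contiguous 100 kb probes on one chromosome, 40/60 p/q split."""
    n = 100
    return ProbeMap([f"p{i:03d}" for i in range(n)], ["chr1"] * n,
                    [i * 100_000 for i in range(n)],
                    [(i + 1) * 100_000 for i in range(n)],
                    ["1p" if i < 40 else "1q" for i in range(n)])


@pytest.fixture(scope="session")
def two_chrom_map() -> ProbeMap:
    """Two chromosomes of 50 probes each."""
    ids, chroms, starts, ends, arms = [], [], [], [], []
    for c in (1, 2):
        for i in range(50):
            ids.append(f"c{c}_{i:02d}")
            chroms.append(f"chr{c}")
            starts.append(i * 100_000)
            ends.append((i + 1) * 100_000)
            arms.append(f"{c}p" if i < 20 else f"{c}q")
    return ProbeMap(ids, chroms, starts, ends, arms)


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort, shared across tests (seed 1)."""
    return generate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def cohort_calls(cohort):
    """(CallMatrix, events, arm_calls) for the shared cohort."""
    return call_cohort(cohort.profiles, cohort.probe_map)


def flat_profile(values, sample_id="s1") -> SegmentedProfile:
    return SegmentedProfile(sample_id, np.asarray(values, dtype=float))
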