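from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from symmeth.modcalls import ModificationRecord, SiteState
from symmeth.motifs import MotifSite, MotifSpec
from symmeth.simulate import SimulationConfig, simulate_dataset

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160422)


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size synthetic study shared across read-only tests."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A quick-to-generate configuration for end-to-end plumbing tests."""
    return SimulationConfig(seed=5, genome_len=30_000, island_start=9_001,
                            island_end=13_500, min_sites_per_motif=60)


def make_record(position: int, strand: str = "+", mod_type: str = "m6A",
                qv: float = 120.0, coverage: int = 100, ipd: float = 4.5) -> ModificationRecord:
    return ModificationRecord(position, strand, mod_type, qv, coverage, ipd)


def make_states(motif: MotifSpec, n_methylated: int, n_unmethylated: int,
                condition: str = "a", start_pos: int = 1) -> list[SiteState]:
    """Synthetic per-site states at consecutive positions, for summaries."""
    states = []
    pos = start_pos
    for _ in range(n_methylated):
        site = MotifSite(motif.name, pos, "+", pos)
        states.append(SiteState(site, condition, "methylated", make_record(pos)))
        pos += len(motif)
    for _ in range(n_unmethylated):
        site = MotifSite(motif.name, pos, "+", pos)
        states.append(SiteState(site, condition, "unmethylated"))
        pos += len(motif)
    return states
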