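import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hypolith.digest import virtual_digest
from hypolith.io import ReferenceRecord
from hypolith.synthetic import SimulationConfig, simulate_study

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def _mk_ref(rid, insert, role="producer", lineage=("Cyanobacteria", "", "", "", "Phormidium"),
            diazotroph=False):
    """Reference = 341F + insert + revcomp(907R with M->A)."""
    seq = "CCTACGGGAGGCAGCAG" + insert + "AAACTCAAATGAATTGACGG"
    return ReferenceRecord(id=rid, sequence=seq, lineage=lineage, role=role,
                           diazotroph=diazotroph)


@pytest.fixture
def make_reference():
    return _mk_ref


@pytest.fixture
def tiny_library():
    """Three references with MspI TRFs 20, 30 and no-site."""
    return [
        _mk_ref("prod_a", "AA" + "CCGG" + "ATATATAT" * 5, role="producer"),
        _mk_ref("cons_b", "ATATATATATAT" + "CCGG" + "TATA" * 6, role="consumer",
                lineage=("Proteobacteria", "", "Rhizobiales", "", "Rhizobium"),
                diazotroph=True),
        _mk_ref("cons_c", "ATTATTATTATTATTATT" * 3, role="consumer",
                lineage=("Actinobacteria", "", "", "", "Arthrobacter")),
    ]


@pytest.fixture
def tiny_digest(tiny_library):
    return virtual_digest(tiny_library)


@pytest.fixture(scope="session")
def small_bundle():
    """A compact study (22 sites, no reads) shared by read-only tests."""
    config = SimulationConfig(seed=11, n_sites=22, with_reads=False)
    return simulate_study(config)


@pytest.fixture(scope="session")
def read_bundle():
    """A small study that also generates pyrosequencing-style reads."""
    config = SimulationConfig(seed=5, n_sites=8, n_taxa=12,
                              reads_per_sample=150, n_sequenced_samples=2)
    return simulate_study(config)
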