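import numpy as np
import pytest

from domscan.gene_io import HaplotypeAlignment, SampleMetadata
from domscan.synthetic_data import SimulationConfig


def make_alignment(seqs, groups=None, names=None, gene_id="toy"):
    names = names or [f"s{i}" for i in range(len(seqs))]
    groups = groups or ["pop"] * len(seqs)
    return HaplotypeAlignment.from_sequences(names, groups, seqs, gene_id)


def random_alignment(rng, n, L, missing_rate=0.0, alphabet="ACGT"):
    mat = rng.choice(list(alphabet), size=(n, L))
    if missing_rate:
        mask = rng.random((n, L)) < missing_rate
        mat[mask] = "N"
    seqs = ["".join(row) for row in mat]
    return make_alignment(seqs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def metadata():
    return SampleMetadata(
        {
            **{f"WW{i + 1:03d}": ("WildWeedy", "EastAfrica", "wild") for i in range(20)},
            **{f"LR{i + 1:03d}": ("Landrace", "WestAfrica", "caudatum") for i in range(40)},
            **{f"s{i}": ("Landrace", "Asia", "durra") for i in range(10)},
        }
    )


@pytest.fixture(scope="session")
def small_config():
    """A fast simulation configuration for unit tests."""
    return SimulationConfig(
        effective_size_ancestral=50,
        bottleneck_fraction=0.5,
        bottleneck_duration=25,
        per_site_mutation_rate=3e-5,
        gene_length=900,
        outgroup_divergence_time=500,
        selected_allele_age=400,
        regimes=("neutral",) * 4,
        burn_in_factor=16,
    )
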