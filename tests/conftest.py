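import numpy as np
import pytest

from groupgwas import GroupSpec, SimConfig
from groupgwas.synthetic_data import simulate_study

# the 27 heterotrimeric G-protein gene symbols used as a realistic GMT fixture
GPROTEIN_GENES = [
    "GNA11", "GNA12", "GNA13", "GNA14", "GNA15", "GNAI1", "GNAI2", "GNAI3",
    "GNAL", "GNAO1", "GNAQ", "GNAS", "GNAT1", "GNAZ", "GNB1", "GNB2", "GNB3",
    "GNB4", "GNB5", "GNG2", "GNG3", "GNG4", "GNG5", "GNG7", "GNG10", "GNG11",
    "GNG12",
]


@pytest.fixture(scope="session")
def small_study():
    """Seeded study with one planted group and a null group."""
    config = SimConfig(
        n_individuals=400,
        n_blocks=10,
        snps_per_block=4,
        ld_rho=0.6,
        group_spec=[GroupSpec("planted", 4, 0.08)],
        seed=3,
    )
    return simulate_study(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return path
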