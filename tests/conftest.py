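import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from wgdkit import simulate as sim  # noqa: E402


@pytest.fixture(scope="session")
def biased_tetraploid():
    """Outgroup R + tetraploid Q with biased subgenome loss (0.2 vs 0.5)."""
    scenario = sim.Scenario(
        species_tree="(R:40,Q:40);",
        wgd_events=[sim.WgdEvent("WGD", 2, "Q", mode="allo",
                                 loss_prob=(0.2, 0.5), run_p=0.6)],
        n_chromosomes=2,
        genes_per_chromosome=400,
        codons_per_gene=3,
        ks_per_myr=0.004,
        seed=101,
    )
    return sim.simulate_scenario(scenario)


@pytest.fixture(scope="session")
def hexa_vs_tetra():
    """Hexaploid H vs tetraploid T descendants of a shared ancestor (2:3)."""
    scenario = sim.Scenario(
        species_tree="(H:50,T:50);",
        wgd_events=[
            sim.WgdEvent("ECH", 3, "H", loss_prob=(0.2, 0.2, 0.2), run_p=0.6),
            sim.WgdEvent("NST", 2, "T", loss_prob=(0.2, 0.3), run_p=0.6),
        ],
        n_chromosomes=2,
        genes_per_chromosome=300,
        codons_per_gene=3,
        ks_per_myr=0.004,
        seed=202,
    )
    return sim.simulate_scenario(scenario)


@pytest.fixture(scope="session")
def nst_like():
    """Single lineage with a tetraploidy whose true Ks peak is 0.49."""
    scenario = sim.Scenario(
        species_tree="(S:62);",
        wgd_events=[sim.WgdEvent("NST", 2, "S", loss_prob=(0.1, 0.1), run_p=0.6)],
        n_chromosomes=2,
        genes_per_chromosome=300,
        codons_per_gene=150,
        ks_per_myr=0.49 / (2 * 62),
        seed=303,
    )
    return sim.simulate_scenario(scenario)
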