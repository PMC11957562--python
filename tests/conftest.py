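import numpy as np
import pytest

from mitoscreen import simulate as sim
from mitoscreen.genome import Annotation


@pytest.fixture(scope="session")
def random_genome():
    return sim.generate_circular_genome(1000, 0.5, seed=1)


@pytest.fixture(scope="session")
def occupancy_dataset():
    """A 16.6-kb genome with 5 occupancy sites, 1 artifact and a D-loop-style
    mask, plus a 50k-read simulated alignment set (shared, read-only)."""
    positions = [2500, 5200, 8100, 11000, 13800]
    genome = sim.generate_circular_genome(16569, 0.44, seed=3)
    placements = [(p, "+", 25.0, "occupancy") for p in positions]
    placements.append((16300, "both", 25.0, "artifact"))
    genome, sites = sim.plant_motifs(genome, "TGACTCAG", placements)
    mask = Annotation(16024, 1122, "dloop")
    aln = sim.simulate_reads(genome, sites, sim.SimConfig(
        n_reads=50000, background_fraction=0.3, seed=42))
    return {"genome": genome, "sites": sites, "mask": mask, "aln": aln,
            "occupancy_positions": positions, "artifact_position": 16300}


def modular_distance(a, b, n):
    return min(abs(a - b), n - abs(a - b))


@pytest.fixture(scope="session")
def moddist():
    return modular_distance
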