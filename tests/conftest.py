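import numpy as np
import pytest

from plastcomp.model import revcomp
from plastcomp.simulate import SimulationConfig, simulate


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def default_truth():
    """One default-condition simulated clade, shared across tests."""
    return simulate(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def toy_ir_genome():
    """1 kb circular toy: 400 bp unique + 150 bp R + 300 bp unique + revcomp(R).

    Boundary-adjacent bases are adjusted so the planted pair is maximal under
    exact matching; the planted arms are [400,550) and [850,1000).
    """
    rng = np.random.default_rng(7)
    seq = list(random_dna(rng, 400) + random_dna(rng, 150) + random_dna(rng, 300))
    seq = seq + list(revcomp("".join(seq[400:550])))
    comp = dict(zip("ACGT", "TGCA"))
    # left flank of arm 1 pairs (circularly) with right flank of arm 2
    if seq[399] == comp[seq[0]]:
        seq[399] = "A" if seq[399] != "A" else "C"
        if seq[399] == comp[seq[0]]:
            seq[399] = "G"
    # right flank of arm 1 pairs with left flank of arm 2
    if seq[550] == comp[seq[849]]:
        seq[550] = "A" if seq[550] != "A" else "C"
        if seq[550] == comp[seq[849]]:
            seq[550] = "G"
    return "".join(seq), (400, 550), (850, 1000)
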