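import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracles.py

from mirevokit.annotate import PrecursorAnnotation
from mirevokit.simulate import SimulationConfig, make_genome


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_annot():
    """A 70-nt stem-loop with 22-nt mature arms one base in from each end
    (5p = [1,23), 3p = [47,69)). Three stem mismatches keep the 3' arm
    from being an exact reverse complement of the 5' arm (as in real
    hairpins), so sense/antisense placements stay distinguishable."""
    arm5 = "ACGTGCATGCAAGCTTGGCACTGGCCGTCGA"
    loop = "TTTCGAAT"
    comp = str.maketrans("ACGT", "TGCA")
    seq = list(arm5 + loop + arm5.translate(comp)[::-1])
    for pos in (41, 53, 64):
        seq[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[pos]]
    return PrecursorAnnotation("mir-toy", "".join(seq), mature_5p=(1, 23), mature_3p=(47, 69))


@pytest.fixture
def small_genome():
    cfg = SimulationConfig(seed=7, genome_length=3000)
    return make_genome(cfg)
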