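import numpy as np
import pytest

from hicprep.digest import DigestFragment, DigestMap, parse_enzyme_spec


@pytest.fixture
def hindiii():
    return parse_enzyme_spec("A^AGCTT,HindIII")


@pytest.fixture
def mboi():
    return parse_enzyme_spec("^GATC,MboI")


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture
def toy_map(hindiii):
    """Three fragments tiling a 150 bp chromosome (cuts at 61 and 101)."""
    frags = [DigestFragment("chrT", 1, 60, 1, False, True),
             DigestFragment("chrT", 61, 100, 2, True, True),
             DigestFragment("chrT", 101, 150, 3, True, False)]
    return DigestMap(genome_id="toy", enzyme1=hindiii,
                     fragments={"chrT": frags})


def random_genome(rng, length):
    return "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))
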