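import numpy as np
import pytest

from circlecap.design import DesignConfig
from circlecap.digest import MSEI
from circlecap.genome_model import Reference


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def mseI():
    return MSEI


@pytest.fixture
def default_cfg():
    return DesignConfig()


def random_dna(rng, n, alphabet="ACGT"):
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), n)])


def scrubbed_random_dna(rng, n, forbidden="TTAA"):
    """Random DNA guaranteed to contain no occurrence of `forbidden`."""
    seq = list(random_dna(rng, n))
    s = "".join(seq)
    while forbidden in s:
        i = s.find(forbidden)
        choices = [b for b in "ACGT" if b != seq[i]]
        seq[i] = choices[rng.integers(0, len(choices))]
        s = "".join(seq)
    return s


def reference_with_planted_sites(rng, spacings, contig="c1"):
    """Build a Reference whose MseI fragments have exactly the given lengths.

    Independent of the package's synthetic generator: constructs the
    sequence by concatenating scrubbed random fragments and overwriting
    TTAA across each internal boundary (cut = site_start + 1).
    """
    total = sum(spacings)
    seq = list(scrubbed_random_dna(rng, total))
    pos = 0
    for spacing in spacings[:-1]:
        pos += spacing
        seq[pos - 1 : pos + 3] = list("TTAA")
    s = "".join(seq)
    # re-scrub accidental sites created by planting, outside planted windows
    planted = set()
    pos = 0
    for spacing in spacings[:-1]:
        pos += spacing
        planted.update(range(pos - 1, pos + 3))
    i = s.find("TTAA")
    while i != -1:
        window = set(range(i, i + 4))
        if not window <= planted:
            j = next(k for k in range(i, i + 4) if k not in planted)
            lst = list(s)
            choices = [b for b in "ACGT" if b != lst[j]]
            lst[j] = choices[rng.integers(0, len(choices))]
            s = "".join(lst)
            i = s.find("TTAA", max(0, i - 3))
        else:
            i = s.find("TTAA", i + 1)
    return Reference({contig: s})
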