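import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from introgramap import synthetic_data as sd
from introgramap.io_core import FragmentMatrix, LinkageMap, MarkerLocus

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def backbone():
    """The bundled 155-locus, 984-cM, 7-group backbone map."""
    return sd.default_backbone_map()


@pytest.fixture
def small_map():
    """Two linkage groups: 0-100 cM with loci every 10 cM, 0-50 cM every 10 cM."""
    loci = [MarkerLocus(f"g1_{i}", "codominant", 1, 10.0 * i) for i in range(11)]
    loci += [MarkerLocus(f"g2_{i}", "codominant", 2, 10.0 * i) for i in range(6)]
    return LinkageMap(loci)


@pytest.fixture
def toy_fragment_matrix():
    """4 lines x 5 fragments used in the species-specific counting examples."""
    calls = pd.DataFrame(
        [[1, 0, 1, 1, 1],
         [1, 0, 1, 0, 1],
         [0, 1, 1, 1, 1],
         [0, 1, 1, 0, 1]],
        index=["am1", "am2", "au1", "au2"],
        columns=["f1", "f2", "f3", "f4", "f5"],
        dtype=float,
    )
    return FragmentMatrix(calls)


def make_f2_dominant_counts(r, n, phase, rng):
    """Multinomial draw of a 2x2 dominant F2 presence table at true r."""
    k = (1 - r) ** 2 if phase == "coupling" else r ** 2
    probs = [(2 + k) / 4, (1 - k) / 4, (1 - k) / 4, k / 4]
    draw = rng.multinomial(n, probs)
    return np.array([[draw[0], draw[1]], [draw[2], draw[3]]], dtype=float)


def make_f2_codominant_counts(r, n, rng):
    """Multinomial draw of the 3x3 codominant F2 table at true r (coupling F1)."""
    hap = np.array([(1 - r) / 2, (1 - r) / 2, r / 2, r / 2])
    haps = [(0, 0), (1, 1), (0, 1), (1, 0)]
    probs = np.zeros((3, 3))
    for (a1, b1), p1 in zip(haps, hap):
        for (a2, b2), p2 in zip(haps, hap):
            probs[a1 + a2, b1 + b2] += p1 * p2
    draw = rng.multinomial(n, probs.ravel())
    return draw.reshape(3, 3).astype(float)
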