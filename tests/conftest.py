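import numpy as np
import pytest

from mhcdivkit.io_core import AlleleCatalog, PBRMask, PopulationSample


@pytest.fixture
def tiny_catalog():
    """Three 9-nt alleles: B differs from A synonymously (ACT→ACA), C
    nonsynonymously (GAT→AAT)."""
    return AlleleCatalog(
        {
            "A*001:01": "ACTGATTTT",
            "A*002:01": "ACAGATTTT",
            "A*003:01": "ACTAATTTT",
        }
    )


@pytest.fixture
def identity_mask_3():
    return PBRMask((1, 2, 3))


def make_sample(label, genotypes):
    return PopulationSample(label, list(genotypes))


def hw_sample(label, freqs, names, n, rng):
    """N genotypes drawn at Hardy–Weinberg proportions from freqs."""
    draws = rng.choice(len(names), size=(n, 2), p=np.asarray(freqs))
    return PopulationSample(label, [(names[a], names[b]) for a, b in draws])
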