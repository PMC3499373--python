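import numpy as np
import pytest

from starqt.simgen import GenotypeMatrix, VariantSite


def make_matrix(counts, mafs=None, sel_coeffs=None):
    """Build a GenotypeMatrix from a plain count array for tests."""
    counts = np.asarray(counts, dtype=np.int8)
    m = counts.shape[1]
    if mafs is None:
        mafs = np.clip(counts.mean(axis=0) / 2.0, 1e-6, 0.5)
    if sel_coeffs is None:
        sel_coeffs = np.zeros(m)
    sites = [
        VariantSite(site_id=f"s{j}", maf=float(mafs[j]), sel_coeff=float(sel_coeffs[j]))
        for j in range(m)
    ]
    return GenotypeMatrix(counts, sites)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def toy_region(rng):
    """20 individuals x 3 rare sites with centred residuals."""
    counts = rng.binomial(2, [0.05, 0.1, 0.02], size=(20, 3))
    G = make_matrix(counts)
    e = rng.standard_normal(20)
    e -= e.mean()
    return G, e
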