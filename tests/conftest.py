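import numpy as np
import pytest

from peprank.ramachandran import fit_angle_density
from peprank.synthetic import make_complex


@pytest.fixture(scope="session")
def density():
    """Angle-density model from a helix/sheet mixture pool."""
    rng = np.random.default_rng(42)
    phi = np.concatenate([rng.normal(-60, 12, 1400), rng.normal(-120, 18, 600)])
    psi = np.concatenate([rng.normal(-45, 12, 1400), rng.normal(130, 18, 600)])
    return fit_angle_density(np.column_stack([phi, psi]))


@pytest.fixture(scope="session")
def small_complex():
    """One synthetic complex (receptor shell + 5-residue peptide)."""
    return make_complex("CPLX", length=5, seed=11)
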