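import numpy as np
import pytest

from turnoverkit import EnrichmentCurve, KineticModelParams

DAYS = np.array([0.0, 1.0, 3.0, 5.0, 7.0, 10.0, 14.0])


@pytest.fixture(scope="session")
def enrichment():
    """Default mouse body-water enrichment curve used across tests."""
    return EnrichmentCurve(p_ss=0.045, k_p=2.0)


@pytest.fixture(scope="session")
def params(enrichment):
    """A representative peptide's kinetic model constants."""
    return KineticModelParams(a=0.5, n_sites=10, enrichment=enrichment)


@pytest.fixture(scope="session")
def days():
    return DAYS.copy()
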