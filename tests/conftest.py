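import numpy as np
import pytest

from plasmidpol.model_core import CellParams, EvolutionParams, PlasmidGenotype


@pytest.fixture
def p() -> CellParams:
    """Default host-cell parameter set used throughout the suite."""
    return CellParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)


@pytest.fixture
def cnc_genotype() -> PlasmidGenotype:
    """A genotype with full copy-number control, inside the stable region."""
    return PlasmidGenotype(alpha=0.06, kappa=0.05, beta=1.0)


@pytest.fixture
def nocnc_genotype() -> PlasmidGenotype:
    """A passively controlled genotype inside the narrow NO-CNC stable band."""
    return PlasmidGenotype(alpha=0.03, kappa=0.0, beta=0.0)


@pytest.fixture
def ev() -> EvolutionParams:
    return EvolutionParams()
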