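import numpy as np
import pytest

from protrefine.fixtures import FixtureSpec, build_peptide


@pytest.fixture(scope="session")
def helix_model():
    """Clash-free 12-residue ideal helix (small side chains)."""
    return build_peptide(FixtureSpec("AASLAEKAGSLA", conformation="helix"))


@pytest.fixture(scope="session")
def strand_model():
    """Clash-free 20-residue extended strand with all side-chain types."""
    return build_peptide(
        FixtureSpec("AVKLDEFSTAYHQNMRWICG", conformation="strand"))


@pytest.fixture(scope="session")
def coil_model():
    """Clash-free 16-residue coil used by closure and clustering tests."""
    return build_peptide(
        FixtureSpec("AVSLDSETAGSLKNQA", conformation="coil", seed=2))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
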