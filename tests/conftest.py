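import numpy as np
import pytest

from solscreen.fixtures import (
    DEFAULT_LIBRARY_SPEC,
    PEGPanelVariant,
    ToyStructureSpec,
    generate_library,
    generate_peg_series,
    generate_toy_structure,
)
from solscreen.screening import load_reference_panel


@pytest.fixture(scope="session")
def library():
    """The bundled default 9-variant synthetic antibody library."""
    return generate_library(DEFAULT_LIBRARY_SPEC)


@pytest.fixture(scope="session")
def reference_panel():
    """The packaged nine-variant characterization table."""
    return load_reference_panel()


@pytest.fixture(scope="session")
def noiseless_series():
    """Exact sigmoid data: a=1, b=0.05, s=2, midpoint 4.9, x = 0..16."""
    var = PEGPanelVariant("exact", peg_half=4.9, s=2.0, a=1.0, b=0.05, noise_sd=0.0)
    return generate_peg_series(var, x_grid=np.arange(0.0, 17.0), seed=0)


@pytest.fixture(scope="session")
def helix_patch():
    """Ideal helix whose central five residues form a hydrophobic patch."""
    seq = "KEKEKEKEKELLLLLKEKEKEKEKE"
    model = generate_toy_structure(ToyStructureSpec(sequence=seq))
    return seq, model
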