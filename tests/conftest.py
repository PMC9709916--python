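import warnings

import pytest

from torsionforge.chem import perceive


@pytest.fixture(autouse=True)
def _quiet_minimizer():
    # stalled-line-search warnings from tight ftol are expected noise here
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="minimization unconverged")
        yield


@pytest.fixture(scope="session")
def biphenyl():
    return perceive("c1ccccc1-c1ccccc1")


@pytest.fixture(scope="session")
def aspirin():
    return perceive("CC(=O)Oc1ccccc1C(=O)O")


@pytest.fixture(scope="session")
def butane():
    return perceive("CCCC")


# a panel of drug-like and plain molecules used by several property tests
PANEL_SMILES = [
    "CCO",
    "CCCC",
    "CC(C)C",
    "CC(=O)O",
    "CCOC",
    "c1ccccc1",
    "Cc1ccccc1",
    "CCc1ccccc1",
    "c1ccncc1",
    "CC(=O)Nc1ccccc1",
    "O=[N+]([O-])c1ccccc1",
    "CC(C)(C)c1ccccc1",
    "OCCN",
    "CSC",
    "CC(N)C(=O)O",
    "FC(F)(F)c1ccccc1",
    "CN1CCCC1",
    "COc1ccccc1",
    "CC#N",
    "ClCCCl",
]


@pytest.fixture(scope="session")
def molecule_panel():
    return [perceive(s) for s in PANEL_SMILES]
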