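import pytest

from cimccs.masscalc import ElementalFormula


@pytest.fixture(scope="session")
def rocuronium():
    """Quaternary-ammonium drug cation seen as [M]+ / [M+H]2+ (C32H53N2O4+)."""
    return ElementalFormula("C32H53N2O4")


@pytest.fixture(scope="session")
def leucine_enkephalin():
    """Lock-mass peptide, observed as [M+H]+ at m/z 556.2771."""
    return ElementalFormula("C28H37N5O7")
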