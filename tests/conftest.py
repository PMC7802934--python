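import pytest

from foldstab import (
    SyntheticSpec,
    make_toy_structure,
    make_training_bundle,
    parse_pdb,
    sasa_profile,
)

HELIX20_SEQ = "LKVADELFWYRICHMNQSTG"


@pytest.fixture(scope="session")
def helix20():
    """Parsed 20-residue toy hairpin with a mixed sequence."""
    return parse_pdb(make_toy_structure(sequence=HELIX20_SEQ, seed=7), id="HX20")


@pytest.fixture(scope="session")
def helix20_sasa(helix20):
    return sasa_profile(helix20)


@pytest.fixture(scope="session")
def small_bundle():
    """Small synthetic study: 4 proteins, 200 mutations after augmentation."""
    spec = SyntheticSpec(
        n_proteins=4, residues_per_protein=40, mutations_per_protein=25, seed=3
    )
    return make_training_bundle(spec)


@pytest.fixture(scope="session")
def default_bundle():
    """The default-condition synthetic study (12 proteins, ~2000 mutations)."""
    return make_training_bundle(SyntheticSpec(seed=1))
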