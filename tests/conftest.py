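import numpy as np
import pytest

from varmech import generate_proteome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_proteome():
    return generate_proteome(n_proteins=10, length_range=(60, 120),
                             low_conf_rate=0.3, seed=7)


@pytest.fixture
def two_residue_pdb(tmp_path):
    """Minimal hand-written PDB: two residues, B-factors 91.0 / 55.0."""
    text = (
        "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 91.00           C\n"
        "ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00 55.00           C\n"
        "END\n"
    )
    path = tmp_path / "mini.pdb"
    path.write_text(text)
    return path
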