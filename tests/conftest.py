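import numpy as np
import pytest

from peptraj.synthetic import (
    SSK36_SEQUENCE,
    build_complex_topology,
    build_template,
)


@pytest.fixture(scope="session")
def peptide_templates():
    """(topology, hairpin_frame, extended_frame) for the designed peptide."""
    topology, hairpin = build_template("hairpin", SSK36_SEQUENCE)
    _, extended = build_template("extended", SSK36_SEQUENCE)
    return topology, hairpin, extended


@pytest.fixture(scope="session")
def complex_topology():
    return build_complex_topology()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def single_model_pdb(tmp_path):
    """Minimal hand-written PDB: one ALA with N, CA, C plus one hydrogen."""
    text = (
        "ATOM      1  N   ALA A  29       1.000   2.000   3.000  1.00  0.00           N\n"
        "ATOM      2  CA  ALA A  29       2.458   2.000   3.000  1.00  0.00           C\n"
        "ATOM      3  C   ALA A  29       3.009   3.420   3.000  1.00  0.00           C\n"
        "ATOM      4  HA  ALA A  29       2.800   1.500   2.100  1.00  0.00           H\n"
        "END\n"
    )
    path = tmp_path / "ala.pdb"
    path.write_text(text)
    return path
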