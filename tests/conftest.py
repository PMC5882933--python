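import numpy as np
import pytest

from fragcharge.fixtures import PeptideSpec, build_peptide, make_contact_fixture


@pytest.fixture(scope="session")
def ala3():
    """Tripeptide AAA, helical torsions."""
    return build_peptide(PeptideSpec("AAA", -57.0, -47.0))


@pytest.fixture(scope="session")
def penta():
    """Extended mixed pentapeptide (no two-body contacts at 4 A)."""
    return build_peptide(PeptideSpec("AGSVA", -135.0, 135.0))


@pytest.fixture(scope="session")
def penta_charged():
    """Pentapeptide carrying GLU(-1) and LYS(+1)."""
    return build_peptide(PeptideSpec("AEKVA", -135.0, 135.0))


@pytest.fixture(scope="session")
def contact():
    """Folded hexapeptide with at least one (i, i+3) contact at 4 A."""
    return make_contact_fixture(1, 4.0)


def brute_force_pairs(structure, lam):
    """O(n^2) oracle for two-body pair enumeration (all atoms)."""
    pos = structure.positions()
    res = structure.residue_of_atom()
    found = set()
    if lam <= 0:
        return found
    for a in range(len(pos)):
        for b in range(a + 1, len(pos)):
            i, j = res[a], res[b]
            if abs(i - j) < 3:
                continue
            if np.linalg.norm(pos[a] - pos[b]) <= lam:
                found.add((min(i, j), max(i, j)))
    return found
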