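"""Shared fixtures: all test structures are generated programmatically."""

from __future__ import annotations

import pytest

from ppi_missense.fixtures import Contact, FixtureSpec, make_dimer, make_pocket_dimer


@pytest.fixture(scope="session")
def salt_bridge_dimer():
    """Two strands with an engineered Lys(A4)-Glu(B4) bridge at 3.0 Å."""
    return make_dimer(FixtureSpec(
        n_residues_per_chain=7,
        engineered_contacts=[Contact(4, 4, "salt_bridge", 3.0)],
    ))


@pytest.fixture(scope="session")
def separated_dimer():
    """Two strands 50 Å apart: no interface anywhere."""
    return make_dimer(FixtureSpec(n_residues_per_chain=7, separation=50.0))


@pytest.fixture(scope="session")
def core_pocket():
    """(structure, site_key) with a Lys-Glu bridge and a core-buried site."""
    return make_pocket_dimer("LYS", "GLU", 3.0, "core")


@pytest.fixture(scope="session")
def rim_pocket():
    """(structure, site_key) with the same chemistry at rim burial."""
    return make_pocket_dimer("LYS", "GLU", 3.0, "rim")
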