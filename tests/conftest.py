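"""Shared fixtures: toy complexes, topologies and a ground-truth ensemble.

Everything is generated programmatically; the heavier simulation fixtures
are session-scoped so the dynamics run once and are reused across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from rigidflex.engine import SimulationConfig, run
from rigidflex.forcefield import ForceFieldParams, build_topology
from rigidflex.structure_io import Residue, Structure
from rigidflex.synthetic import ToySpec, make_toy_complex

THREE_RESIDUE_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  ALA A   3       7.600   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture()
def three_residue_pdb(tmp_path):
    p = tmp_path / "three.pdb"
    p.write_text(THREE_RESIDUE_PDB)
    return p


@pytest.fixture()
def flexible_chain_10():
    """Fully flexible 10-residue chain (no deposited coordinates)."""
    st = Structure(chains=["A"],
                   residues={"A": [Residue(i, "ALA", None)
                                   for i in range(1, 11)]})
    return build_topology(st, {"A": (1, 10)})


@pytest.fixture(scope="session")
def toy_spec():
    return ToySpec()  # 60-bead core, one 20-residue tail


@pytest.fixture(scope="session")
def toy_structure(toy_spec):
    return make_toy_complex(toy_spec)


@pytest.fixture(scope="session")
def toy_topology(toy_structure):
    st, _ = toy_structure
    return build_topology(st, {"A": (1, 80)})


@pytest.fixture(scope="session")
def core_topology():
    """60-bead rigid helix bundle with no flexible residues."""
    st, _ = make_toy_complex(ToySpec(flexible_chains=[]))
    return build_topology(st, {"A": (1, 60)})


@pytest.fixture(scope="session")
def ground_truth(toy_topology):
    """Reference ensemble for cross-link sampling and SAXS synthesis.

    Run at a different temperature and seed than any test simulation so
    recovery checks are not circular at the trajectory level.
    """
    cfg = SimulationConfig(timestep=0.01, temperature=280.0, seed=4242,
                           total_time=600.0, save_interval=4.0)
    return run(toy_topology, ForceFieldParams(), cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
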