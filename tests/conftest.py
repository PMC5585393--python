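import numpy as np
import pytest

from oligoqs.structure_model import Assembly, Chain, Residue
from oligoqs.synthetic_fixtures import OligomerSpec, make_oligomer


def build_chain(chain_id, sequence, coords, extra_atoms=None):
    """Chain with one CB (representative) atom per residue at the given
    coordinates, plus a CA 1 Å below (so chains are not Cα traces)."""
    residues = []
    for i, (aa, xyz) in enumerate(zip(sequence, coords)):
        xyz = np.asarray(xyz, dtype=float)
        atoms = [("CA", xyz - np.array([0.0, 0.0, 1.0]), 20.0),
                 ("CB", xyz, 20.0)]
        if extra_atoms:
            atoms.extend(extra_atoms)
        residues.append(Residue((chain_id, i + 1, ""), aa, atoms, xyz))
    return Chain(chain_id, sequence, residues)


def line_chain(chain_id, sequence, origin=(0.0, 0.0, 0.0),
               step=(3.8, 0.0, 0.0)):
    o, s = np.asarray(origin, float), np.asarray(step, float)
    return build_chain(chain_id, sequence,
                       [o + i * s for i in range(len(sequence))])


@pytest.fixture(scope="session")
def c2_dimer():
    return make_oligomer(OligomerSpec(2, "C2", 30, "homo", seed=101))


@pytest.fixture(scope="session")
def c3_trimer():
    return make_oligomer(OligomerSpec(3, "C3", 30, "homo", seed=102))


@pytest.fixture(scope="session")
def d2_tetramer():
    return make_oligomer(OligomerSpec(4, "D2", 30, "homo", seed=103))


@pytest.fixture(scope="session")
def a2b2():
    return make_oligomer(OligomerSpec(4, "C2", 30, "hetero", seed=104))


@pytest.fixture(scope="session")
def dimer_context(c2_dimer):
    """Conservation context of chain A of the C2 dimer, with the
    contact-based interface designation; returns (ctx, interface query
    positions, chain length)."""
    from oligoqs.contact_map import contact_interface_residues, \
        interface_contacts
    from oligoqs.ppi_fingerprint import build_chain_context

    iface = {r for r in contact_interface_residues(
        interface_contacts(c2_dimer)) if r[0] == "A"}
    ctx = build_chain_context(c2_dimer, "A", interface_residue_ids=iface)
    positions = tuple(sorted(r[1] - 1 for r in iface))
    return ctx, positions, len(c2_dimer.chains[0].residues)


@pytest.fixture(scope="session")
def buried_assembly():
    """Two chains engineered so the last residue of chain A is solvent
    exposed in isolation but encaged by chain B in the assembly."""
    seq_a = "ACDEF"
    chain_a = line_chain("A", seq_a)
    target = np.array([(len(seq_a) - 1) * 3.8, 0.0, 0.0])
    n = 40
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    dirs = np.column_stack((np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta), np.cos(phi)))
    dirs = dirs[dirs[:, 0] > -0.45]  # leave the side facing chain A open
    residues = []
    for k, d in enumerate(dirs):
        xyz = target + 4.2 * d
        residues.append(Residue(("B", k + 1, ""), "A",
                                [("CB", xyz, 20.0)], xyz))
    chain_b = Chain("B", "A" * len(residues), residues)
    return Assembly("buried", [chain_a, chain_b])
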