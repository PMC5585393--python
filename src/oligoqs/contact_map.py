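"""Inter-chain residue contacts on representative (Cβ / Cα-for-Gly) atoms.

A contact is a pair of residues on *different* chains whose representative
coordinates are strictly closer than the cutoff (12 Å by default — the
interface definition used by the QS-score).  Residues without a
representative coordinate are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure_model import Assembly

DEFAULT_CUTOFF = 12.0  # Å


@dataclass
class ContactSet:
    """Inter-chain contacts: ``{(res_id_1, res_id_2): distance}`` with
    ``res_id_1 < res_id_2`` lexicographically."""

    contacts: dict
    cutoff: float

    def __len__(self):
        return len(self.contacts)

    def __contains__(self, pair):
        return tuple(sorted(pair)) in self.contacts

    def distance(self, pair) -> float:
        return self.contacts[tuple(sorted(pair))]


def interface_contacts(a: Assembly, cutoff: float = DEFAULT_CUTOFF) -> ContactSet:
    """All inter-chain residue pairs with rep-coordinate distance < cutoff.

    Uses a k-d tree; equivalent to brute-force all-pairs enumeration.
    """
    ids, coords, chains = [], [], []
    for chain in a.chains:
        rids, xyz = chain.rep_coords()
        ids.extend(rids)
        chains.extend([chain.chain_id] * len(rids))
        if len(rids):
            coords.append(xyz)
    contacts = {}
    if not coords:
        return ContactSet(contacts, cutoff)
    coords = np.vstack(coords)
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(r=cutoff):
        if chains[i] == chains[j]:
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d < cutoff:  # strict inequality at the boundary
            key = tuple(sorted((ids[i], ids[j])))
            contacts[key] = d
    return ContactSet(contacts, cutoff)


def contact_interface_residues(cs: ContactSet) -> set:
    """Residue ids participating in at least one inter-chain contact.

    This is the contact-based view of an interface (the one the QS-score
    is built on); the accessibility-based 25% classification is the
    complementary, burial-based view.
    """
    out = set()
    for r1, r2 in cs.contacts:
        out.add(r1)
        out.add(r2)
    return out


def write_contacts_tsv(cs: ContactSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("chain1\tres1\ticode1\tchain2\tres2\ticode2\tdistance\n")
        for (r1, r2), d in sorted(cs.contacts.items()):
            fh.write(f"{r1[0]}\t{r1[1]}\t{r1[2]}\t"
                     f"{r2[0]}\t{r2[1]}\t{r2[2]}\t{d:.3f}\n")
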