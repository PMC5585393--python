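"""Solvent accessibility and core / surface / interface residue classes.

Accessible surface area is computed with the Shrake–Rupley algorithm
(deterministic golden-spiral test points, probe 1.4 Å, 960 points per atom
by default).  Relative accessibilities use the theoretical maximal ASA per
residue type of Tien et al. (2013).

Classification follows the 25% rules used for interface analysis:

* **surface** — relative accessibility of the residue in the isolated
  chain (rASA) above 25%;
* **interface** — relative buried surface area (rBSA) above 25% *and*
  rASA in the full assembly below 25%;
* **core** — everything else.

A residue can satisfy both the surface and the interface definition;
interface takes precedence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure_model import Assembly, Chain

PROBE_RADIUS = 1.4  # Å, water probe
N_POINTS = 960
RASA_CUT = 0.25

# Theoretical maximal ASA (Å^2), Tien et al. 2013
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
    "X": 200.0,
}

# van der Waals radii (Å) by element
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
             "SE": 1.90, "H": 1.20}
DEFAULT_RADIUS = 1.70


@dataclass
class AccessibilityRecord:
    """Per-residue accessibility in monomer and assembly context."""

    res_id: tuple
    aa: str
    asa_monomer: float     # Å², chain in isolation
    asa_assembly: float    # Å², full assembly
    rasa: float            # asa_monomer / max ASA
    rasa_assembly: float   # asa_assembly / max ASA
    rbsa: float            # (asa_monomer - asa_assembly) / max ASA


@dataclass
class ResidueClassification:
    res_id: tuple
    label: str  # core | surface | interface


def _element_radius(atom_name: str) -> float:
    name = atom_name.strip().lstrip("0123456789")
    if name[:2].upper() == "SE":
        return VDW_RADII["SE"]
    return VDW_RADII.get(name[0].upper(), DEFAULT_RADIUS)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack((np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)))


def shrake_rupley(coords: np.ndarray, radii: np.ndarray,
                  probe_radius: float = PROBE_RADIUS,
                  n_points: int = N_POINTS) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²).

    For each atom, ``n_points`` test points are placed on the expanded
    sphere of radius ``r_i + probe``; a point is accessible when it lies
    outside every neighbour's expanded sphere.  ASA_i = exposed fraction
    times the expanded-sphere area.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or coords.shape[0] == 0:
        raise ValueError("need at least one atom with coordinates")
    n = coords.shape[0]
    expanded = radii + probe_radius
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    asa = np.empty(n)
    for i in range(n):
        pts = coords[i] + expanded[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], max_reach)
                     if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 > expanded[j] ** 2
        asa[i] = exposed.mean() * 4.0 * np.pi * expanded[i] ** 2
    return asa


def _chain_atoms(chain: Chain):
    coords, radii, owner = [], [], []
    for ridx, res in enumerate(chain.residues):
        for name, xyz, _ in res.atoms:
            coords.append(xyz)
            radii.append(_element_radius(name))
            owner.append(ridx)
    return np.asarray(coords, float), np.asarray(radii, float), owner


def compute_sasa(a: Assembly, context: str = "assembly",
                 probe_radius: float = PROBE_RADIUS,
                 n_points: int = N_POINTS) -> dict:
    """Per-residue ASA (Å²) as ``{res_id: asa}``.

    ``context="monomer"`` treats each chain in isolation;
    ``context="assembly"`` uses all atoms of the assembly.
    """
    if context not in ("monomer", "assembly"):
        raise ValueError(f"unknown context {context!r}")
    out = {}
    if context == "monomer":
        for chain in a.chains:
            coords, radii, owner = _chain_atoms(chain)
            if coords.shape[0] == 0:
                raise ValueError(f"chain {chain.chain_id} has no heavy atoms")
            atom_asa = shrake_rupley(coords, radii, probe_radius, n_points)
            for ridx, res in enumerate(chain.residues):
                out[res.res_id] = 0.0
            for asa_val, ridx in zip(atom_asa, owner):
                rid = chain.residues[ridx].res_id
                out[rid] += asa_val
    else:
        coords, radii, owners = [], [], []
        for chain in a.chains:
            c, r, own = _chain_atoms(chain)
            if c.shape[0] == 0:
                raise ValueError(f"chain {chain.chain_id} has no heavy atoms")
            coords.append(c)
            radii.append(r)
            owners.extend((chain.chain_id, ridx) for ridx in own)
        coords = np.vstack(coords)
        radii = np.concatenate(radii)
        atom_asa = shrake_rupley(coords, radii, probe_radius, n_points)
        for chain in a.chains:
            for res in chain.residues:
                out[res.res_id] = 0.0
        for asa_val, (cid, ridx) in zip(atom_asa, owners):
            rid = a.chain(cid).residues[ridx].res_id
            out[rid] += asa_val
    return out


def accessibility_records(a: Assembly, probe_radius: float = PROBE_RADIUS,
                          n_points: int = N_POINTS) -> list:
    """Monomer + assembly ASA and the derived rASA / rBSA per residue."""
    mono = compute_sasa(a, "monomer", probe_radius, n_points)
    asm = compute_sasa(a, "assembly", probe_radius, n_points)
    records = []
    for chain in a.chains:
        for res in chain.residues:
            ref = MAX_ASA.get(res.aa, MAX_ASA["X"])
            am, aa_ = mono[res.res_id], asm[res.res_id]
            records.append(AccessibilityRecord(
                res_id=res.res_id, aa=res.aa,
                asa_monomer=am, asa_assembly=aa_,
                rasa=am / ref, rasa_assembly=aa_ / ref,
                rbsa=(am - aa_) / ref))
    return records


def classify_residues(records: list) -> list:
    """Core / surface / interface labels from the 25% rules.

    Interface takes precedence over surface when a residue satisfies both.
    """
    out = []
    for rec in records:
        if rec.rbsa > RASA_CUT and rec.rasa_assembly < RASA_CUT:
            label = "interface"
        elif rec.rasa > RASA_CUT:
            label = "surface"
        else:
            label = "core"
        out.append(ResidueClassification(rec.res_id, label))
    return out


def interaction_bsa(a: Assembly, chain_pair,
                    probe_radius: float = PROBE_RADIUS,
                    n_points: int = N_POINTS) -> float:
    """Buried surface area (Å²) of one chain-chain interaction.

    Half the total ASA lost by the two chains on pairing, the standard
    per-interface BSA.  Used e.g. to filter out spurious crystal-packing
    interactions (BSA below ~250 Å²).
    """
    cid1, cid2 = chain_pair
    c1, c2 = a.chain(cid1), a.chain(cid2)
    pair = Assembly(a.id + f"_{cid1}{cid2}",
                    [Chain(c1.chain_id, c1.sequence, c1.residues),
                     Chain(c2.chain_id, c2.sequence, c2.residues)],
                    a.source_format)
    mono = compute_sasa(pair, "monomer", probe_radius, n_points)
    complex_ = compute_sasa(pair, "assembly", probe_radius, n_points)
    lost = sum(mono[rid] - complex_[rid] for rid in mono)
    return max(0.0, 0.5 * lost)


def write_classification_tsv(records: list, classifications: list, path):
    """TSV export: chain, resnum, icode, aa, ASA values, rASA, rBSA, label."""
    label_of = {c.res_id: c.label for c in classifications}
    with open(path, "w") as fh:
        fh.write("chain\tresnum\ticode\taa\tasa_monomer\tasa_assembly"
                 "\trASA\trBSA\tlabel\n")
        for rec in records:
            cid, num, icode = rec.res_id
            fh.write(f"{cid}\t{num}\t{icode}\t{rec.aa}\t"
                     f"{rec.asa_monomer:.2f}\t{rec.asa_assembly:.2f}\t"
                     f"{rec.rasa:.4f}\t{rec.rbsa:.4f}\t"
                     f"{label_of[rec.res_id]}\n")
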