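"""Seeded generators for toy oligomers and controlled MSAs.

The oligomer generator arranges idealised chains (Cα at 3.8 Å spacing along
circular arcs, pseudo-Cβ 1.5 Å outward) so that chains touch across
designed interfaces, and applies exact symmetry operators (C2/C3/C4/D2).
Physical realism is deliberately limited to what the downstream modules
consume: inter-chain contacts, solvent accessibility, and rigid geometry.

The MSA generator emulates a protein family with differential selective
pressure: sequences are placed on a ladder of identities to the query, and
substitutions hit interface columns at rate ``r_i`` and surface columns at
rate ``r_s`` (uniform over the 19 alternatives).  Rates are renormalised so
each row realises its requested overall identity; per-row substitution
counts are exact, positions random, keeping realized identities within
rounding of the ladder.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .structure_model import (Assembly, Chain, Residue,
                              group_chemical_entities, write_pdb)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
CA_SPACING = 3.8   # Å along the arc
CB_OFFSET = 1.5    # Å radially outward
CHAIN_GAP = 5.0    # Å arc gap between consecutive chains
STACK_DZ = 5.5     # Å vertical offset between stacked hetero partners


class InfeasibleSpecError(ValueError):
    pass


@dataclass
class OligomerSpec:
    n_chains: int
    symmetry: str = "C2"           # C2 | C3 | C4 | D2 | none
    chain_length: int = 30
    composition: str = "homo"      # homo | hetero
    seed: int = 0


@dataclass
class MSASpec:
    n_sequences: int = 40
    length: int = 60
    interface_columns: tuple = ()
    r_i: float = 1.0               # interface substitution rate
    r_s: float = 1.0               # surface substitution rate
    identity_ladder: tuple | None = None
    r_i_schedule: tuple | None = None  # ((identity_floor, rate), ...) desc
    seed: int = 0


# ---------------------------------------------------------------------------
# rotations

def _rot_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


# ---------------------------------------------------------------------------
# oligomers

def _random_sequence(rng, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def _arc_chain(chain_id: str, sequence: str, radius: float,
               angle0: float, z_base: float, rng) -> Chain:
    """One chain along a circular arc with a gentle z undulation.

    Residues carry an idealised five-atom backbone+Cβ (N, CA, C, O, CB);
    the Cβ points radially outward and is the representative atom.
    """
    residues = []
    for i, aa in enumerate(sequence):
        phi = angle0 + (i * CA_SPACING) / radius
        z = z_base + 1.0 * np.sin(0.7 * i)

        def pt(d_arc, d_r, d_z):
            ang = phi + d_arc / radius
            return np.array([(radius + d_r) * np.cos(ang),
                             (radius + d_r) * np.sin(ang), z + d_z])

        bf = float(rng.uniform(10.0, 50.0))
        atoms = [("N", pt(-1.25, 0.0, 0.3), bf),
                 ("CA", pt(0.0, 0.0, 0.0), bf),
                 ("C", pt(1.25, 0.0, -0.3), bf),
                 ("O", pt(1.45, -0.8, -0.3), bf)]
        if aa != "G":
            atoms.append(("CB", pt(0.0, CB_OFFSET, 0.5), bf))
        rep = atoms[-1][1] if aa != "G" else atoms[1][1]
        residues.append(Residue((chain_id, i + 1, ""), aa, atoms, rep))
    return Chain(chain_id, sequence, residues)


def _transform_chain(chain: Chain, new_id: str, rot: np.ndarray,
                     trans: np.ndarray | None = None) -> Chain:
    trans = np.zeros(3) if trans is None else trans
    residues = []
    for res in chain.residues:
        atoms = [(n, rot @ xyz + trans, b) for n, xyz, b in res.atoms]
        rep = None if res.rep_coord is None else rot @ res.rep_coord + trans
        residues.append(Residue((new_id, res.res_id[1], res.res_id[2]),
                                res.aa, atoms, rep, res.rep_is_fallback))
    return Chain(new_id, chain.sequence, residues)


def _chain_letters(n: int):
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    if n <= len(alphabet):
        return list(alphabet[:n])
    return [f"{alphabet[i % 26]}{i // 26}" for i in range(n)]


def make_oligomer(spec: OligomerSpec, out_path=None) -> Assembly:
    """Build a toy oligomer satisfying the requested symmetry exactly.

    Raises :class:`InfeasibleSpecError` for inconsistent specs (wrong chain
    count for the symmetry, unsupported combinations).
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.chain_length
    if L < 20:
        raise InfeasibleSpecError("chains shorter than 20 residues are "
                                  "filtered out on reading")
    sym = spec.symmetry

    if sym in ("C2", "C3", "C4"):
        n_sym = int(sym[1])
        expected = n_sym if spec.composition == "homo" else 2 * n_sym
        if spec.n_chains != expected:
            raise InfeasibleSpecError(
                f"{sym} {spec.composition} requires {expected} chains, "
                f"got {spec.n_chains}")
        span = 2.0 * np.pi / n_sym
        radius = ((L - 1) * CA_SPACING + CHAIN_GAP) / span
        gap_angle = CHAIN_GAP / radius
        if spec.composition == "homo":
            seq = _random_sequence(rng, L)
            unit = [_arc_chain("U0", seq, radius, gap_angle / 2.0, 0.0, rng)]
        else:
            seq_a = _random_sequence(rng, L)
            seq_b = _random_sequence(rng, L)
            unit = [
                _arc_chain("U0", seq_a, radius, gap_angle / 2.0,
                           +STACK_DZ / 2.0, rng),
                _arc_chain("U1", seq_b, radius, gap_angle / 2.0,
                           -STACK_DZ / 2.0, rng),
            ]
        ops = [_rot_z(k * span) for k in range(n_sym)]
    elif sym == "D2":
        if spec.composition != "homo" or spec.n_chains != 4:
            raise InfeasibleSpecError("D2 fixtures are homotetramers "
                                      "(4 chains)")
        span = np.pi
        radius = ((L - 1) * CA_SPACING + CHAIN_GAP) / span
        gap_angle = CHAIN_GAP / radius
        seq = _random_sequence(rng, L)
        unit = [_arc_chain("U0", seq, radius,
                           -span / 2.0 + gap_angle / 2.0, 3.0, rng)]
        ops = [np.eye(3), _rot_z(np.pi), _rot_y(np.pi),
               _rot_z(np.pi) @ _rot_y(np.pi)]
    elif sym == "none":
        if spec.n_chains < 1:
            raise InfeasibleSpecError("need at least one chain")
        chains = []
        letters = _chain_letters(spec.n_chains)
        radius = ((L - 1) * CA_SPACING + CHAIN_GAP) / (2.0 * np.pi / 3.0)
        for k in range(spec.n_chains):
            seq = _random_sequence(rng, L)
            chains.append(_arc_chain(letters[k], seq, radius,
                                     0.0, STACK_DZ * k, rng))
        a = Assembly(f"oligomer_none_{spec.seed}", chains)
        group_chemical_entities(a)
        if out_path is not None:
            write_pdb(a, out_path)
        return a
    else:
        raise InfeasibleSpecError(f"unknown symmetry {sym!r}")

    letters = _chain_letters(len(ops) * len(unit))
    chains = []
    idx = 0
    for op in ops:
        for uchain in unit:
            chains.append(_transform_chain(uchain, letters[idx], op))
            idx += 1
    a = Assembly(f"oligomer_{sym}_{spec.composition}_{spec.seed}", chains)
    group_chemical_entities(a)
    if out_path is not None:
        write_pdb(a, out_path)
    return a


def clone_assembly(a: Assembly, new_id: str | None = None) -> Assembly:
    b = copy.deepcopy(a)
    if new_id is not None:
        b.id = new_id
    return b


def perturb_assembly(a: Assembly, sigma: float = 0.0, mode: str = "jitter",
                     seed: int = 0, n_keep: int | None = None) -> Assembly:
    """Controlled perturbations of an assembly.

    ``jitter`` adds isotropic Gaussian noise of scale ``sigma`` to every
    atom; ``swap_interface`` re-stacks all chains on top of the first one
    (an alternative binding mode with disjoint contacts); ``subcomplex``
    keeps the first ``n_keep`` chains (stoichiometry change).
    """
    rng = np.random.default_rng(seed)
    b = clone_assembly(a, f"{a.id}_{mode}{seed}")
    if mode == "jitter":
        for chain in b.chains:
            for res in chain.residues:
                res.atoms = [(n, xyz + rng.normal(0.0, sigma, 3), bf)
                             for n, xyz, bf in res.atoms]
                _reset_rep(res)
    elif mode == "swap_interface":
        ref = _chain_centroid(b.chains[0])
        for k, chain in enumerate(b.chains[1:], start=1):
            shift = ref - _chain_centroid(chain) + np.array(
                [0.0, 0.0, (STACK_DZ + 1.0) * k])
            for res in chain.residues:
                res.atoms = [(n, xyz + shift, bf) for n, xyz, bf in res.atoms]
                _reset_rep(res)
    elif mode == "subcomplex":
        keep = n_keep if n_keep is not None else max(1, len(b.chains) // 2)
        b.chains = b.chains[:keep]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return b


def _chain_centroid(chain: Chain) -> np.ndarray:
    pts = np.vstack([xyz for res in chain.residues
                     for _, xyz, _ in res.atoms])
    return pts.mean(axis=0)


def _reset_rep(res: Residue) -> None:
    names = {n: xyz for n, xyz, _ in res.atoms}
    res.rep_coord = names.get("CB", names.get("CA"))


# ---------------------------------------------------------------------------
# MSAs

def _rate_at(spec: MSASpec, identity: float) -> float:
    if spec.r_i_schedule:
        for floor, rate in sorted(spec.r_i_schedule, reverse=True):
            if identity >= floor:
                return rate
    return spec.r_i


def make_msa(spec: MSASpec, out_path=None) -> list:
    """Query plus mutated copies along the identity ladder.

    Returns ``[(name, sequence), ...]`` with the query first; optionally
    writes an aligned FASTA.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    interface = sorted(set(spec.interface_columns))
    if any(c < 0 or c >= L for c in interface):
        raise ValueError("interface columns out of range")
    surface = [c for c in range(L) if c not in set(interface)]
    query = _random_sequence(rng, L)
    ladder = spec.identity_ladder
    if ladder is None:
        ladder = tuple(np.linspace(0.97, 0.12, spec.n_sequences))
    rows = [("query", query)]
    for k, ident in enumerate(ladder):
        r_i = _rate_at(spec, ident)
        m = int(round((1.0 - ident) * L))
        w_i = r_i * len(interface)
        w_s = spec.r_s * len(surface)
        if w_i + w_s == 0:
            m_i = m_s = 0
        else:
            m_i = min(len(interface), int(round(m * w_i / (w_i + w_s))))
            m_s = min(len(surface), m - m_i)
            short = m - m_i - m_s
            if short > 0 and r_i > 0:
                # surface saturated; spill into the interface unless its
                # rate is zero (rate semantics beat the identity request)
                m_i = min(len(interface), m_i + short)
        seq = list(query)
        if m_i:
            for c in rng.choice(interface, size=m_i, replace=False):
                seq[c] = _mutate(rng, seq[c])
        if m_s:
            for c in rng.choice(surface, size=m_s, replace=False):
                seq[c] = _mutate(rng, seq[c])
        rows.append((f"seq{k:03d}_id{ident:.2f}", "".join(seq)))
    if out_path is not None:
        write_msa(rows, out_path)
    return rows


def _mutate(rng, aa: str) -> str:
    choices = [x for x in AA20 if x != aa]
    return choices[rng.integers(len(choices))]


def write_msa(rows: list, path) -> None:
    with open(path, "w") as fh:
        for name, seq in rows:
            fh.write(f">{name}\n{seq}\n")
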