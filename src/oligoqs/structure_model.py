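"""Multi-chain protein assemblies: parsing, representation, entity grouping.

An :class:`Assembly` is an ordered collection of polypeptide chains with
per-residue coordinates.  Every residue carries a representative coordinate
(``rep_coord``): the Cβ atom, or Cα for glycine.  All inter-chain contacts
and superpositions downstream operate on these representative points, which
makes assemblies with different side chains directly comparable.

Chains are grouped into *chemical entities*: transitive closure of the
relation "globally alignable at >= 95% sequence identity over >= 90% mutual
coverage".  The entity partition underlies stoichiometry strings (``A2B2``)
and the chain-mapping search space.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass

import gemmi
import networkx as nx
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

MIN_CHAIN_LENGTH = 20  # peptide filter: shorter chains are dropped on read
ENTITY_IDENTITY = 0.95
ENTITY_COVERAGE = 0.90


class FormatError(ValueError):
    """The input file could not be parsed as PDB/mmCIF."""


class EmptyAssemblyError(ValueError):
    """No chain survived the peptide / Cα-trace filters."""


@dataclass
class Residue:
    """One amino-acid residue.

    ``res_id`` is ``(chain_id, residue_number, insertion_code)`` and is the
    stable key used everywhere (contacts, SASA records, mappings).
    ``rep_coord`` is the Cβ coordinate (Cα for Gly); ``None`` when neither
    atom is present, in which case the residue is excluded from contact
    computations.
    """

    res_id: tuple
    aa: str
    atoms: list  # of (atom_name, np.ndarray shape (3,), b_factor)
    rep_coord: np.ndarray | None = None
    rep_is_fallback: bool = False  # Cα used for a non-Gly residue

    def atom_coords(self) -> np.ndarray:
        return np.array([xyz for _, xyz, _ in self.atoms], dtype=float)

    def mean_bfactor(self) -> float:
        return float(np.mean([b for _, _, b in self.atoms]))


@dataclass
class Chain:
    chain_id: str
    sequence: str
    residues: list
    entity_key: int = -1

    def __post_init__(self):
        if len(self.sequence) != len(self.residues):
            raise ValueError("sequence length must equal residue count")

    def rep_coords(self):
        """(res_id list, coordinate array) for residues with a rep_coord."""
        ids, xyz = [], []
        for r in self.residues:
            if r.rep_coord is not None:
                ids.append(r.res_id)
                xyz.append(r.rep_coord)
        return ids, np.asarray(xyz, dtype=float)


@dataclass
class Assembly:
    id: str
    chains: list
    source_format: str = "pdb"

    def __post_init__(self):
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError("chain identifiers must be unique")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    def residue(self, res_id: tuple) -> Residue:
        c = self.chain(res_id[0])
        for r in c.residues:
            if r.res_id == res_id:
                return r
        raise KeyError(res_id)

    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)


# ---------------------------------------------------------------------------
# parsing

def _one_letter(resname: str) -> str | None:
    """One-letter code; modified residues map to their parent, unknown -> X.

    Returns None for non-amino-acid residues (waters, ligands, nucleotides).
    """
    info = gemmi.find_tabulated_residue(resname)
    if info is None:
        return "X"
    if not info.is_amino_acid():
        return None
    code = info.one_letter_code.upper()
    return code if code.isalpha() and code != " " else "X"


def _best_altloc_atoms(res: gemmi.Residue):
    """Keep, per atom name, the highest-occupancy conformer."""
    best = {}
    for atom in res:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    return list(best.values())


def _convert_residue(chain_id: str, res: gemmi.Residue) -> Residue | None:
    aa = _one_letter(res.name)
    if aa is None:
        return None
    atoms = []
    for atom in _best_altloc_atoms(res):
        if atom.element.name == "H":
            continue
        pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z], dtype=float)
        atoms.append((atom.name, pos, float(atom.b_iso)))
    if not atoms:
        return None
    names = {n for n, _, _ in atoms}
    rep = None
    fallback = False
    if "CB" in names:
        rep = next(x for n, x, _ in atoms if n == "CB")
    elif "CA" in names:
        rep = next(x for n, x, _ in atoms if n == "CA")
        fallback = aa != "G"
        if fallback:
            logger.warning("residue %s %s%s lacks CB; using CA", chain_id,
                           res.seqid.num, res.seqid.icode.strip())
    icode = res.seqid.icode.strip() or ""
    return Residue((chain_id, res.seqid.num, icode), aa, atoms, rep, fallback)


def read_assembly(path, assembly_id: str | None = None) -> Assembly:
    """Read a PDB or mmCIF file into an :class:`Assembly`.

    Applies the standard filters used for quaternary-structure analysis:
    chains shorter than 20 residues (peptides) and chains consisting only of
    Cα atoms (traces) are dropped.  If ``assembly_id`` names a biological
    assembly stored in the file, the corresponding operator expansion is
    applied first.

    Raises
    ------
    FormatError
        if the file cannot be parsed.
    EmptyAssemblyError
        if no chain survives filtering.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    source = "mmcif" if st.input_format == gemmi.CoorFormat.Mmcif else "pdb"
    st.setup_entities()
    if assembly_id is not None:
        names = [a.name for a in st.assemblies]
        if assembly_id not in names:
            raise FormatError(
                f"assembly {assembly_id!r} not defined in {path} "
                f"(available: {names})")
        st.transform_to_assembly(assembly_id,
                                 gemmi.HowToNameCopiedChain.AddNumber)
    if len(st) == 0:
        raise EmptyAssemblyError(f"{path}: no model")
    model = st[0]

    chains = []
    for gchain in model:
        residues = []
        for gres in gchain:
            if gres.het_flag == "H" and _one_letter(gres.name) == "X" and \
                    gres.name not in ("MSE",):
                # unknown heteroatom groups (ligands/waters) are skipped;
                # tabulated modified amino acids pass through _convert_residue
                info = gemmi.find_tabulated_residue(gres.name)
                if info is None or not info.is_amino_acid():
                    continue
            r = _convert_residue(gchain.name, gres)
            if r is not None:
                residues.append(r)
        if len(residues) < MIN_CHAIN_LENGTH:
            if residues:
                logger.info("dropping short chain %s (%d residues)",
                            gchain.name, len(residues))
            continue
        if all(len(r.atoms) == 1 and r.atoms[0][0] == "CA" for r in residues):
            logger.info("dropping Calpha-trace chain %s", gchain.name)
            continue
        seq = "".join(r.aa for r in residues)
        chains.append(Chain(gchain.name, seq, residues))
    if not chains:
        raise EmptyAssemblyError(f"{path}: no chain survives filtering")
    return Assembly(st.name or str(path), chains, source)


def write_pdb(a: Assembly, path) -> None:
    """Write the assembly as a PDB file (debugging / superposed output)."""
    st = gemmi.Structure()
    st.name = a.id
    model = gemmi.Model("1")
    for chain in a.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = _THREE_LETTER.get(res.aa, "UNK")
            gres.seqid = gemmi.SeqId(res.res_id[1], res.res_id[2] or " ")
            for name, xyz, b in res.atoms:
                atom = gemmi.Atom()
                atom.name = name
                atom.pos = gemmi.Position(*xyz)
                atom.b_iso = b
                atom.occ = 1.0
                atom.element = gemmi.Element(_element_of(name))
                gres.add_atom(atom)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


_THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}


def _element_of(atom_name: str) -> str:
    name = atom_name.strip().lstrip("0123456789")
    if name[:2].upper() in ("SE", "FE", "ZN", "MG", "MN"):
        return name[:2].capitalize()
    return name[0].upper()


# ---------------------------------------------------------------------------
# global sequence alignment helpers (shared by several modules)

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


_ALIGNER = _make_aligner()


@functools.lru_cache(maxsize=4096)
def align_sequences(seq_a: str, seq_b: str):
    """Global Needleman-Wunsch alignment (BLOSUM62, gap -11/-1).

    Returns the list of aligned index pairs ``(i_a, i_b)`` (0-based,
    non-gap columns only).
    """
    sa = seq_a.replace("X", "A") if "X" in seq_a else seq_a
    sb = seq_b.replace("X", "A") if "X" in seq_b else seq_b
    aln = _ALIGNER.align(sa, sb)[0]
    pairs = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    return pairs


def global_identity(seq_a: str, seq_b: str):
    """(identity, coverage_a, coverage_b) from a global alignment.

    Identity is matches / aligned (both non-gap) columns; coverage is
    aligned columns / sequence length.
    """
    if not seq_a or not seq_b:
        return 0.0, 0.0, 0.0
    pairs = align_sequences(seq_a, seq_b)
    if not pairs:
        return 0.0, 0.0, 0.0
    matches = sum(1 for i, j in pairs if seq_a[i] == seq_b[j])
    aligned = len(pairs)
    return (matches / aligned, aligned / len(seq_a), aligned / len(seq_b))


# ---------------------------------------------------------------------------
# entity grouping and stoichiometry

def group_chemical_entities(a: Assembly) -> Assembly:
    """Assign ``entity_key`` to every chain by chemical equivalence.

    Two chains are chemically equivalent when their global-alignment
    sequence identity is >= 95% over >= 90% mutual coverage; the partition
    is the transitive closure of that relation (so slightly divergent
    engineered constructs still group together).  Returns the same assembly
    with keys assigned in order of first chain appearance.
    """
    g = nx.Graph()
    g.add_nodes_from(range(len(a.chains)))
    for i in range(len(a.chains)):
        for j in range(i + 1, len(a.chains)):
            ident, cov_i, cov_j = global_identity(a.chains[i].sequence,
                                                  a.chains[j].sequence)
            if ident >= ENTITY_IDENTITY and min(cov_i, cov_j) >= ENTITY_COVERAGE:
                g.add_edge(i, j)
    comp_of = {}
    for comp in nx.connected_components(g):
        rep = min(comp)
        for idx in comp:
            comp_of[idx] = rep
    reps_in_order = sorted(set(comp_of.values()))
    key_of_rep = {rep: k for k, rep in enumerate(reps_in_order)}
    for idx, chain in enumerate(a.chains):
        chain.entity_key = key_of_rep[comp_of[idx]]
    return a


def _ensure_entities(a: Assembly) -> Assembly:
    if any(c.entity_key < 0 for c in a.chains):
        group_chemical_entities(a)
    return a


def entity_sequences(a: Assembly) -> dict:
    """entity_key -> representative sequence (first chain of the entity)."""
    _ensure_entities(a)
    out = {}
    for c in a.chains:
        out.setdefault(c.entity_key, c.sequence)
    return out


def stoichiometry_string(a: Assembly) -> str:
    """Canonical stoichiometry such as ``A2B2`` (multiplicity descending,
    ties broken by the entity's representative sequence)."""
    _ensure_entities(a)
    counts = {}
    for c in a.chains:
        counts[c.entity_key] = counts.get(c.entity_key, 0) + 1
    seqs = entity_sequences(a)
    order = sorted(counts, key=lambda k: (-counts[k], seqs[k]))
    parts = []
    for rank, key in enumerate(order):
        letter = _entity_letter(rank)
        parts.append(f"{letter}{counts[key]}")
    return "".join(parts)


def _entity_letter(rank: int) -> str:
    letters = ""
    rank += 1
    while rank:
        rank, rem = divmod(rank - 1, 26)
        letters = chr(ord("A") + rem) + letters
    return letters
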