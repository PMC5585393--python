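"""Chain- and residue-level correspondence between two assemblies.

Comparing two oligomers requires a bijection between their chains.  With
``n`` equivalent chains there are up to ``n!`` candidate bijections, so the
search is organised in the classical way:

1. chains of each assembly are grouped by chemical equivalence (entities);
2. equivalent entities *between* the assemblies are matched by global
   sequence alignment (homology floor 20% identity);
3. the (pseudo-)symmetry of each assembly is detected and chains are
   partitioned into symmetry groups related by a rigid transformation;
4. candidate mappings are either enumerated exhaustively (small cases) or
   seeded from symmetry-group pairs: superposing one group pair fixes a
   rigid transform which determines the assignment of all other chains;
5. the mapping with the lowest global RMSD over aligned representative
   coordinates wins; residue correspondence comes from per-chain-pair
   global sequence alignments.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .structure_model import (Assembly, _ensure_entities, align_sequences,
                              entity_sequences, global_identity)

logger = logging.getLogger(__name__)

HOMOLOGY_FLOOR = 0.20     # min identity for cross-assembly entity matching
SYMMETRY_TOL = 3.0        # Å RMSD for a valid symmetry operation
ROT_DEDUP_DEG = 15.0      # candidate transforms closer than this are merged
MAX_BRUTE_DEFAULT = 10080  # covers n <= 7 single-entity complexes (7!)
MAX_SEEDS = 100_000        # symmetry-guided seed budget before giving up
RMSD_TIE_TOL = 1e-6


class NoMappingError(ValueError):
    """No entity of one assembly is alignable to any entity of the other."""


class IntractableMappingError(ValueError):
    """Too many candidate mappings even with symmetry reduction."""


@dataclass
class ChainMapping:
    pairs: list          # of (chain_id_a, chain_id_b)
    rmsd: float          # Å, global superposition under this mapping
    method: str          # brute_force | symmetry_guided

    def as_dict(self):
        return dict(self.pairs)


@dataclass
class ResidueMapping:
    pairs: list  # of (res_id_a, res_id_b)

    def as_dict(self):
        return dict(self.pairs)

    def inverse_dict(self):
        return {b: a for a, b in self.pairs}


@dataclass
class SymmetryGroups:
    groups: list                 # list of lists of chain ids
    rotation: np.ndarray | None  # op mapping group j onto group j+1
    translation: np.ndarray | None
    order: int                   # cycle length of the op (1 = no symmetry)
    rmsd: float


# ---------------------------------------------------------------------------
# rigid superposition (Kabsch)

def superpose(coords_a, coords_b):
    """Least-squares rigid superposition of A onto B (no reflection).

    Returns ``(rotation, translation, rmsd)`` with
    ``b ≈ rotation @ a + translation``.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("coordinate sets must have equal shape")
    if a.ndim != 2 or a.shape[0] < 3 or a.shape[1] != 3:
        raise ValueError("need at least 3 points of dimension 3")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (a - ca).T @ (b - cb)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cb - rot @ ca
    diff = (a @ rot.T + trans) - b
    rmsd = float(np.sqrt((diff ** 2).sum() / a.shape[0]))
    return rot, trans, rmsd


def apply_transform(coords, rotation, translation):
    return np.asarray(coords, float) @ np.asarray(rotation).T + translation


def _rmsd_fixed(coords_a, coords_b, rotation, translation) -> float:
    diff = apply_transform(coords_a, rotation, translation) - coords_b
    return float(np.sqrt((diff ** 2).sum() / max(len(diff), 1)))


def rotation_angle_deg(rotation) -> float:
    c = (np.trace(rotation) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# aligned representative coordinates

def _aligned_rep_coords(chain_a, chain_b):
    """Rep-coordinate arrays over the global sequence alignment of two
    chains (only positions where both residues have a rep_coord)."""
    pairs = align_sequences(chain_a.sequence, chain_b.sequence)
    xa, xb = [], []
    for i, j in pairs:
        ra, rb = chain_a.residues[i], chain_b.residues[j]
        if ra.rep_coord is not None and rb.rep_coord is not None:
            xa.append(ra.rep_coord)
            xb.append(rb.rep_coord)
    return np.asarray(xa, float), np.asarray(xb, float)


def _aligned_residue_pairs(chain_a, chain_b):
    pairs = align_sequences(chain_a.sequence, chain_b.sequence)
    return [(chain_a.residues[i].res_id, chain_b.residues[j].res_id)
            for i, j in pairs]


# ---------------------------------------------------------------------------
# entity matching between assemblies

def match_entities(a: Assembly, b: Assembly,
                   floor: float = HOMOLOGY_FLOOR) -> dict:
    """One-to-one matching of A entities to B entities by alignment identity.

    Greedy on descending identity; pairs below the homology floor are never
    matched.  Returns ``{entity_key_a: entity_key_b}``.
    """
    _ensure_entities(a)
    _ensure_entities(b)
    seqs_a, seqs_b = entity_sequences(a), entity_sequences(b)
    scored = []
    for ka, sa in seqs_a.items():
        for kb, sb in seqs_b.items():
            ident, _, _ = global_identity(sa, sb)
            if ident >= floor:
                scored.append((ident, ka, kb))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a, used_b, match = set(), set(), {}
    for ident, ka, kb in scored:
        if ka in used_a or kb in used_b:
            continue
        match[ka] = kb
        used_a.add(ka)
        used_b.add(kb)
    return match


def _chains_by_entity(a: Assembly, keys):
    out = {k: [] for k in keys}
    for c in a.chains:
        if c.entity_key in out:
            out[c.entity_key].append(c)
    return out


def count_brute_candidates(a: Assembly, b: Assembly) -> int:
    """Number of entity-consistent chain bijections enumerated brute-force."""
    match = match_entities(a, b)
    if not match:
        raise NoMappingError("no alignable entity pair between assemblies")
    ca = _chains_by_entity(a, match.keys())
    cb = _chains_by_entity(b, match.values())
    total = 1
    for ka, kb in match.items():
        na, nb = len(ca[ka]), len(cb[kb])
        lo, hi = min(na, nb), max(na, nb)
        perm = 1
        for i in range(lo):
            perm *= hi - i
        total *= perm
    return total


# ---------------------------------------------------------------------------
# symmetry detection

def detect_symmetry_groups(a: Assembly, tol: float = SYMMETRY_TOL) -> SymmetryGroups:
    """Partition chains into groups related by one rigid transformation.

    Candidate transforms come from superposing entity-equivalent chain
    pairs; a candidate is a valid (pseudo-)symmetry operation when it maps
    every chain onto a distinct chain of the same entity within ``tol`` Å
    RMSD, and the induced permutation has uniform cycle length.  The groups
    returned are the asymmetric units: group ``j+1`` is the image of group
    ``j`` under the operation.  Falls back to singleton groups when no
    operation is found.
    """
    _ensure_entities(a)
    chains = a.chains
    n = len(chains)
    singletons = SymmetryGroups([[c.chain_id] for c in chains],
                                None, None, 1, 0.0)
    if n < 2:
        return singletons

    tested: list = []  # (rotation, translation) already examined
    best = None  # (order k, -mean_rmsd) maximised
    for i in range(n):
        for j in range(n):
            if i == j or chains[i].entity_key != chains[j].entity_key:
                continue
            xa, xb = _aligned_rep_coords(chains[i], chains[j])
            if len(xa) < 3:
                continue
            rot, trans, _ = superpose(xa, xb)
            dup = False
            for prot, ptrans in tested:
                if (rotation_angle_deg(rot @ prot.T) < ROT_DEDUP_DEG
                        and np.linalg.norm(trans - ptrans) < 1.0):
                    dup = True
                    break
            if dup:
                continue
            tested.append((rot, trans))
            perm = _induced_permutation(a, rot, trans, tol)
            if perm is None:
                continue
            cycles = _cycles(perm, n)
            lengths = {len(c) for c in cycles}
            if len(lengths) != 1:
                continue
            k = lengths.pop()
            if k < 2:
                continue
            rmsds = perm[1]
            cand = (k, -float(np.mean(rmsds)), cycles, rot, trans)
            if best is None or cand[:2] > best[:2]:
                best = cand
    if best is None:
        return singletons
    k, neg_rmsd, cycles, rot, trans = best
    groups = [[chains[cyc[j]].chain_id for cyc in cycles] for j in range(k)]
    return SymmetryGroups(groups, rot, trans, k, -neg_rmsd)


def _induced_permutation(a: Assembly, rot, trans, tol):
    """Map each chain to its best image under the transform; None if the
    result is not a proper non-identity permutation within tolerance."""
    chains = a.chains
    n = len(chains)
    target = [None] * n
    rmsds = [np.inf] * n
    for ci, chain in enumerate(chains):
        best_j, best_r = None, np.inf
        for cj, other in enumerate(chains):
            if other.entity_key != chain.entity_key:
                continue
            xa, xb = _aligned_rep_coords(chain, other)
            if len(xa) < 3:
                continue
            r = _rmsd_fixed(xa, xb, rot, trans)
            if r < best_r:
                best_r, best_j = r, cj
        if best_j is None or best_r > tol:
            return None
        target[ci] = best_j
        rmsds[ci] = best_r
    if len(set(target)) != n:
        return None
    if all(t == i for i, t in enumerate(target)):
        return None
    return target, rmsds


def _cycles(perm_result, n):
    target = perm_result[0]
    seen = [False] * n
    cycles = []
    for start in range(n):
        if seen[start]:
            continue
        cyc, cur = [], start
        while not seen[cur]:
            seen[cur] = True
            cyc.append(cur)
            cur = target[cur]
        cycles.append(cyc)
    return cycles


# ---------------------------------------------------------------------------
# chain mapping search

def _mapping_rmsd(a: Assembly, b: Assembly, pairs):
    """Global Kabsch RMSD over aligned rep coords of all chain pairs."""
    xa, xb = [], []
    for cid_a, cid_b in pairs:
        ca_, cb_ = a.chain(cid_a), b.chain(cid_b)
        pa, pb = _aligned_rep_coords(ca_, cb_)
        if len(pa):
            xa.append(pa)
            xb.append(pb)
    if not xa:
        return np.inf
    xa, xb = np.vstack(xa), np.vstack(xb)
    if len(xa) < 3:
        return np.inf
    _, _, rmsd = superpose(xa, xb)
    return rmsd


def _enumerate_brute(a, b, match):
    ca = _chains_by_entity(a, match.keys())
    cb = _chains_by_entity(b, match.values())
    per_entity = []
    for ka in sorted(match):
        kb = match[ka]
        la = sorted(ca[ka], key=lambda c: c.chain_id)
        lb = sorted(cb[kb], key=lambda c: c.chain_id)
        opts = []
        if len(la) <= len(lb):
            for perm in itertools.permutations(lb, len(la)):
                opts.append([(x.chain_id, y.chain_id)
                             for x, y in zip(la, perm)])
        else:
            for perm in itertools.permutations(la, len(lb)):
                opts.append([(x.chain_id, y.chain_id)
                             for x, y in zip(perm, lb)])
        per_entity.append(opts)
    for combo in itertools.product(*per_entity):
        yield sorted(p for part in combo for p in part)


def _extend_from_transform(a, b, match, rot, trans, seed_pairs):
    """Given a rigid transform of A onto B, assign remaining chains per
    entity by minimum RMSD under the fixed transform (Hungarian)."""
    assigned_a = {p[0] for p in seed_pairs}
    assigned_b = {p[1] for p in seed_pairs}
    pairs = list(seed_pairs)
    for ka in sorted(match):
        kb = match[ka]
        rest_a = [c for c in a.chains
                  if c.entity_key == ka and c.chain_id not in assigned_a]
        rest_b = [c for c in b.chains
                  if c.entity_key == kb and c.chain_id not in assigned_b]
        if not rest_a or not rest_b:
            continue
        cost = np.full((len(rest_a), len(rest_b)), 1e6)
        for i, cai in enumerate(rest_a):
            for j, cbj in enumerate(rest_b):
                xa, xb = _aligned_rep_coords(cai, cbj)
                if len(xa) >= 3:
                    cost[i, j] = _rmsd_fixed(xa, xb, rot, trans)
        rows, cols = linear_sum_assignment(cost)
        order = np.argsort(cost[rows, cols])
        keep = min(len(rest_a), len(rest_b))
        taken = 0
        for idx in order:
            if taken >= keep or cost[rows[idx], cols[idx]] >= 1e6:
                break
            pairs.append((rest_a[rows[idx]].chain_id,
                          rest_b[cols[idx]].chain_id))
            taken += 1
    return sorted(pairs)


def _symmetry_guided_candidates(a, b, match, max_seeds):
    sga = detect_symmetry_groups(a)
    sgb = detect_symmetry_groups(b)
    ent_a = {c.chain_id: c.entity_key for c in a.chains}
    ent_b = {c.chain_id: c.entity_key for c in b.chains}
    seeds = []
    # single chain-pair seeds: robust when the two assemblies admit
    # incompatible symmetry-group decompositions
    for ca in a.chains:
        if ca.entity_key not in match:
            continue
        for cb in b.chains:
            if cb.entity_key == match[ca.entity_key]:
                seeds.append([(ca.chain_id, cb.chain_id)])
    for ga in sga.groups:
        ga = [cid for cid in ga if ent_a[cid] in match]
        if not ga:
            continue
        for gb in sgb.groups:
            gbf = [cid for cid in gb if ent_b[cid] in match.values()]
            if not gbf:
                continue
            seeds.extend(_group_pair_injections(ga, gbf, match,
                                                ent_a, ent_b))
            if len(seeds) > max_seeds:
                raise IntractableMappingError(
                    "candidate mapping count intractable even with "
                    "symmetry-group reduction")
    return seeds


def _group_pair_injections(ga, gb, match, ent_a, ent_b):
    """Entity-consistent injections between the chains of two symmetry
    groups (the smaller side into the larger)."""
    by_ent_a, by_ent_b = {}, {}
    for cid in ga:
        by_ent_a.setdefault(match[ent_a[cid]], []).append(cid)
    for cid in gb:
        by_ent_b.setdefault(ent_b[cid], []).append(cid)
    common = sorted(set(by_ent_a) & set(by_ent_b))
    if not common:
        return []
    per_entity = []
    for kb in common:
        la, lb = sorted(by_ent_a[kb]), sorted(by_ent_b[kb])
        opts = []
        if len(la) <= len(lb):
            for perm in itertools.permutations(lb, len(la)):
                opts.append(list(zip(la, perm)))
        else:
            for perm in itertools.permutations(la, len(lb)):
                opts.append(list(zip(perm, lb)))
        per_entity.append(opts)
    out = []
    for combo in itertools.product(*per_entity):
        out.append([p for part in combo for p in part])
    return out


def map_chains(a: Assembly, b: Assembly,
               max_brute: int = MAX_BRUTE_DEFAULT):
    """Best chain mapping between two assemblies.

    Exhaustive enumeration when the number of entity-consistent bijections
    is at most ``max_brute``; otherwise symmetry-guided search (seed a
    rigid transform from one symmetry-group pair, extend it to all chains,
    keep the candidate with the lowest global RMSD).

    Returns ``(ChainMapping, ResidueMapping)``.
    """
    _ensure_entities(a)
    _ensure_entities(b)
    match = match_entities(a, b)
    if not match:
        raise NoMappingError("no alignable entity pair between assemblies")
    n_cand = count_brute_candidates(a, b)

    best_pairs, best_rmsd = None, np.inf
    if n_cand <= max_brute:
        method = "brute_force"
        for pairs in _enumerate_brute(a, b, match):
            rmsd = _mapping_rmsd(a, b, pairs)
            if rmsd < best_rmsd - RMSD_TIE_TOL or (
                    abs(rmsd - best_rmsd) <= RMSD_TIE_TOL
                    and (best_pairs is None or pairs < best_pairs)):
                best_pairs, best_rmsd = pairs, min(rmsd, best_rmsd)
    else:
        method = "symmetry_guided"
        seeds = _symmetry_guided_candidates(a, b, match, max_seeds=MAX_SEEDS)
        if not seeds:
            raise NoMappingError("no symmetry-guided seed mapping found")
        for seed in seeds:
            xa, xb = [], []
            for cid_a, cid_b in seed:
                pa, pb = _aligned_rep_coords(a.chain(cid_a), b.chain(cid_b))
                if len(pa):
                    xa.append(pa)
                    xb.append(pb)
            if not xa:
                continue
            xa_, xb_ = np.vstack(xa), np.vstack(xb)
            if len(xa_) < 3:
                continue
            rot, trans, _ = superpose(xa_, xb_)
            pairs = _extend_from_transform(a, b, match, rot, trans, seed)
            rmsd = _mapping_rmsd(a, b, pairs)
            if rmsd < best_rmsd - RMSD_TIE_TOL or (
                    abs(rmsd - best_rmsd) <= RMSD_TIE_TOL
                    and (best_pairs is None or pairs < best_pairs)):
                best_pairs, best_rmsd = pairs, min(rmsd, best_rmsd)
    if best_pairs is None or not np.isfinite(best_rmsd):
        raise NoMappingError("no superposable chain mapping found")

    res_pairs = []
    for cid_a, cid_b in best_pairs:
        res_pairs.extend(_aligned_residue_pairs(a.chain(cid_a),
                                                b.chain(cid_b)))
    logger.debug("mapped %s -> %s: %s (rmsd %.3f, %s)", a.id, b.id,
                 best_pairs, best_rmsd, method)
    return (ChainMapping(best_pairs, best_rmsd, method),
            ResidueMapping(res_pairs))


def mapping_report(a: Assembly, b: Assembly, cm: ChainMapping) -> dict:
    """JSON-ready summary of a chain mapping."""
    per_chain = []
    for cid_a, cid_b in cm.pairs:
        ident, cov_a, cov_b = global_identity(a.chain(cid_a).sequence,
                                              b.chain(cid_b).sequence)
        per_chain.append({"chain_a": cid_a, "chain_b": cid_b,
                          "identity": round(ident, 4),
                          "coverage_a": round(cov_a, 4),
                          "coverage_b": round(cov_b, 4)})
    return {"assembly_a": a.id, "assembly_b": b.id, "pairs": per_chain,
            "global_rmsd": round(cm.rmsd, 4), "method": cm.method}
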