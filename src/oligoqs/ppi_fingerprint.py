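"""PPI fingerprints: interface-vs-surface conservation across an MSA.

The conservation of an interface is compared with the rest of the protein
surface at increasing evolutionary proximity.  For each of 20 sequence
identity inclusion thresholds (0%, 5%, ..., 95%) the MSA is restricted to
sequences at least that similar to the query and:

1. per-column conservation is computed as relative entropy
   ``RE_c = sum_a p_a log2(p_a / p_ab)`` against the alignment-wide
   background, normalised to [0, 1];
2. the interface and surface regions are summarised by rASA-weighted mean
   entropies ``<S>_i`` and ``<S>_s``;
3. their log-ratio ``IS = ln((1+<S>_i)/(1+<S>_s))`` is negative when the
   interface is more conserved than the surface;
4. a null distribution of IS values from random connected surface patches
   of the same size yields a P-value via a Gaussian KDE (Silverman
   bandwidth), and ``C_score = IS * (1 - P)``.

The resulting curve ("fingerprint") is summarised by four features: its
minimum, its absolute maximum (sign preserved), the value for the full
MSA, and its area (composite trapezoid).  Biological interfaces typically
show persistently negative curves; crystal contacts do not.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.stats import gaussian_kde

from .structure_model import Assembly, align_sequences
from .surface_interface import accessibility_records, classify_residues

logger = logging.getLogger(__name__)

N_THRESHOLDS = 20
DEFAULT_THRESHOLDS = tuple(round(0.05 * i, 2) for i in range(N_THRESHOLDS))
MIN_ROWS = 5            # fewer retained sequences -> C_score undefined
MIN_ROWS_ENTROPY = 2
ADJACENCY_START = 4.5   # Å, initial atom-atom neighbour cutoff
ADJACENCY_STEP = 0.5
LOG2_20 = math.log2(20.0)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = set("-.")


class MSAError(ValueError):
    pass


# ---------------------------------------------------------------------------
# MSA handling

def read_msa(path) -> list:
    """Aligned FASTA or A3M; first record is the query.

    A3M lowercase letters are insertions relative to the query and are
    removed, leaving all rows with the query's column count.
    """
    records = []
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records.append((name, "".join(chunks)))
                name, chunks = line[1:].split()[0] if line[1:] else "", []
            else:
                chunks.append(line)
    if name is not None:
        records.append((name, "".join(chunks)))
    if not records:
        raise MSAError(f"no sequences in {path}")
    if any(c.islower() for _, s in records for c in s):  # a3m
        records = [(n, "".join(c for c in s if not c.islower()))
                   for n, s in records]
    lengths = {len(s) for _, s in records}
    if len(lengths) != 1:
        raise MSAError("alignment rows have unequal lengths")
    return records


def sequence_identity_to_query(query: str, row: str) -> float:
    """Matches over columns where both query and row are non-gap."""
    both = [(q, r) for q, r in zip(query, row)
            if q not in GAP_CHARS and r not in GAP_CHARS]
    if not both:
        return 0.0
    return sum(q == r for q, r in both) / len(both)


@dataclass
class ThresholdedMSA:
    query: str
    rows: list            # all aligned sequences incl. query
    threshold: float
    retained_rows: list   # rows with identity-to-query >= threshold


def threshold_msa(rows: list, threshold: float) -> ThresholdedMSA:
    """Restrict an alignment to rows at least ``threshold`` identical to
    the query (first row).  The query is always retained."""
    seqs = [s for _, s in rows] if rows and isinstance(rows[0], tuple) else list(rows)
    query = seqs[0]
    retained = [query] + [s for s in seqs[1:]
                          if sequence_identity_to_query(query, s) >= threshold]
    return ThresholdedMSA(query, seqs, threshold, retained)


# ---------------------------------------------------------------------------
# column conservation (relative entropy)

@dataclass
class ColumnConservation:
    re: np.ndarray        # raw relative entropy, bits
    re_norm: np.ndarray   # conservation, clamped to [0, 1] (1 = conserved)
    defined: np.ndarray   # False for all-gap columns

    @property
    def entropy_norm(self) -> np.ndarray:
        """Normalised column entropy: 0 = fully conserved, 1 = background-
        like variability.  This is the quantity the region means average,
        so a conserved interface yields a *negative* interface-surface
        log-ratio."""
        return 1.0 - self.re_norm


def column_relative_entropy(msa) -> ColumnConservation:
    """Per-column relative entropy of a (possibly thresholded) alignment.

    Column probabilities exclude gaps; the background is the amino-acid
    distribution over all non-gap residues of the retained alignment.
    """
    seqs = msa.retained_rows if isinstance(msa, ThresholdedMSA) else list(msa)
    if len(seqs) < MIN_ROWS_ENTROPY:
        raise MSAError("need at least 2 retained rows")
    ncol = len(seqs[0])
    arr = np.array([list(s) for s in seqs])
    background = {}
    total = 0
    for aa in AA20:
        cnt = int(np.sum(arr == aa))
        background[aa] = cnt
        total += cnt
    other = int(np.isin(arr, list(AA20) + list(GAP_CHARS), invert=True).sum())
    total += other
    if total == 0:
        raise MSAError("alignment contains no residues")
    re = np.zeros(ncol)
    defined = np.zeros(ncol, dtype=bool)
    for c in range(ncol):
        col = [x for x in arr[:, c] if x not in GAP_CHARS]
        if not col:
            continue
        defined[c] = True
        ncolres = len(col)
        val = 0.0
        for aa in set(col):
            p_a = col.count(aa) / ncolres
            p_ab = background.get(aa, other) / total
            if p_ab <= 0:
                p_ab = 1.0 / total
            val += p_a * math.log2(p_a / p_ab)
        re[c] = max(val, 0.0)
    re_norm = np.clip(re / LOG2_20, 0.0, 1.0)
    return ColumnConservation(re, re_norm, defined)


def region_mean_entropy(cons: ColumnConservation, cols, weights) -> float:
    """rASA-weighted mean normalised entropy (0 = conserved) over columns."""
    cols = list(cols)
    weights = np.asarray(list(weights), dtype=float)
    if len(cols) == 0:
        raise ValueError("empty region")
    keep = [k for k, c in enumerate(cols) if cons.defined[c]]
    if not keep:
        raise ValueError("region has no defined columns")
    w = weights[keep]
    v = cons.entropy_norm[[cols[k] for k in keep]]
    tot = w.sum()
    if tot <= 0:
        raise ValueError("region has zero total weight")
    return float((w * v).sum() / tot)


def interface_surface_ratio(s_i: float, s_s: float) -> float:
    """ln((1 + <S>_i) / (1 + <S>_s)); negative = interface more conserved."""
    if s_i < 0 or s_s < 0:
        raise ValueError("mean entropies must be non-negative")
    return math.log((1.0 + s_i) / (1.0 + s_s))


# ---------------------------------------------------------------------------
# structural context and the patch null

@dataclass
class ConservationContext:
    """Everything the fingerprint needs to know about one chain.

    ``positions`` are query-sequence indices (0-based) per residue;
    residues whose label is neither interface nor surface are ignored.
    """

    interface: list       # residue indices into `positions`
    surface: list
    positions: list       # query position per residue (None = unmapped)
    weights: list         # monomer rASA per residue
    adjacency: nx.Graph   # over surface residue indices
    adjacency_cutoff: float


def build_chain_context(a: Assembly, chain_id: str, query_seq: str | None = None,
                        records=None, classifications=None,
                        interface_positions=None,
                        interface_residue_ids=None) -> ConservationContext:
    """Build the conservation context of one chain of an assembly.

    Interface/surface labels and rASA come from the 25% classification of
    the full assembly.  ``query_seq`` (default: the chain's own sequence)
    maps residues onto MSA-query positions via global alignment.
    ``interface_positions`` optionally restricts the interface to a subset
    of query positions (e.g. the template interface fraction mapped onto a
    modeling target).  ``interface_residue_ids`` overrides the label-based
    interface with an explicit residue-id set (e.g. the contact-based
    interface); non-core residues outside the set become surface.
    """
    chain = a.chain(chain_id)
    if records is None:
        records = accessibility_records(a)
    if classifications is None:
        classifications = classify_residues(records)
    label_of = {c.res_id: c.label for c in classifications}
    rasa_of = {r.res_id: r.rasa for r in records}

    if query_seq is None or query_seq == chain.sequence:
        pos_of = {i: i for i in range(len(chain.residues))}
    else:
        pos_of = {j: i for i, j in align_sequences(query_seq, chain.sequence)}

    interface, surface, positions, weights, coords = [], [], [], [], []
    for i, res in enumerate(chain.residues):
        positions.append(pos_of.get(i))
        weights.append(rasa_of[res.res_id])
        coords.append(res.atom_coords())
        if positions[-1] is None:
            continue
        label = label_of[res.res_id]
        if interface_residue_ids is not None:
            if res.res_id in interface_residue_ids:
                label = "interface"
            elif label == "interface":
                label = "surface"
        if label == "interface":
            if (interface_positions is None
                    or positions[-1] in interface_positions):
                interface.append(i)
        elif label == "surface":
            surface.append(i)

    graph, cutoff = _surface_adjacency(surface, coords)
    return ConservationContext(interface, surface, positions, weights,
                               graph, cutoff)


def _surface_adjacency(surface, coords):
    """Graph over surface residues; the atom-atom cutoff N grows from
    4.5 Å in 0.5 Å steps until the graph is connected."""
    cutoff = ADJACENCY_START
    graph = nx.Graph()
    graph.add_nodes_from(surface)
    if len(surface) <= 1:
        return graph, cutoff
    # precompute pairwise minimal atom-atom distances
    mind = {}
    for ii, i in enumerate(surface):
        for j in surface[ii + 1:]:
            d = np.sqrt(((coords[i][:, None, :] - coords[j][None, :, :]) ** 2
                         ).sum(-1)).min()
            mind[(i, j)] = float(d)
    while True:
        graph = nx.Graph()
        graph.add_nodes_from(surface)
        for (i, j), d in mind.items():
            if d <= cutoff:
                graph.add_edge(i, j)
        if nx.is_connected(graph):
            return graph, cutoff
        cutoff += ADJACENCY_STEP


def _region_is(cons, ctx, region_a, region_b) -> float:
    cols_a = [ctx.positions[i] for i in region_a]
    w_a = [ctx.weights[i] for i in region_a]
    cols_b = [ctx.positions[i] for i in region_b]
    w_b = [ctx.weights[i] for i in region_b]
    s_a = region_mean_entropy(cons, cols_a, w_a)
    s_b = region_mean_entropy(cons, cols_b, w_b)
    return interface_surface_ratio(s_a, s_b)


def patch_null_distribution(ctx: ConservationContext,
                            cons: ColumnConservation,
                            n_iter: int | None = None,
                            seed: int = 0) -> np.ndarray:
    """IS values of random connected surface patches of interface size.

    The original interface residues are excluded throughout; each patch is
    grown by repeatedly adding a random graph-neighbour of the current
    patch, and scored against the remaining surface.
    """
    size = len(ctx.interface)
    surface = list(ctx.surface)
    if len(surface) <= size:
        raise ValueError("not enough surface residues to sample patches")
    if n_iter is None:
        n_iter = max(100, 2 * len(surface))
    rng = np.random.default_rng(seed)
    logger.debug("patch null: size=%d n_iter=%d seed=%d cutoff=%.1f",
                 size, n_iter, seed, ctx.adjacency_cutoff)
    values = np.empty(n_iter)
    for it in range(n_iter):
        start = surface[rng.integers(len(surface))]
        patch = {start}
        while len(patch) < size:
            frontier = sorted({nb for p in patch
                               for nb in ctx.adjacency.neighbors(p)} - patch)
            if not frontier:
                start = surface[rng.integers(len(surface))]
                patch = {start}
                continue
            patch.add(frontier[rng.integers(len(frontier))])
        rest = [s for s in surface if s not in patch]
        values[it] = _region_is(cons, ctx, sorted(patch), rest)
    return values


def interface_p_value(is_value: float, x) -> float:
    """Two-tailed KDE P-value of the interface IS against the patch null.

    Gaussian KDE with Silverman bandwidth;
    ``P = min(int_{min X}^{IS} f, int_{IS}^{max X} f)`` clamped to [0, 1].
    IS outside the null's range gives P = 0.  A zero-variance null is
    degenerate: P = 1 if IS equals the constant, else 0.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 null samples")
    if np.ptp(x) == 0.0:
        return 1.0 if is_value == x[0] else 0.0
    lo, hi = float(x.min()), float(x.max())
    if is_value < lo or is_value > hi:
        return 0.0
    kde = gaussian_kde(x, bw_method="silverman")
    left = kde.integrate_box_1d(lo, is_value)
    right = kde.integrate_box_1d(is_value, hi)
    return float(np.clip(min(left, right), 0.0, 1.0))


def conservation_score(is_value: float, p_value: float) -> float:
    """C_score = IS * (1 - P)."""
    if not 0.0 <= p_value <= 1.0:
        raise ValueError("P must lie in [0, 1]")
    return is_value * (1.0 - p_value)


def conservation_at(seqs: list, ctx: ConservationContext,
                    n_iter: int | None = None, seed: int = 0):
    """(C_score, IS, P) for one retained alignment and one interface."""
    cons = column_relative_entropy(seqs)
    query_pos_to_col = _query_columns(seqs[0])
    cons_mapped = _remap(cons, query_pos_to_col)
    is_value = _region_is(cons_mapped, ctx, ctx.interface, ctx.surface)
    null = patch_null_distribution(ctx, cons_mapped, n_iter, seed)
    p = interface_p_value(is_value, null)
    return conservation_score(is_value, p), is_value, p


def _query_columns(query_row: str) -> list:
    return [c for c, ch in enumerate(query_row) if ch not in GAP_CHARS]


def _remap(cons: ColumnConservation, query_cols) -> ColumnConservation:
    """Re-index column conservation by query position instead of alignment
    column, so structural positions address it directly."""
    npos = len(query_cols)
    re = np.array([cons.re[c] for c in query_cols])
    re_norm = np.array([cons.re_norm[c] for c in query_cols])
    defined = np.array([cons.defined[c] for c in query_cols])
    return ColumnConservation(re, re_norm, defined)


# ---------------------------------------------------------------------------
# the fingerprint curve

@dataclass
class FingerprintCurve:
    thresholds: tuple
    c_scores: list        # per threshold; None where undefined
    features: dict        # minimum, absolute_maximum, full_msa_value, area
    is_values: list = field(default_factory=list)
    p_values: list = field(default_factory=list)


def curve_features(thresholds, c_scores) -> dict:
    """Four summary features of a fingerprint curve (undefined points are
    excluded; the area integrates the defined points trapezoidally)."""
    pts = [(t, c) for t, c in zip(thresholds, c_scores) if c is not None]
    if not pts:
        return {"minimum": None, "absolute_maximum": None,
                "full_msa_value": None, "area": None}
    xs = np.array([t for t, _ in pts])
    ys = np.array([c for _, c in pts])
    absmax = ys[int(np.argmax(np.abs(ys)))]
    full = c_scores[0] if c_scores[0] is not None else None
    area = float(np.trapezoid(ys, xs)) if len(pts) > 1 else 0.0
    return {"minimum": float(ys.min()), "absolute_maximum": float(absmax),
            "full_msa_value": full, "area": area}


def fingerprint(msa_rows: list, ctx: ConservationContext, seed: int = 0,
                thresholds=DEFAULT_THRESHOLDS, min_rows: int = MIN_ROWS,
                n_iter: int | None = None) -> FingerprintCurve:
    """PPI fingerprint of one interface over the identity-threshold ladder.

    ``msa_rows`` is a list of ``(name, sequence)`` or plain sequences with
    the query first.  Thresholds with fewer than ``min_rows`` retained
    sequences give an undefined point.
    """
    if not msa_rows:
        raise MSAError("empty MSA")
    if not ctx.interface:
        raise ValueError("no interface residues mapped to the query")
    c_scores, is_values, p_values = [], [], []
    for k, t in enumerate(thresholds):
        tm = threshold_msa(msa_rows, t)
        if len(tm.retained_rows) < min_rows:
            c_scores.append(None)
            is_values.append(None)
            p_values.append(None)
            continue
        c, is_v, p = conservation_at(tm.retained_rows, ctx, n_iter,
                                     seed=seed * N_THRESHOLDS + k)
        c_scores.append(c)
        is_values.append(is_v)
        p_values.append(p)
    feats = curve_features(thresholds, c_scores)
    return FingerprintCurve(tuple(thresholds), c_scores, feats,
                            is_values, p_values)


def fingerprint_json(fp: FingerprintCurve) -> dict:
    return {"thresholds": list(fp.thresholds),
            "c_scores": fp.c_scores,
            "is_values": fp.is_values,
            "p_values": fp.p_values,
            "features": fp.features}
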