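"""Hierarchical clustering of homologous assemblies.

Assemblies are organised on three nested levels:

1. **state** — mono / homo / hetero;
2. **stoichiometry** — the canonical entity-multiplicity string (``A2B2``);
3. **geometry** — clusters of the QS-score distance (1 − QS) within each
   stoichiometry, using complete linkage (PDB-style survey) or greedy
   agglomeration (template consensus).

The threshold convention follows the heterogeneity-survey axis: a
threshold ``t`` merges assemblies whose QS-score is at least ``t``
(equivalently, cuts the dendrogram at distance ``1 − t``), so ``t = 0``
puts every assembly of a stoichiometry group in one cluster.  A literal
distance threshold is available via ``threshold_kind="distance"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .chain_mapping import IntractableMappingError, NoMappingError
from .qs_score import qs_score
from .structure_model import Assembly, _ensure_entities, global_identity, \
    stoichiometry_string

logger = logging.getLogger(__name__)

SEQ_CLUSTER_IDENTITY = 0.90


def oligomeric_state(a: Assembly) -> str:
    """mono / homo / hetero by chain count and entity composition."""
    _ensure_entities(a)
    if len(a.chains) == 1:
        return "mono"
    keys = {c.entity_key for c in a.chains}
    return "homo" if len(keys) == 1 else "hetero"


@dataclass
class AssemblyClusterTree:
    level1: dict            # state -> [assembly index]
    level2: dict            # (state, stoichiometry) -> [assembly index]
    level3: dict            # (state, stoichiometry, cluster_id) -> [index]
    excluded: list          # indices set aside (incomputable QS pairs)
    assemblies: list

    def cluster_of(self, index: int):
        for key, members in self.level3.items():
            if index in members:
                return key
        return None

    def to_json(self) -> dict:
        out = {}
        for (state, stoich, cid), members in sorted(self.level3.items()):
            out.setdefault(state, {}).setdefault(stoich, {})[str(cid)] = [
                self.assemblies[i].id for i in members]
        return {"tree": out,
                "excluded": [self.assemblies[i].id for i in self.excluded]}


def qs_distance_matrix(assemblies: list, max_brute: int | None = None):
    """Pairwise 1 − QS-score; incomputable pairs are recorded.

    Returns ``(matrix, failed_pairs)``; failed entries hold ``nan``.
    """
    n = len(assemblies)
    dist = np.zeros((n, n))
    failed = []
    for i in range(n):
        for j in range(i + 1, n):
            try:
                res = qs_score(assemblies[i], assemblies[j],
                               max_brute=max_brute)
                dist[i, j] = dist[j, i] = 1.0 - res.qs_score
            except (NoMappingError, IntractableMappingError) as exc:
                logger.warning("QS incomputable for %s vs %s: %s",
                               assemblies[i].id, assemblies[j].id, exc)
                dist[i, j] = dist[j, i] = np.nan
                failed.append((i, j))
    return dist, failed


def _drop_failed(indices, failed):
    """Greedily remove the assemblies involved in the most failed pairs."""
    failed = set(failed)
    dropped = []
    while failed:
        counts = {}
        for i, j in failed:
            counts[i] = counts.get(i, 0) + 1
            counts[j] = counts.get(j, 0) + 1
        worst = max(sorted(counts), key=lambda k: counts[k])
        dropped.append(worst)
        failed = {(i, j) for i, j in failed if worst not in (i, j)}
    kept = [i for i in indices if i not in dropped]
    return kept, dropped


def _cut_distance(threshold: float, threshold_kind: str) -> float:
    if threshold_kind == "qs":
        return 1.0 - threshold
    if threshold_kind == "distance":
        return threshold
    raise ValueError(f"unknown threshold_kind {threshold_kind!r}")


def _complete_linkage_clusters(dist: np.ndarray, cut: float):
    n = dist.shape[0]
    if n == 1:
        return np.array([1])
    z = linkage(squareform(dist, checks=False), method="complete")
    return fcluster(z, t=cut, criterion="distance")


def _greedy_clusters(dist: np.ndarray, cut: float):
    """Greedy agglomeration: repeatedly merge the closest pair of clusters
    (complete-linkage distance) not exceeding the cut; ties go to the
    lowest-index pair."""
    n = dist.shape[0]
    clusters = [[i] for i in range(n)]
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(dist[a, b] for a in clusters[i] for b in clusters[j])
                if d <= cut and (best is None or d < best[0] - 1e-12):
                    best = (d, i, j)
        if best is None:
            break
        _, i, j = best
        clusters[i] = sorted(clusters[i] + clusters[j])
        del clusters[j]
    labels = np.empty(n, dtype=int)
    for cid, members in enumerate(sorted(clusters), start=1):
        for m in members:
            labels[m] = cid
    return labels


def cluster_assemblies(assemblies: list, qs_threshold: float,
                       linkage_method: str = "complete",
                       threshold_kind: str = "qs",
                       max_brute: int | None = None) -> AssemblyClusterTree:
    """Three-level clustering of a set of homologous assemblies."""
    if not assemblies:
        raise ValueError("need at least one assembly")
    if linkage_method not in ("complete", "greedy"):
        raise ValueError(f"unknown linkage {linkage_method!r}")
    cut = _cut_distance(qs_threshold, threshold_kind)

    level1, level2, level3 = {}, {}, {}
    excluded = []
    for idx, a in enumerate(assemblies):
        state = oligomeric_state(a)
        level1.setdefault(state, []).append(idx)
    for state, members in level1.items():
        for idx in members:
            stoich = stoichiometry_string(assemblies[idx])
            level2.setdefault((state, stoich), []).append(idx)
    for (state, stoich), members in level2.items():
        sub = [assemblies[i] for i in members]
        dist, failed = qs_distance_matrix(sub, max_brute=max_brute)
        kept_local, dropped_local = _drop_failed(range(len(sub)), failed)
        excluded.extend(members[i] for i in dropped_local)
        if not kept_local:
            continue
        sel = np.ix_(kept_local, kept_local)
        dsub = dist[sel]
        if linkage_method == "complete":
            labels = _complete_linkage_clusters(dsub, cut)
        else:
            labels = _greedy_clusters(dsub, cut)
        for lab in sorted(set(labels)):
            key = (state, stoich, int(lab))
            level3[key] = [members[kept_local[k]]
                           for k in range(len(kept_local)) if labels[k] == lab]
    return AssemblyClusterTree(level1, level2, level3, excluded,
                               list(assemblies))


def heterogeneity_sweep(groups: list, thresholds,
                        threshold_kind: str = "qs",
                        linkage_method: str = "complete",
                        max_brute: int | None = None) -> pd.DataFrame:
    """Cluster-count distribution over assembly groups per threshold.

    Each group (e.g. a 90%-identity sequence cluster) is QS-clustered at
    every threshold; the table reports the fraction of groups with one,
    two, or three-plus QS clusters.  Fractions sum to 1 per threshold.
    """
    if any(len(g) == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    dists = []
    for group in groups:
        d, failed = qs_distance_matrix(group, max_brute=max_brute)
        kept, _ = _drop_failed(range(len(group)), failed)
        dists.append(d[np.ix_(kept, kept)])
    rows = []
    for t in thresholds:
        cut = _cut_distance(t, threshold_kind)
        counts = {1: 0, 2: 0, 3: 0}
        n_groups = 0
        for d in dists:
            if d.shape[0] == 0:
                continue
            n_groups += 1
            if linkage_method == "complete":
                labels = _complete_linkage_clusters(d, cut)
            else:
                labels = _greedy_clusters(d, cut)
            k = len(set(labels))
            counts[min(k, 3)] += 1
        rows.append({"threshold": t,
                     "frac_1_cluster": counts[1] / n_groups,
                     "frac_2_clusters": counts[2] / n_groups,
                     "frac_3plus_clusters": counts[3] / n_groups})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sequence-level grouping (CD-HIT-style greedy clustering at 90%)

def group_by_sequence(assemblies: list,
                      identity: float = SEQ_CLUSTER_IDENTITY) -> dict:
    """Group assemblies into sequence clusters.

    Chain sequences are greedily clustered (longest first; a sequence joins
    the first cluster whose representative it matches at >= ``identity``).
    An assembly's group key is the frozen set of its chains' cluster ids,
    which handles heteromers whose chains fall into different clusters.
    """
    reps = []  # (cluster_id, sequence)
    seq_cluster = {}
    all_seqs = sorted({c.sequence for a in assemblies for c in a.chains},
                      key=lambda s: (-len(s), s))
    for seq in all_seqs:
        placed = False
        for cid, rep in reps:
            ident, cov_s, cov_r = global_identity(seq, rep)
            if ident >= identity:
                seq_cluster[seq] = cid
                placed = True
                break
        if not placed:
            cid = len(reps)
            reps.append((cid, seq))
            seq_cluster[seq] = cid
    groups = {}
    for a in assemblies:
        key = frozenset(seq_cluster[c.sequence] for c in a.chains)
        groups.setdefault(key, []).append(a)
    return groups
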