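"""End-to-end template evaluation: filter, cluster, score, rank, report.

Given one or more target sequences, a pool of candidate template
assemblies and the target family MSA, ``run_pipeline``:

1. filters templates by three admissibility criteria — every target
   sequence must have a homologous chain in the template; two target
   sequences may not map to overlapping fragments of the same template
   chain; a heteromeric template must be topologically connected (its
   chain-chain contact graph has a single component);
2. clusters the surviving templates by state / stoichiometry / QS-score
   and derives per-template consensus fractions;
3. extracts the feature vector of every target–template pair (averaged
   over target sequences for hetero targets);
4. ranks templates by predicted QS-score when a trained ranker is given,
   by target–template sequence identity otherwise;
5. emits the clustering tree as a JSON report with per-template predicted
   QS, identity and coverage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import networkx as nx

from .assembly_clustering import cluster_assemblies, oligomeric_state
from .chain_mapping import HOMOLOGY_FLOOR
from .contact_map import contact_interface_residues, interface_contacts
from .structure_model import Assembly, align_sequences, global_identity, \
    stoichiometry_string
from .surface_interface import accessibility_records, classify_residues
from .template_features import (TemplateFeatureVector, TrainedRanker,
                                extract_features, rank_templates)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    homology_floor: float = HOMOLOGY_FLOOR
    qs_cluster_threshold: float = 0.7   # min QS for merging templates
    linkage: str = "greedy"
    seed: int = 0


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s")


# ---------------------------------------------------------------------------
# admissibility criteria

def template_admissible(target_seqs: list, template: Assembly,
                        floor: float = HOMOLOGY_FLOOR):
    """(admissible, reason).  Checks homologous-chain existence, fragment
    overlap, and topological connectivity."""
    # 1. every target sequence must hit at least one template chain
    best_chain = {}
    for t_idx, tseq in enumerate(target_seqs):
        hits = []
        for chain in template.chains:
            ident, _, _ = global_identity(tseq, chain.sequence)
            if ident >= floor:
                hits.append((ident, chain.chain_id))
        if not hits:
            return False, f"target {t_idx} has no homologous chain"
        best_chain[t_idx] = max(hits)[1]

    # 2. targets sharing a template chain must cover disjoint fragments
    by_chain = {}
    for t_idx, cid in best_chain.items():
        by_chain.setdefault(cid, []).append(t_idx)
    for cid, t_idxs in by_chain.items():
        if len(t_idxs) < 2:
            continue
        chain_seq = template.chain(cid).sequence
        ranges = []
        for t_idx in t_idxs:
            pairs = align_sequences(target_seqs[t_idx], chain_seq)
            cols = [j for _, j in pairs]
            ranges.append((min(cols), max(cols)))
        ranges.sort()
        for (s1, e1), (s2, e2) in zip(ranges, ranges[1:]):
            if s2 <= e1:
                return False, (f"targets map to overlapping fragments of "
                               f"chain {cid}")

    # 3. heteromeric templates must be topologically connected
    if len(template.chains) > 1:
        g = nx.Graph()
        g.add_nodes_from(c.chain_id for c in template.chains)
        contacts = interface_contacts(template)
        for (r1, r2) in contacts.contacts:
            g.add_edge(r1[0], r2[0])
        if not nx.is_connected(g):
            return False, "template is not topologically connected"
    return True, ""


# ---------------------------------------------------------------------------
# pipeline

def run_pipeline(target_seqs: list, templates: list,
                 msa_rows: list | None = None,
                 ranker: TrainedRanker | None = None,
                 config: PipelineConfig | None = None) -> dict:
    """Evaluate and rank candidate templates for a (possibly heteromeric)
    target; returns the hierarchical JSON report."""
    config = config or PipelineConfig()
    if not target_seqs:
        raise ValueError("need at least one target sequence")

    admissible, rejected = [], []
    for tpl in templates:
        ok, reason = template_admissible(target_seqs, tpl,
                                         config.homology_floor)
        if ok:
            admissible.append(tpl)
        else:
            logger.info("template %s rejected: %s", tpl.id, reason)
            rejected.append({"template": tpl.id, "reason": reason})
    if not admissible:
        return {"status": "no-template", "rejected": rejected,
                "n_targets": len(target_seqs)}

    tree = cluster_assemblies(admissible, config.qs_cluster_threshold,
                              linkage_method=config.linkage)
    n_total = len(admissible)
    consensus_of = {}
    for idx, tpl in enumerate(admissible):
        state = oligomeric_state(tpl)
        stoich = stoichiometry_string(tpl)
        state_n = len(tree.level1[state])
        stoich_n = len(tree.level2[(state, stoich)])
        key = tree.cluster_of(idx)
        qs_n = len(tree.level3[key]) if key else 1
        consensus_of[idx] = (state_n / n_total, stoich_n / n_total,
                             qs_n / n_total)

    candidates = []
    for idx, tpl in enumerate(admissible):
        records = accessibility_records(tpl)
        classifications = classify_residues(records)
        # sparse or low-resolution structures can lack residues passing the
        # burial rule; fall back to the contact-based interface then
        iface_ids = None
        if not any(c.label == "interface" for c in classifications):
            iface_ids = contact_interface_residues(interface_contacts(tpl))
            logger.info("template %s: no burial-classified interface; "
                        "using contact-based interface (%d residues)",
                        tpl.id, len(iface_ids))
        per_target = []
        for tseq in target_seqs:
            best = None
            for chain in tpl.chains:
                ident, _, _ = global_identity(tseq, chain.sequence)
                if best is None or ident > best[0]:
                    best = (ident, chain.chain_id)
            per_target.append(extract_features(
                tseq, tpl, template_id=tpl.id, chain_id=best[1],
                msa_rows=msa_rows, consensus=consensus_of[idx],
                records=records, classifications=classifications,
                interface_residue_ids=iface_ids, seed=config.seed))
        merged = _average_features(per_target)
        candidates.append(merged)

    if ranker is not None:
        ranked = rank_templates(ranker, candidates)
    else:  # identity baseline
        ranked = [(c, float("nan")) for c in sorted(
            candidates,
            key=lambda c: (-c.values["seq_identity_whole"], c.template_id))]

    report = _build_report(admissible, tree, candidates, ranked, rejected)
    return report


def _average_features(vectors: list) -> TemplateFeatureVector:
    if len(vectors) == 1:
        return vectors[0]
    base = vectors[0]
    values = {name: float(sum(v.values[name] for v in vectors) / len(vectors))
              for name in base.values}
    return TemplateFeatureVector(base.target_id, base.template_id, values,
                                 all(v.usable for v in vectors))


def _build_report(templates, tree, candidates, ranked, rejected) -> dict:
    rank_of = {cand.template_id: (pos + 1, pred)
               for pos, (cand, pred) in enumerate(ranked)}
    cand_of = {c.template_id: c for c in candidates}
    tree_json = {}
    for (state, stoich, cid), members in sorted(tree.level3.items()):
        leaf = []
        for idx in members:
            tpl = templates[idx]
            cand = cand_of[tpl.id]
            pos, pred = rank_of[tpl.id]
            cov = cand.values["coverage"]
            ident = (cand.values["seq_identity_whole"] / cov) if cov else 0.0
            leaf.append({"template": tpl.id, "rank": pos,
                         "predicted_qs": None if pred != pred else round(pred, 4),
                         "identity": round(ident, 4),
                         "coverage": round(cov, 4)})
        leaf.sort(key=lambda d: d["rank"])
        tree_json.setdefault(state, {}).setdefault(stoich, {})[str(cid)] = leaf
    ordered = [{"template": cand.template_id, "rank": pos + 1,
                "predicted_qs": None if pred != pred else round(pred, 4)}
               for pos, (cand, pred) in enumerate(ranked)]
    return {"status": "ok", "n_templates": len(templates),
            "ranking": ordered, "tree": tree_json, "rejected": rejected}


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
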