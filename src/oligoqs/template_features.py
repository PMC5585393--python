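"""Target–template features, quality labels, and the SVR template ranker.

For every target–template pair a numeric feature vector is assembled from
four property classes:

1. **sequence** — identity and BLOSUM62 similarity of the target–template
   alignment, plus secondary-structure and accessibility agreement, each
   over four structural regions of the template (whole, interface, core,
   surface);
2. **MSA** — mean profile entropy of the target family alignment, the
   template e-value, and the four fingerprint-curve features computed on
   the template interface fraction mapped onto the target;
3. **QS consensus** — the relative size of the template's cluster at the
   state, stoichiometry and QS-geometry levels of the homolog clustering;
4. **interface composition** — hydrophobic / hydrophilic composition
   difference between interface and surface, and the interface-vs-surface
   mean B-factor ratio.

All properties are weighted by the coverage of the target sequence.  A
support-vector regressor (RBF kernel, grid-searched hyper-parameters,
cross-validation folds grouped by target) predicts the model-vs-native
QS-score from these features; templates are ranked by the prediction.
"""

from __future__ import annotations

import hashlib
import logging
import math
import warnings
from dataclasses import dataclass

import joblib
import numpy as np
from Bio.Align import substitution_matrices
from sklearn.feature_selection import SelectKBest
from sklearn.model_selection import GridSearchCV, GroupKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .ppi_fingerprint import (build_chain_context, column_relative_entropy,
                              fingerprint)
from .structure_model import Assembly, align_sequences
from .surface_interface import (RASA_CUT, accessibility_records,
                                classify_residues)

logger = logging.getLogger(__name__)

BLOSUM62 = substitution_matrices.load("BLOSUM62")
HYDROPHOBIC = set("AVLIMFWC")
HYDROPHILIC = set("RNDQEHKSTY")
COEVOLUTION_CUTOFF = 7.0       # Å, realized-contact distance
COEVOLUTION_FACTOR = 1.5       # retain top 1.5 * target length predictions

REGIONS = ("whole", "interface", "core", "surface")
SCHEMA_VERSION = "v1"
FEATURE_NAMES = tuple(
    [f"seq_identity_{r}" for r in REGIONS]
    + [f"seq_similarity_{r}" for r in REGIONS]
    + [f"ss_agreement_{r}" for r in REGIONS]
    + [f"acc_agreement_{r}" for r in REGIONS]
    + ["msa_mean_entropy", "template_evalue",
       "fp_minimum", "fp_absolute_maximum", "fp_full_msa_value", "fp_area",
       "consensus_state", "consensus_stoichiometry", "consensus_qs_cluster",
       "comp_hydrophobic", "comp_hydrophilic", "comp_bfactor_ratio",
       "coverage"])


def schema_hash(names=FEATURE_NAMES) -> str:
    h = hashlib.sha256((SCHEMA_VERSION + "|".join(names)).encode())
    return h.hexdigest()[:12]


@dataclass
class TemplateFeatureVector:
    target_id: str
    template_id: str
    values: dict                 # feature name -> float
    usable: bool = True
    label: float | None = None   # observed QS-score, when known

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in FEATURE_NAMES], dtype=float)


# ---------------------------------------------------------------------------
# quality categories

QUALITY_BINS = (0.1, 0.3, 0.7)


@dataclass
class QualityLabel:
    category: str  # incorrect | low | medium | high


def quality_label(qs: float) -> QualityLabel:
    """CAPRI-style bins on the QS-score: [0,0.1) incorrect, [0.1,0.3) low,
    [0.3,0.7] medium, (0.7,1] high."""
    if not 0.0 <= qs <= 1.0:
        raise ValueError("QS-score must lie in [0, 1]")
    if qs < QUALITY_BINS[0]:
        return QualityLabel("incorrect")
    if qs < QUALITY_BINS[1]:
        return QualityLabel("low")
    if qs <= QUALITY_BINS[2]:
        return QualityLabel("medium")
    return QualityLabel("high")


# ---------------------------------------------------------------------------
# secondary structure and helpers

def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return math.degrees(math.atan2(y, x))


def assign_secondary_structure(chain) -> str:
    """3-state (H/E/C) assignment from backbone phi/psi dihedrals.

    Residues without a complete N-CA-C backbone context are coil.
    """
    atoms = []
    for res in chain.residues:
        d = {n: xyz for n, xyz, _ in res.atoms}
        atoms.append((d.get("N"), d.get("CA"), d.get("C")))
    ss = []
    for i in range(len(atoms)):
        n_i, ca_i, c_i = atoms[i]
        prev_c = atoms[i - 1][2] if i > 0 else None
        next_n = atoms[i + 1][0] if i + 1 < len(atoms) else None
        if any(x is None for x in (n_i, ca_i, c_i, prev_c, next_n)):
            ss.append("C")
            continue
        phi = _dihedral(prev_c, n_i, ca_i, c_i)
        psi = _dihedral(n_i, ca_i, c_i, next_n)
        if -100.0 <= phi <= -30.0 and -80.0 <= psi <= 0.0:
            ss.append("H")
        elif phi <= -90.0 and (psi >= 90.0 or psi <= -150.0):
            ss.append("E")
        else:
            ss.append("C")
    return "".join(ss)


# ---------------------------------------------------------------------------
# feature extraction

def _region_indices(chain, classifications, interface_residue_ids=None):
    label_of = {c.res_id: c.label for c in classifications}
    regions = {"whole": [], "interface": [], "core": [], "surface": []}
    for i, res in enumerate(chain.residues):
        regions["whole"].append(i)
        label = label_of[res.res_id]
        if interface_residue_ids is not None:
            if res.res_id in interface_residue_ids:
                label = "interface"
            elif label == "interface":
                label = "surface"
        regions[label].append(i)
    return regions


def _agreement_features(pairs_by_template_idx, region_idx, value_fn):
    """Mean of a per-aligned-position agreement over each region; regions
    with no aligned position score 0."""
    out = {}
    for region, idxs in region_idx.items():
        vals = [value_fn(i) for i in idxs if i in pairs_by_template_idx]
        vals = [v for v in vals if v is not None]
        out[region] = float(np.mean(vals)) if vals else 0.0
    return out


def extract_features(target_seq: str, template: Assembly, *,
                     target_id: str = "target", template_id: str | None = None,
                     chain_id: str | None = None,
                     msa_rows: list | None = None,
                     template_evalue: float = 0.0,
                     consensus: tuple = (1.0, 1.0, 1.0),
                     target_ss: str | None = None,
                     target_acc: str | None = None,
                     records=None, classifications=None,
                     interface_residue_ids=None,
                     seed: int = 0) -> TemplateFeatureVector:
    """Feature vector of one target-sequence / template pair.

    The target sequence is globally aligned to one template chain (the
    first, unless ``chain_id`` is given); template regions come from the
    25% core/surface/interface classification of the full template
    assembly.  ``target_ss`` / ``target_acc`` are optional per-target-
    position strings (H/E/C and e/b); without them the corresponding
    agreement features are 0.  The pair is flagged unusable when no
    template interface residue is aligned.
    """
    template_id = template_id or template.id
    chain = template.chain(chain_id) if chain_id else template.chains[0]
    if records is None:
        records = accessibility_records(template)
    if classifications is None:
        classifications = classify_residues(records)
    region_idx = _region_indices(chain, classifications,
                                 interface_residue_ids)
    rasa_of = {r.res_id: r.rasa for r in records}

    pairs = align_sequences(target_seq, chain.sequence)
    t_of_template = {j: i for i, j in pairs}  # template idx -> target idx
    coverage = len(pairs) / len(target_seq) if target_seq else 0.0

    usable = any(j in t_of_template for j in region_idx["interface"])

    def identity_at(j):
        i = t_of_template[j]
        return 1.0 if target_seq[i] == chain.sequence[j] else 0.0

    def similarity_at(j):
        i = t_of_template[j]
        try:
            return 1.0 if BLOSUM62[target_seq[i], chain.sequence[j]] > 0 \
                else 0.0
        except (KeyError, IndexError):
            return 0.0

    template_ss = assign_secondary_structure(chain)

    def ss_at(j):
        if target_ss is None:
            return None
        i = t_of_template[j]
        if i >= len(target_ss):
            return None
        return 1.0 if target_ss[i] == template_ss[j] else 0.0

    def acc_at(j):
        if target_acc is None:
            return None
        i = t_of_template[j]
        if i >= len(target_acc):
            return None
        buried = rasa_of[chain.residues[j].res_id] < RASA_CUT
        return 1.0 if target_acc[i] == ("b" if buried else "e") else 0.0

    ident = _agreement_features(t_of_template, region_idx, identity_at)
    simil = _agreement_features(t_of_template, region_idx, similarity_at)
    ss_agr = _agreement_features(t_of_template, region_idx, ss_at)
    acc_agr = _agreement_features(t_of_template, region_idx, acc_at)

    # MSA properties
    mean_entropy = 0.0
    fp_feats = {"minimum": 0.0, "absolute_maximum": 0.0,
                "full_msa_value": 0.0, "area": 0.0}
    if msa_rows:
        cons = column_relative_entropy([s for _, s in msa_rows]
                                       if isinstance(msa_rows[0], tuple)
                                       else msa_rows)
        mean_entropy = float(cons.entropy_norm[cons.defined].mean()) \
            if cons.defined.any() else 0.0
        mapped_interface = {t_of_template[j]
                            for j in region_idx["interface"]
                            if j in t_of_template}
        if mapped_interface:
            ctx = build_chain_context(template, chain.chain_id,
                                      query_seq=target_seq,
                                      records=records,
                                      classifications=classifications,
                                      interface_positions=mapped_interface,
                                      interface_residue_ids=interface_residue_ids)
            if ctx.interface and len(ctx.surface) > len(ctx.interface):
                fp = fingerprint(msa_rows, ctx, seed=seed)
                fp_feats = {k: (v if v is not None else 0.0)
                            for k, v in fp.features.items()}

    # composition
    def _frac(idxs, pool):
        aas = [chain.residues[i].aa for i in idxs]
        return sum(a in pool for a in aas) / len(aas) if aas else 0.0

    iface, surf = region_idx["interface"], region_idx["surface"]
    comp_phob = _frac(iface, HYDROPHOBIC) - _frac(surf, HYDROPHOBIC)
    comp_phil = _frac(iface, HYDROPHILIC) - _frac(surf, HYDROPHILIC)
    b_iface = np.mean([chain.residues[i].mean_bfactor() for i in iface]) \
        if iface else 0.0
    b_surf = np.mean([chain.residues[i].mean_bfactor() for i in surf]) \
        if surf else 0.0
    b_ratio = float(b_iface / b_surf) if b_surf > 0 else 1.0

    values = {}
    for region in REGIONS:
        values[f"seq_identity_{region}"] = ident[region]
        values[f"seq_similarity_{region}"] = simil[region]
        values[f"ss_agreement_{region}"] = ss_agr[region]
        values[f"acc_agreement_{region}"] = acc_agr[region]
    values["msa_mean_entropy"] = mean_entropy
    values["template_evalue"] = float(template_evalue)
    values["fp_minimum"] = fp_feats["minimum"]
    values["fp_absolute_maximum"] = fp_feats["absolute_maximum"]
    values["fp_full_msa_value"] = fp_feats["full_msa_value"]
    values["fp_area"] = fp_feats["area"]
    values["consensus_state"] = float(consensus[0])
    values["consensus_stoichiometry"] = float(consensus[1])
    values["consensus_qs_cluster"] = float(consensus[2])
    values["comp_hydrophobic"] = comp_phob
    values["comp_hydrophilic"] = comp_phil
    values["comp_bfactor_ratio"] = b_ratio
    values["coverage"] = coverage
    for name in FEATURE_NAMES:
        if name != "coverage":
            values[name] *= coverage
    return TemplateFeatureVector(target_id, template_id, values, usable)


# ---------------------------------------------------------------------------
# co-evolution agreement

def coevolution_agreement(model: Assembly, predicted_contacts: list,
                          target_length: int) -> float:
    """Fraction of predicted inter-chain contacts realized in a model.

    ``predicted_contacts`` rows are ``(chain1, res1, chain2, res2, score)``;
    only the top ``1.5 * target_length`` predictions by score are retained.
    A prediction is realized when both residues exist in the model and
    their representative atoms are closer than 7 Å.
    """
    if not predicted_contacts:
        raise ValueError("empty contact prediction")
    ranked = sorted(predicted_contacts, key=lambda r: -float(r[4]))
    keep = max(1, int(COEVOLUTION_FACTOR * target_length))
    ranked = ranked[:keep]
    realized = 0
    for c1, r1, c2, r2, _ in ranked:
        try:
            res1 = model.residue((c1, int(r1), ""))
            res2 = model.residue((c2, int(r2), ""))
        except KeyError:
            continue
        if res1.rep_coord is None or res2.rep_coord is None:
            continue
        if np.linalg.norm(res1.rep_coord - res2.rep_coord) < COEVOLUTION_CUTOFF:
            realized += 1
    return realized / len(ranked)


# ---------------------------------------------------------------------------
# SVR ranker

@dataclass
class RankerConfig:
    n_folds: int = 10
    c_grid: tuple = (1.0, 10.0, 100.0)
    gamma_grid: tuple = ("scale", 0.1, 0.01)
    epsilon_grid: tuple = (0.01, 0.1)
    top_k_features: int | None = 25
    seed: int = 0


@dataclass
class TrainedRanker:
    model: object
    feature_names: tuple
    schema: str
    best_params: dict

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.model.predict(np.asarray(x, dtype=float))

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "TrainedRanker":
        return joblib.load(path)


def _finite_f_regression(x, y):
    """Univariate regression scores that stay rankable in edge cases.

    Ranks features by the absolute Pearson correlation with the label
    (the same ordering as the univariate F-test), which remains finite
    for a perfectly correlated feature — where the F-statistic blows up
    and the feature would silently drop out of the top-k selection — and
    is 0 for a constant feature.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    xc = x - x.mean(axis=0)
    denom = np.sqrt((xc ** 2).sum(axis=0) * (yc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.abs(xc.T @ yc) / denom
    scores = np.nan_to_num(r, nan=0.0)
    return scores, 1.0 - scores


def train_ranker(features, labels, groups,
                 config: RankerConfig | None = None) -> TrainedRanker:
    """Fit the RBF support-vector regressor on (feature vector, QS) pairs.

    ``groups`` assigns each row to a target; cross-validation folds never
    split a target between train and test.  Grid search covers the
    regularisation, kernel width and epsilon; optional univariate feature
    selection keeps the top-k features.
    """
    config = config or RankerConfig()
    if features and isinstance(features[0], TemplateFeatureVector):
        x = np.vstack([f.as_array() for f in features])
    else:
        x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    groups = np.asarray(groups)
    if not np.isfinite(x).all() or not np.isfinite(y).all():
        raise ValueError("features and labels must be finite")
    n_groups = len(set(groups.tolist()))
    if n_groups < 2:
        raise ValueError("need at least 2 target groups")
    n_folds = config.n_folds
    if n_groups < n_folds:
        warnings.warn(f"only {n_groups} target groups; reducing folds "
                      f"from {n_folds}", stacklevel=2)
        n_folds = n_groups

    steps = [("scale", StandardScaler())]
    if config.top_k_features is not None and np.var(y) > 0:
        k = min(config.top_k_features, x.shape[1])
        steps.append(("select", SelectKBest(_finite_f_regression, k=k)))
    steps.append(("svr", SVR(kernel="rbf")))
    pipe = Pipeline(steps)
    grid = {"svr__C": list(config.c_grid),
            "svr__gamma": list(config.gamma_grid),
            "svr__epsilon": list(config.epsilon_grid)}
    cv = GroupKFold(n_splits=n_folds)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        search = GridSearchCV(pipe, grid, cv=cv, n_jobs=1,
                              scoring="neg_mean_squared_error")
        search.fit(x, y, groups=groups)
    logger.info("SVR grid search best params: %s", search.best_params_)
    return TrainedRanker(search.best_estimator_, FEATURE_NAMES,
                         schema_hash(), search.best_params_)


def rank_templates(ranker: TrainedRanker, candidates: list) -> list:
    """Candidates ordered by descending predicted QS-score.

    Returns ``[(candidate, predicted_qs), ...]``; ties break on template
    id for determinism.  Raises on feature-schema mismatch.
    """
    if ranker.schema != schema_hash():
        raise ValueError("feature schema mismatch between ranker and "
                         "candidates")
    if not candidates:
        return []
    x = np.vstack([c.as_array() for c in candidates])
    preds = ranker.predict(x)
    order = sorted(range(len(candidates)),
                   key=lambda i: (-preds[i], candidates[i].template_id))
    return [(candidates[i], float(preds[i])) for i in order]


def write_feature_table(features: list, path) -> None:
    """TSV export with a versioned header line."""
    with open(path, "w") as fh:
        fh.write(f"#schema\t{SCHEMA_VERSION}\t{schema_hash()}\n")
        fh.write("target_id\ttemplate_id\tusable\tlabel\t"
                 + "\t".join(FEATURE_NAMES) + "\n")
        for f in features:
            lab = "" if f.label is None else f"{f.label:.6f}"
            vals = "\t".join(f"{f.values[n]:.6f}" for n in FEATURE_NAMES)
            fh.write(f"{f.target_id}\t{f.template_id}\t{int(f.usable)}\t"
                     f"{lab}\t{vals}\n")


def read_feature_table(path) -> list:
    feats = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "#schema" or header[2] != schema_hash():
            raise ValueError("feature table schema mismatch")
        cols = fh.readline().rstrip("\n").split("\t")
        name_idx = {n: i for i, n in enumerate(cols)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            values = {n: float(parts[name_idx[n]]) for n in FEATURE_NAMES}
            label = float(parts[3]) if parts[3] else None
            feats.append(TemplateFeatureVector(
                parts[0], parts[1], values, bool(int(parts[2])), label))
    return feats


def read_contact_predictions(path) -> list:
    """TSV contact predictions: chain1, res1, chain2, res2, score."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            c1, r1, c2, r2, score = line.split()[:5]
            rows.append((c1, int(r1), c2, int(r2), float(score)))
    if not rows:
        raise ValueError(f"no contact predictions in {path}")
    return rows
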