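import numpy as np
import pytest
from scipy.stats import spearmanr

from oligoqs.contact_map import contact_interface_residues, interface_contacts
from oligoqs.structure_model import Assembly
from oligoqs.synthetic_fixtures import MSASpec, OligomerSpec, make_msa, \
    make_oligomer
from oligoqs.template_features import (FEATURE_NAMES, RankerConfig,
                                       TemplateFeatureVector,
                                       assign_secondary_structure,
                                       coevolution_agreement,
                                       extract_features, quality_label,
                                       rank_templates, read_feature_table,
                                       train_ranker, write_feature_table)

from conftest import build_chain


class TestQualityLabel:
    @pytest.mark.parametrize("qs,expected", [
        (0.0, "incorrect"), (0.05, "incorrect"),
        (0.1, "low"), (0.25, "low"),
        (0.3, "medium"), (0.5, "medium"), (0.7, "medium"),
        (0.75, "high"), (1.0, "high"),
    ])
    def test_bins(self, qs, expected):
        assert quality_label(qs).category == expected

    def test_out_of_range_rejected(self):
        for qs in (-0.1, 1.1):
            with pytest.raises(ValueError):
                quality_label(qs)

    def test_monotone_in_qs(self):
        order = ["incorrect", "low", "medium", "high"]
        prev = 0
        for qs in np.linspace(0.0, 1.0, 101):
            rank = order.index(quality_label(float(qs)).category)
            assert rank >= prev
            prev = rank


class TestCoevolutionAgreement:
    def model(self):
        # chains 10 Å apart in y; residues 50 Å apart in x
        coords_a = [(50.0 * i, 0.0, 0.0) for i in range(6)]
        coords_b = [(50.0 * i, 5.0, 0.0) for i in range(6)]
        return Assembly("m", [build_chain("A", "ACDEFG", coords_a),
                              build_chain("B", "ACDEFG", coords_b)])

    def test_all_realized(self):
        m = self.model()
        preds = [("A", i + 1, "B", i + 1, 1.0) for i in range(6)]
        assert coevolution_agreement(m, preds, target_length=4) == 1.0

    def test_none_realized(self):
        m = self.model()
        preds = [("A", i + 1, "B", (i + 3) % 6 + 1, 1.0) for i in range(6)]
        assert coevolution_agreement(m, preds, target_length=4) == 0.0

    def test_half_realized(self):
        m = self.model()
        preds = ([("A", i + 1, "B", i + 1, 1.0) for i in range(3)]
                 + [("A", i + 1, "B", (i + 3) % 6 + 1, 1.0)
                    for i in range(3, 6)])
        assert coevolution_agreement(m, preds, target_length=4) == 0.5

    def test_truncation_to_top_scoring(self):
        m = self.model()
        # 3 realized with high scores + 6 unrealizable low-score decoys;
        # 1.5 * target_length 2 = 3 retained -> all realized
        preds = [("A", i + 1, "B", i + 1, 10.0) for i in range(3)]
        preds += [("A", 1, "B", 6, 0.1)] * 6
        assert coevolution_agreement(m, preds, target_length=2) == 1.0

    def test_empty_prediction_rejected(self):
        with pytest.raises(ValueError):
            coevolution_agreement(self.model(), [], target_length=4)


@pytest.fixture(scope="module")
def template_with_interface():
    tpl = make_oligomer(OligomerSpec(2, "C2", 30, "homo", seed=400))
    iface = contact_interface_residues(interface_contacts(tpl))
    return tpl, iface


class TestExtractFeatures:
    def test_identical_template_scores_one(self, template_with_interface):
        tpl, iface = template_with_interface
        chain = tpl.chains[0]
        ss = assign_secondary_structure(chain)
        fv = extract_features(chain.sequence, tpl,
                              interface_residue_ids=iface,
                              target_ss=ss,
                              consensus=(1.0, 1.0, 1.0))
        assert fv.usable
        assert fv.values["coverage"] == pytest.approx(1.0)
        for region in ("whole", "interface", "surface"):
            assert fv.values[f"seq_identity_{region}"] == pytest.approx(1.0)
            assert fv.values[f"seq_similarity_{region}"] == pytest.approx(1.0)
            assert fv.values[f"ss_agreement_{region}"] == pytest.approx(1.0)
        for name in ("consensus_state", "consensus_stoichiometry",
                     "consensus_qs_cluster"):
            assert fv.values[name] == pytest.approx(1.0)

    def test_coverage_weighting(self, template_with_interface):
        """Target twice the template length: coverage 0.5 halves every
        property feature."""
        tpl, iface = template_with_interface
        chain = tpl.chains[0]
        target = chain.sequence + "G" * len(chain.sequence)
        fv = extract_features(target, tpl, interface_residue_ids=iface)
        assert fv.values["coverage"] == pytest.approx(0.5)
        # aligned half is identical: identity 1.0 weighted by coverage 0.5
        assert fv.values["seq_identity_whole"] == pytest.approx(0.5)

    def test_unrelated_target_flagged_unusable(self, template_with_interface):
        tpl, iface = template_with_interface
        fv = extract_features("G" * 30, tpl, interface_residue_ids=set())
        assert not fv.usable

    def test_feature_vector_complete_and_finite(self,
                                                template_with_interface):
        tpl, iface = template_with_interface
        rows = make_msa(MSASpec(n_sequences=20, length=30,
                                interface_columns=(0, 1, 28, 29), seed=4))
        fv = extract_features(tpl.chains[0].sequence, tpl,
                              interface_residue_ids=iface, msa_rows=rows)
        arr = fv.as_array()
        assert arr.shape == (len(FEATURE_NAMES),)
        assert np.isfinite(arr).all()


def synthetic_dataset(rng, n_targets, n_templates, noise=0.0):
    """Feature vectors with qs = clamp(first feature); optional noise."""
    feats, labels, groups = [], [], []
    for t in range(n_targets):
        for k in range(n_templates):
            x = rng.uniform(0.0, 1.0, len(FEATURE_NAMES))
            qs = float(np.clip(x[0] + rng.normal(0.0, noise), 0.0, 1.0))
            feats.append(TemplateFeatureVector(
                f"t{t:03d}", f"t{t:03d}_tpl{k}",
                dict(zip(FEATURE_NAMES, x)), True, qs))
            labels.append(qs)
            groups.append(f"t{t:03d}")
    return feats, labels, groups


class TestRanker:
    def test_recovers_planted_monotone_relation(self):
        rng = np.random.default_rng(7)
        feats, labels, groups = synthetic_dataset(rng, 30, 8)
        targets = sorted(set(groups))
        train_t = set(targets[:21])
        tr = [i for i, g in enumerate(groups) if g in train_t]
        te = [i for i, g in enumerate(groups) if g not in train_t]
        ranker = train_ranker([feats[i] for i in tr],
                              [labels[i] for i in tr],
                              [groups[i] for i in tr],
                              RankerConfig(n_folds=10))
        preds = ranker.predict(np.vstack([feats[i].as_array() for i in te]))
        rho = spearmanr(preds, [labels[i] for i in te]).statistic
        assert rho > 0.95

    def test_constant_labels_give_constant_predictor(self):
        rng = np.random.default_rng(8)
        feats, _, groups = synthetic_dataset(rng, 6, 4)
        labels = [0.42] * len(feats)
        ranker = train_ranker(feats, labels, groups,
                              RankerConfig(n_folds=3, c_grid=(1.0,),
                                           gamma_grid=("scale",),
                                           epsilon_grid=(0.05,)))
        preds = ranker.predict(np.vstack([f.as_array() for f in feats]))
        assert np.allclose(preds, 0.42, atol=0.05 + 1e-6)

    def test_fold_count_reduced_with_warning(self):
        rng = np.random.default_rng(9)
        feats, labels, groups = synthetic_dataset(rng, 4, 5)
        with pytest.warns(UserWarning, match="reducing folds"):
            train_ranker(feats, labels, groups,
                         RankerConfig(n_folds=10, c_grid=(1.0,),
                                      gamma_grid=("scale",),
                                      epsilon_grid=(0.05,)))

    def test_single_group_rejected(self):
        rng = np.random.default_rng(10)
        feats, labels, _ = synthetic_dataset(rng, 1, 6)
        with pytest.raises(ValueError):
            train_ranker(feats, labels, ["t0"] * len(feats))


@pytest.fixture(scope="module")
def trained():
    rng = np.random.default_rng(11)
    feats, labels, groups = synthetic_dataset(rng, 12, 5)
    return train_ranker(feats, labels, groups,
                        RankerConfig(n_folds=5, c_grid=(10.0,),
                                     gamma_grid=(0.01,),
                                     epsilon_grid=(0.01,)))


class TestRankTemplates:
    def test_single_candidate_ranks_first(self, trained):
        rng = np.random.default_rng(12)
        feats, _, _ = synthetic_dataset(rng, 1, 1)
        ranked = rank_templates(trained, feats)
        assert len(ranked) == 1 and ranked[0][0] is feats[0]

    def test_monotone_feature_order_preserved(self, trained):
        cands = []
        for k, v in enumerate((0.1, 0.5, 0.9)):
            values = dict(zip(FEATURE_NAMES, [v] * len(FEATURE_NAMES)))
            cands.append(TemplateFeatureVector("t", f"tpl{k}", values, True))
        ranked = rank_templates(trained, cands)
        assert [c.template_id for c, _ in ranked] == ["tpl2", "tpl1", "tpl0"]

    def test_identical_candidates_stable_id_order(self, trained):
        values = dict(zip(FEATURE_NAMES, [0.5] * len(FEATURE_NAMES)))
        cands = [TemplateFeatureVector("t", "tplB", dict(values), True),
                 TemplateFeatureVector("t", "tplA", dict(values), True)]
        ranked = rank_templates(trained, cands)
        assert [c.template_id for c, _ in ranked] == ["tplA", "tplB"]


def test_feature_table_round_trip(tmp_path):
    rng = np.random.default_rng(13)
    feats, _, _ = synthetic_dataset(rng, 2, 3)
    path = tmp_path / "features.tsv"
    write_feature_table(feats, path)
    back = read_feature_table(path)
    assert len(back) == len(feats)
    for a, b in zip(feats, back):
        assert a.template_id == b.template_id
        assert a.label == pytest.approx(b.label, abs=1e-6)
        assert np.allclose(a.as_array(), b.as_array(), atol=1e-6)
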