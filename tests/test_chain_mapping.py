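import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from oligoqs.chain_mapping import (NoMappingError, count_brute_candidates,
                                   detect_symmetry_groups, map_chains,
                                   superpose, _mapping_rmsd)
from oligoqs.structure_model import Assembly
from oligoqs.synthetic_fixtures import (OligomerSpec, clone_assembly,
                                        make_oligomer, perturb_assembly)

from conftest import line_chain


def rigid_copy(a, seed=0, angle=40.0):
    """Exact rigid motion of a whole assembly."""
    rng = np.random.default_rng(seed)
    rot = Rotation.from_euler("xyz", rng.uniform(-angle, angle, 3),
                              degrees=True).as_matrix()
    trans = rng.uniform(-20, 20, 3)
    b = clone_assembly(a, a.id + "_moved")
    for chain in b.chains:
        for res in chain.residues:
            res.atoms = [(n, rot @ xyz + trans, bf)
                         for n, xyz, bf in res.atoms]
            if res.rep_coord is not None:
                res.rep_coord = rot @ res.rep_coord + trans
    return b


class TestSuperpose:
    def test_identical_sets_rmsd_zero(self):
        pts = np.random.default_rng(1).uniform(0, 10, (10, 3))
        _, _, rmsd = superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_pure_translation_rmsd_zero(self):
        pts = np.random.default_rng(2).uniform(0, 10, (10, 3))
        rot, trans, rmsd = superpose(pts, pts + np.array([5.0, 0, 0]))
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(rot, np.eye(3), atol=1e-9)

    def test_agrees_with_independent_kabsch(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 10, (10, 3))
        b = a.copy()
        b[0] += np.array([1.0, 0, 0])
        _, _, rmsd = superpose(a, b)
        # scipy's align_vectors is an independent Kabsch implementation
        rot, rssd = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
        assert rmsd == pytest.approx(rssd / np.sqrt(len(a)), abs=1e-9)

    def test_no_reflection(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 10, (12, 3))
        b = a @ np.diag([-1.0, 1.0, 1.0])  # mirror image
        rot, _, rmsd = superpose(a, b)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1

    def test_errors(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        with pytest.raises(ValueError):
            superpose(np.zeros((4, 3)), np.zeros((5, 3)))


class TestSymmetryGroups:
    def test_c2_dimer_two_singletons_one_transform(self, c2_dimer):
        sg = detect_symmetry_groups(c2_dimer)
        assert sg.order == 2
        assert sorted(map(sorted, sg.groups)) == [["A"], ["B"]]
        assert sg.rotation is not None

    def test_d2_tetramer_two_groups_of_two(self, d2_tetramer):
        sg = detect_symmetry_groups(d2_tetramer)
        assert sg.order == 2
        assert sorted(len(g) for g in sg.groups) == [2, 2]

    def test_hetero_tetramer_pairs_of_alpha_beta(self, a2b2):
        sg = detect_symmetry_groups(a2b2)
        assert sg.order == 2
        ent = {c.chain_id: c.entity_key for c in a2b2.chains}
        for group in sg.groups:
            assert sorted(ent[cid] for cid in group) == [0, 1]

    def test_asymmetric_assembly_falls_back_to_singletons(self):
        a = make_oligomer(OligomerSpec(3, "none", 25, seed=5))
        sg = detect_symmetry_groups(a)
        assert sg.order == 1
        assert all(len(g) == 1 for g in sg.groups)


def brute_force_min_rmsd(a, b):
    """Independent oracle: enumerate every entity-consistent bijection."""
    from oligoqs.chain_mapping import match_entities, _chains_by_entity
    match = match_entities(a, b)
    ca = _chains_by_entity(a, match.keys())
    cb = _chains_by_entity(b, match.values())
    per_entity = []
    for ka in sorted(match):
        la = sorted(ca[ka], key=lambda c: c.chain_id)
        lb = sorted(cb[match[ka]], key=lambda c: c.chain_id)
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
    best = np.inf
    for combo in itertools.product(*per_entity):
        pairs = [p for part in combo for p in part]
        best = min(best, _mapping_rmsd(a, b, pairs))
    return best


class TestMapChains:
    def test_self_mapping_rmsd_zero(self, c2_dimer):
        cm, rm = map_chains(c2_dimer, clone_assembly(c2_dimer, "copy"))
        assert cm.rmsd == pytest.approx(0.0, abs=1e-9)
        assert set(cm.as_dict()) == {"A", "B"}
        assert len(rm.pairs) == c2_dimer.n_residues()

    def test_rotated_trimer_maps_at_zero_rmsd(self, c3_trimer):
        moved = rigid_copy(c3_trimer, seed=11)
        assert count_brute_candidates(c3_trimer, moved) == 6  # 3!
        cm, _ = map_chains(c3_trimer, moved)
        assert cm.method == "brute_force"
        assert cm.rmsd == pytest.approx(0.0, abs=1e-6)

    def test_dimer_against_tetramer_partial_mapping(self, d2_tetramer):
        dimer = perturb_assembly(d2_tetramer, 0.0, "subcomplex", n_keep=2)
        cm, _ = map_chains(d2_tetramer, dimer)
        assert len(cm.pairs) == 2
        assert cm.rmsd == pytest.approx(
            brute_force_min_rmsd(d2_tetramer, dimer), abs=1e-6)

    @pytest.mark.parametrize("fixture,seed", [
        ("c3_trimer", 21), ("d2_tetramer", 22), ("a2b2", 23)])
    def test_symmetry_guided_equals_brute_force(self, fixture, seed, request):
        a = request.getfixturevalue(fixture)
        b = perturb_assembly(rigid_copy(a, seed=seed), 0.4, "jitter",
                             seed=seed)
        cm_sym, _ = map_chains(a, b, max_brute=0)  # force symmetry search
        assert cm_sym.method == "symmetry_guided"
        assert cm_sym.rmsd == pytest.approx(brute_force_min_rmsd(a, b),
                                            abs=1e-6)

    def test_forward_and_backward_mappings_are_inverse(self, a2b2):
        b = perturb_assembly(rigid_copy(a2b2, seed=31), 0.5, "jitter",
                             seed=31)
        cm_ab, _ = map_chains(a2b2, b)
        cm_ba, _ = map_chains(b, a2b2)
        assert sorted((y, x) for x, y in cm_ab.pairs) == sorted(cm_ba.pairs)
        assert cm_ab.rmsd == pytest.approx(cm_ba.rmsd, abs=1e-9)

    def test_unrelated_assemblies_raise(self):
        a = Assembly("a", [line_chain("A", "ACDEFGHIKLMNPQRSTVWYA")])
        b = Assembly("b", [line_chain("B", "GGGGGGGGGGGGGGGGGGGGG")])
        with pytest.raises(NoMappingError):
            map_chains(a, b)
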