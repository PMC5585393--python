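import math

import numpy as np
import pytest
from scipy.stats import gaussian_kde

from oligoqs.ppi_fingerprint import (ColumnConservation, MSAError,
                                     column_relative_entropy,
                                     conservation_score,
                                     curve_features, fingerprint,
                                     interface_p_value,
                                     interface_surface_ratio,
                                     patch_null_distribution, read_msa,
                                     region_mean_entropy,
                                     sequence_identity_to_query,
                                     threshold_msa)
from oligoqs.synthetic_fixtures import MSASpec, make_msa


class TestColumnRelativeEntropy:
    def test_background_like_column_scores_zero(self):
        cons = column_relative_entropy(["AV", "VA"])
        assert cons.re[0] == pytest.approx(0.0, abs=1e-12)
        assert cons.re[1] == pytest.approx(0.0, abs=1e-12)

    def test_conserved_column_uniform_background(self):
        rows = ["ACDEFGHIKLMNPQRSTVWY"] * 3
        cons = column_relative_entropy(rows)
        assert np.allclose(cons.re, math.log2(20.0), atol=1e-12)
        assert np.allclose(cons.re_norm, 1.0)
        assert np.allclose(cons.entropy_norm, 0.0)

    def test_two_residue_column_against_skewed_background(self):
        # column {A: 1/2, V: 1/2}; background {A: 1/4, V: 3/4}
        cons = column_relative_entropy(["AV", "VV"])
        expected = 0.5 * math.log2(2.0) + 0.5 * math.log2(2.0 / 3.0)
        assert cons.re[0] == pytest.approx(expected, abs=1e-12)

    def test_all_gap_column_undefined(self):
        cons = column_relative_entropy(["A-C", "A-C", "V-C"])
        assert not cons.defined[1]
        assert cons.defined[0] and cons.defined[2]

    def test_single_row_rejected(self):
        with pytest.raises(MSAError):
            column_relative_entropy(["ACDEF"])


class TestRegionMean:
    def cons(self, entropies):
        re_norm = 1.0 - np.asarray(entropies, dtype=float)
        return ColumnConservation(re_norm * math.log2(20), re_norm,
                                  np.ones(len(entropies), dtype=bool))

    def test_equal_weights_give_arithmetic_mean(self):
        cons = self.cons([0.2, 0.4, 0.9])
        got = region_mean_entropy(cons, [0, 1, 2], [1.0, 1.0, 1.0])
        assert got == pytest.approx(0.5)

    def test_single_residue_region(self):
        cons = self.cons([0.37])
        assert region_mean_entropy(cons, [0], [0.8]) == pytest.approx(0.37)

    def test_weighted_mean(self):
        cons = self.cons([0.8, 0.4, 0.0])
        got = region_mean_entropy(cons, [0, 1, 2], [0.5, 0.25, 0.25])
        assert got == pytest.approx(0.5)

    def test_zero_weight_rejected(self):
        cons = self.cons([0.5])
        with pytest.raises(ValueError):
            region_mean_entropy(cons, [0], [0.0])


class TestInterfaceSurfaceRatio:
    def test_equal_entropies_zero(self):
        assert interface_surface_ratio(0.4, 0.4) == pytest.approx(0.0)

    def test_conserved_interface_negative(self):
        assert interface_surface_ratio(0.0, 1.0) == pytest.approx(
            math.log(0.5), abs=1e-12)

    def test_variable_interface_positive(self):
        assert interface_surface_ratio(1.0, 0.0) == pytest.approx(
            math.log(2.0), abs=1e-12)


class TestPValue:
    def test_is_below_null_range_gives_zero(self):
        x = np.linspace(-1, 1, 50)
        assert interface_p_value(-2.0, x) == 0.0
        assert interface_p_value(2.0, x) == 0.0

    def test_median_of_symmetric_null_near_half(self):
        x = np.random.default_rng(0).normal(0.0, 1.0, 1000)
        assert interface_p_value(0.0, x) == pytest.approx(0.5, abs=0.05)

    def test_agrees_with_dense_quadrature(self):
        x = np.random.default_rng(1).normal(0.0, 1.0, 400)
        is_value = 0.7
        p = interface_p_value(is_value, x)
        kde = gaussian_kde(x, bw_method="silverman")
        for lo, hi, side in ((x.min(), is_value, "left"),
                             (is_value, x.max(), "right")):
            grid = np.linspace(lo, hi, 20001)
            if side == "left":
                left = np.trapezoid(kde(grid), grid)
            else:
                right = np.trapezoid(kde(grid), grid)
        assert p == pytest.approx(min(left, right), abs=1e-3)

    def test_degenerate_null_convention(self):
        x = np.zeros(20)
        assert interface_p_value(0.0, x) == 1.0
        assert interface_p_value(0.1, x) == 0.0

    def test_small_null_rejected(self):
        with pytest.raises(ValueError):
            interface_p_value(0.0, np.arange(5))


class TestConservationScore:
    @pytest.mark.parametrize("is_v,p,expected", [
        (0.5, 1.0, 0.0),
        (-0.8, 0.0, -0.8),
        (-0.5, 0.2, -0.4),
    ])
    def test_arithmetic(self, is_v, p, expected):
        assert conservation_score(is_v, p) == pytest.approx(expected)

    def test_bad_p_rejected(self):
        with pytest.raises(ValueError):
            conservation_score(0.1, 1.5)


class TestThresholding:
    def test_retained_rows_monotone_and_query_kept(self):
        rows = make_msa(MSASpec(n_sequences=30, length=40,
                                interface_columns=(0, 1), seed=3))
        prev = None
        for t in np.arange(0.0, 1.0, 0.05):
            tm = threshold_msa(rows, float(t))
            assert tm.retained_rows[0] == rows[0][1]
            if prev is not None:
                assert len(tm.retained_rows) <= prev
            prev = len(tm.retained_rows)

    def test_identity_uses_mutually_aligned_columns(self):
        assert sequence_identity_to_query("ACDE", "AC-E") == pytest.approx(
            3.0 / 3.0)
        assert sequence_identity_to_query("ACDE", "ACVE") == pytest.approx(
            3.0 / 4.0)


class TestPatchNull:
    def test_fixed_seed_reproducible(self, dimer_context):
        ctx, _, _ = dimer_context
        cons = ColumnConservation(np.full(30, 1.0), np.full(30, 0.3),
                                  np.ones(30, dtype=bool))
        x1 = patch_null_distribution(ctx, cons, n_iter=50, seed=9)
        x2 = patch_null_distribution(ctx, cons, n_iter=50, seed=9)
        assert np.array_equal(x1, x2)

    def test_uniform_entropy_gives_zero_ratios(self, dimer_context):
        ctx, _, _ = dimer_context
        cons = ColumnConservation(np.full(30, 1.0), np.full(30, 0.42),
                                  np.ones(30, dtype=bool))
        x = patch_null_distribution(ctx, cons, n_iter=30, seed=1)
        assert np.allclose(x, 0.0, atol=1e-12)

    def test_single_residue_patches_match_enumeration(self, c2_dimer):
        from oligoqs.ppi_fingerprint import (_region_is,
                                             build_chain_context)
        first = c2_dimer.chains[0].residues[0].res_id
        ctx = build_chain_context(c2_dimer, "A",
                                  interface_residue_ids={first})
        rng_cons = np.random.default_rng(4)
        re_norm = rng_cons.uniform(0, 1, 30)
        cons = ColumnConservation(re_norm * math.log2(20), re_norm,
                                  np.ones(30, dtype=bool))
        sampled = patch_null_distribution(ctx, cons, n_iter=200, seed=2)
        enumerated = {
            round(_region_is(cons, ctx, [s],
                             [t for t in ctx.surface if t != s]), 12)
            for s in ctx.surface}
        assert {round(v, 12) for v in sampled} <= enumerated


class TestFingerprint:
    def test_curve_has_twenty_thresholds(self, dimer_context, c2_dimer):
        ctx, positions, length = dimer_context
        rows = make_msa(MSASpec(n_sequences=25, length=length,
                                interface_columns=positions, seed=8))
        fp = fingerprint(rows, ctx, seed=0, n_iter=40)
        assert len(fp.thresholds) == 20
        assert fp.thresholds[0] == 0.0 and fp.thresholds[-1] == 0.95
        assert len(fp.c_scores) == 20

    def test_conserved_interface_gives_negative_scores(self, dimer_context):
        # mutation-free interface columns, heavily randomized surface
        ctx, positions, length = dimer_context
        ladder = tuple(np.linspace(0.65, 0.25, 30))
        rows = make_msa(MSASpec(n_sequences=30, length=length,
                                interface_columns=positions,
                                r_i=0.0, r_s=1.0, identity_ladder=ladder,
                                seed=13))
        fp = fingerprint(rows, ctx, seed=1, n_iter=60)
        defined = [c for c in fp.c_scores if c is not None]
        assert defined and all(c < 0 for c in defined)
        assert fp.features["full_msa_value"] < 0

    def test_sparse_thresholds_undefined(self, dimer_context):
        ctx, positions, length = dimer_context
        rows = make_msa(MSASpec(n_sequences=8, length=length,
                                interface_columns=positions,
                                identity_ladder=(0.2,) * 8, seed=2))
        fp = fingerprint(rows, ctx, seed=0, n_iter=30)
        assert fp.c_scores[-1] is None       # nothing retained at 95%
        assert fp.c_scores[0] is not None    # full MSA defined

    def test_requires_interface(self, dimer_context, c2_dimer):
        from oligoqs.ppi_fingerprint import build_chain_context
        ctx = build_chain_context(c2_dimer, "A", interface_residue_ids=set())
        rows = make_msa(MSASpec(n_sequences=10, length=30, seed=1))
        with pytest.raises(ValueError):
            fingerprint(rows, ctx)


class TestCurveFeatures:
    def test_constant_curve(self):
        thresholds = tuple(round(0.05 * i, 2) for i in range(20))
        feats = curve_features(thresholds, [-0.3] * 20)
        assert feats["minimum"] == pytest.approx(-0.3)
        assert feats["absolute_maximum"] == pytest.approx(-0.3)
        assert feats["full_msa_value"] == pytest.approx(-0.3)
        assert feats["area"] == pytest.approx(-0.3 * 0.95)

    def test_absolute_maximum_keeps_sign(self):
        thresholds = (0.0, 0.05, 0.10)
        feats = curve_features(thresholds, [-0.9, 0.2, 0.1])
        assert feats["absolute_maximum"] == pytest.approx(-0.9)
        assert feats["minimum"] == pytest.approx(-0.9)

    def test_undefined_points_excluded(self):
        thresholds = (0.0, 0.05, 0.10, 0.15)
        feats = curve_features(thresholds, [-0.2, None, -0.4, None])
        assert feats["minimum"] == pytest.approx(-0.4)
        assert feats["area"] == pytest.approx(np.trapezoid([-0.2, -0.4],
                                                           [0.0, 0.10]))


def test_read_msa_fasta_and_a3m(tmp_path):
    fasta = tmp_path / "m.fasta"
    fasta.write_text(">q\nACDEF\n>s\nAC-EF\n")
    assert read_msa(fasta) == [("q", "ACDEF"), ("s", "AC-EF")]
    a3m = tmp_path / "m.a3m"
    a3m.write_text(">q\nACDEF\n>s\nACdefDEF\n")
    assert read_msa(a3m) == [("q", "ACDEF"), ("s", "ACDEF")]
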