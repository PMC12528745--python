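"""Unit and property tests for the IT2 T-S kernel-weight generator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gliofuzz as gf
from gliofuzz.fuzzy_weights import (
    SUPPORTED_KERNEL_SIZES,
    default_rulebase,
    kernel_from_gene,
    parameter_reduction,
)

# ---------------------------------------------------------------------------
# independent oracle: literal rule-by-rule scalar evaluation, written
# separately from the vectorized implementation it checks


def oracle_membership(x, peak, hw):
    return max(0.0, 1.0 - abs(x - peak) / hw)


ORACLE_TERMS = {"Low": 0.0, "Mid": 0.5, "High": 1.0}
ORACLE_RULES = {
    ("Low", "Low"): 0.25, ("Mid", "Low"): 0.50, ("High", "Low"): 0.75,
    ("Low", "Mid"): 0.75, ("Mid", "Mid"): 0.50, ("High", "Mid"): 0.25,
    ("Low", "High"): 0.75, ("Mid", "High"): 0.25, ("High", "High"): 0.75,
}


def oracle_infer(numin, code, h=0.5, delta=0.1):
    num = den = 0.0
    for (t_in, t_code), y in ORACLE_RULES.items():
        fl = min(
            oracle_membership(numin, ORACLE_TERMS[t_in], h - delta),
            oracle_membership(code, ORACLE_TERMS[t_code], h - delta),
        )
        fu = min(
            oracle_membership(numin, ORACLE_TERMS[t_in], h + delta),
            oracle_membership(code, ORACLE_TERMS[t_code], h + delta),
        )
        strength = 0.5 * (fl + fu)
        num += strength * y
        den += strength
    return num / den


# ---------------------------------------------------------------------------
# membership functions


class TestMembership:
    def test_peak_membership_is_one_for_both_bounds(self):
        mf = gf.IT2Triangular(peak=0.3, upper_halfwidth=0.6, lower_halfwidth=0.4)
        assert gf.membership_interval(0.3, mf) == (1.0, 1.0)

    def test_outside_support_is_zero(self):
        mf = gf.IT2Triangular(peak=0.5, upper_halfwidth=0.6, lower_halfwidth=0.4)
        assert gf.membership_interval(0.5 + 0.61, mf) == (0.0, 0.0)

    def test_interior_point_frozen_values(self):
        # triangle formula at x=0.8: lower 1-0.3/0.4, upper 1-0.3/0.6
        mf = gf.IT2Triangular(peak=0.5, upper_halfwidth=0.6, lower_halfwidth=0.4)
        lower, upper = gf.membership_interval(0.8, mf)
        assert lower == pytest.approx(0.25, abs=1e-12)
        assert upper == pytest.approx(0.5, abs=1e-12)

    def test_lower_bound_never_exceeds_upper(self):
        xs = np.linspace(0, 1, 501)
        for mf in default_rulebase().terms.values():
            lower, upper = mf.membership(xs)
            assert np.all(lower <= upper + 1e-15)
            assert np.all((0 <= lower) & (upper <= 1))

    def test_rejects_non_finite_input(self):
        mf = gf.IT2Triangular(peak=0.5, upper_halfwidth=0.6, lower_halfwidth=0.4)
        with pytest.raises(ValueError, match="finite"):
            mf.membership(np.nan)

    def test_degenerate_fou_rejected(self):
        with pytest.raises(ValueError):
            gf.IT2Triangular(peak=0.5, upper_halfwidth=0.4, lower_halfwidth=0.4)


# ---------------------------------------------------------------------------
# inference


class TestInference:
    def test_matches_independent_oracle_on_grid(self):
        for numin in np.linspace(0, 1, 11):
            for code in np.linspace(0, 1, 11):
                assert gf.infer_pattern(numin, code) == pytest.approx(
                    oracle_infer(numin, code), abs=1e-12
                )

    def test_central_point_value(self):
        # the rule base has more High than Low consequents, so the central
        # point sits slightly above the Mid consequent: 0.5125 exactly
        s = gf.infer_pattern(0.5, 0.5)
        assert s == pytest.approx(oracle_infer(0.5, 0.5), abs=1e-12)
        assert s == pytest.approx(0.5125, abs=1e-12)

    def test_origin_dominated_by_low_rule(self):
        s = gf.infer_pattern(0.0, 0.0)
        assert 0.25 < s <= 0.5
        assert s == pytest.approx(oracle_infer(0.0, 0.0), abs=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(
        numin=st.floats(0, 1, allow_nan=False),
        code=st.floats(0, 1, allow_nan=False),
    )
    def test_output_is_convex_combination_of_consequents(self, numin, code):
        assert 0.25 <= gf.infer_pattern(numin, code) <= 0.75

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            gf.infer_pattern(1.2, 0.5)

    def test_rulebase_config_roundtrip(self):
        rb = default_rulebase()
        rb2 = gf.FuzzyRuleBase.from_config(rb.to_config())
        assert gf.infer_pattern(0.37, 0.81, rb2) == gf.infer_pattern(0.37, 0.81, rb)

    def test_rulebase_must_cover_all_antecedents(self):
        bad = (default_rulebase().rules[:8] + ((("Low", "Low"), "M"),))
        with pytest.raises(ValueError, match="antecedent"):
            gf.FuzzyRuleBase(rules=bad)


# ---------------------------------------------------------------------------
# weighting function


class TestWeightingFunc:
    def test_zero_w_gives_all_three(self):
        kw = gf.weighting_func(gf.FilterGene(w=0.0, code=0.42), 27)
        np.testing.assert_allclose(kw.values, 3.0)

    @pytest.mark.parametrize("n", sorted(SUPPORTED_KERNEL_SIZES))
    def test_output_length_matches_requested_size(self, n):
        kw = gf.weighting_func(gf.FilterGene(w=0.6, code=0.3), n)
        assert kw.values.shape == (n,)

    def test_gene_size_constant_across_kernel_sizes(self):
        # extending 3x3 -> 7x7 never grows the gene: still two scalars
        gene = gf.FilterGene(w=0.5, code=0.5)
        for n in (9, 25, 49):
            gf.weighting_func(gene, n)
        assert len(gene.__dataclass_fields__) == 2

    def test_composition_matches_oracle(self):
        gene = gf.FilterGene(w=0.5, code=0.5)
        kw = gf.weighting_func(gene, 9)
        expected = [
            3.0 * np.cos(np.pi * 0.5 * oracle_infer((i + 0.5) / 9, 0.5))
            for i in range(9)
        ]
        np.testing.assert_allclose(kw.values, expected, atol=1e-12)

    def test_unsupported_size_rejected(self):
        with pytest.raises(ValueError, match="unsupported"):
            gf.weighting_func(gf.FilterGene(0.5, 0.5), 10)

    def test_deterministic_bitwise(self):
        gene = gf.FilterGene(w=0.123456, code=0.654321)
        a = gf.weighting_func(gene, 27).values
        b = gf.weighting_func(gene, 27).values
        assert a.tobytes() == b.tobytes()

    def test_bound_holds_over_many_random_genes(self):
        # |W_i| = |3 cos(.)| <= 3 for 10,000 random genes
        rng = np.random.default_rng(0)
        genes = rng.random((10_000, 2))
        positions = (np.arange(27) + 0.5) / 27
        worst = 0.0
        for w, code in genes:
            win = gf.infer_pattern(positions, code)
            worst = max(worst, np.max(np.abs(3 * np.cos(np.pi * w * win))))
        assert worst <= 3.0 + 1e-12

    def test_monotone_in_w_at_largest_pattern_position(self):
        # cos is decreasing on [0, pi], so growing w never increases W at
        # the position with the largest inferred pattern value
        for code in (0.0, 0.3, 0.7, 1.0):
            positions = (np.arange(27) + 0.5) / 27
            win = gf.infer_pattern(positions, code)
            i_max = int(np.argmax(win))
            ws = np.linspace(0, 1, 21)
            values = [
                gf.weighting_func(gf.FilterGene(w, code), 27).values[i_max]
                for w in ws
            ]
            assert np.all(np.diff(values) <= 1e-12)

    def test_gene_clamped_on_construction(self):
        g = gf.FilterGene(w=1.7, code=-0.3)
        assert g.w == 1.0 and g.code == 0.0


# ---------------------------------------------------------------------------
# kernel bank


class TestKernelBank:
    def test_untied_bank_counts(self):
        spec = gf.NetworkSpec()
        rng = np.random.default_rng(1)
        genes = [
            [gf.FilterGene(*rng.random(2)) for _ in range(c)] for c in spec.channels
        ]
        bank = gf.build_kernel_bank(genes, spec)
        assert bank.n_kernels == 8 + 16 + 32 + 64 + 128
        assert all(
            layer.shape == (c, 3, 3, 3)
            for layer, c in zip(bank.layers, spec.channels)
        )

    def test_layer_tied_five_genes_fill_bank(self):
        spec = gf.NetworkSpec()
        genes = [[gf.FilterGene(0.2 * i, 0.5)] for i in range(5)]
        bank = gf.build_kernel_bank(genes, spec)
        assert bank.n_kernels == sum(spec.channels)
        for layer in bank.layers:  # all filters in a layer share the kernel
            assert np.ptp(layer, axis=0).max() == 0.0

    def test_every_coefficient_bounded(self, tied_bank_relu):
        bank, _ = tied_bank_relu
        for layer in bank.layers:
            assert np.max(np.abs(layer)) <= 3.0 + 1e-12

    def test_gene_count_mismatch_rejected(self):
        spec = gf.NetworkSpec()
        genes = [[gf.FilterGene(0.5, 0.5)] * 3] + [[gf.FilterGene(0.5, 0.5)]] * 4
        with pytest.raises(ValueError, match="3 genes"):
            gf.build_kernel_bank(genes, spec)


def test_parameter_reduction_for_default_kernel():
    # 27-coefficient kernel driven by 2 scalars: 92.59...% -> 92.6%
    assert parameter_reduction(27) == pytest.approx((27 - 2) / 27)
    assert round(100 * parameter_reduction(27), 1) == 92.6


def test_kernel_from_gene_shapes():
    k = kernel_from_gene(gf.FilterGene(0.4, 0.6), (3, 3, 3))
    assert k.shape == (3, 3, 3)
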