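from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cistrans import regmech
from cistrans.regmech import (classify_regulatory_mechanism,
                              classify_inheritance, regulatory_ratios,
                              trans_contribution_test, CATEGORIES)


def fisher_enumeration(a, b, c, d):
    """Exact two-sided Fisher p by big-integer enumeration over the
    hypergeometric support (sums probabilities <= that of the observed
    table)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c1 - a), denom)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        if pk <= p_obs:
            total += pk
    return float(total)


class TestRegulatoryRatios:
    def test_hybrid_ratio_with_pseudocount(self):
        h, p, l2h, l2p = regulatory_ratios(60, 30, 100, 100)
        assert h == pytest.approx(60.5 / 30.5)
        assert l2h == pytest.approx(np.log2(60.5 / 30.5))
        assert p == pytest.approx(1.0)
        assert l2p == pytest.approx(0.0)

    def test_zero_maternal_counts_finite(self):
        h, _, l2h, _ = regulatory_ratios(0, 20, 50, 50)
        assert h == pytest.approx(0.5 / 20.5)
        assert np.isfinite(l2h) and l2h < 0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            regulatory_ratios(-1, 5, 5, 5)


class TestTransContributionTest:
    def test_identical_ratios_p_one(self):
        assert trans_contribution_test(50, 50, 50, 50) == pytest.approx(1.0)

    def test_discordant_ratios_significant(self):
        p = trans_contribution_test(80, 20, 50, 50)
        assert p == pytest.approx(fisher_enumeration(80, 20, 50, 50),
                                  abs=1e-10)
        assert p < 0.05

    def test_concordant_ratios_not_significant(self):
        p = trans_contribution_test(20, 10, 200, 100)
        assert p == pytest.approx(fisher_enumeration(20, 10, 200, 100),
                                  abs=1e-10)
        assert p >= 0.05

    def test_zero_margin_convention(self):
        assert trans_contribution_test(0, 0, 50, 50) == 1.0
        assert trans_contribution_test(0, 10, 0, 20) == 1.0

    def test_matches_enumeration_on_random_tables(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 501))
            cuts = sorted(rng.integers(0, n + 1, size=3))
            a, b, c = cuts[0], cuts[1] - cuts[0], cuts[2] - cuts[1]
            d = n - a - b - c
            p = trans_contribution_test(a, b, c, d)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                assert p == 1.0
            else:
                assert p == pytest.approx(fisher_enumeration(a, b, c, d),
                                          abs=1e-10)


class TestClassifyMechanism:
    def case(self, de, flags, t_p, l2h, l2p, **kw):
        return classify_regulatory_mechanism(de, flags, t_p, l2h, l2p, **kw)

    def test_cis_pattern(self):
        # DE, ASE in all hybrids, no trans contribution
        assert self.case(True, [True, True, True], 0.8, 1.0, 1.1) == "cis"

    def test_trans_pattern(self):
        assert self.case(True, [False, False, False], 0.001, 0.0, 1.2) == \
            "trans"

    def test_conserved_pattern(self):
        assert self.case(False, [False, False, False], 0.9, 0.0, 0.0) == \
            "conserved"

    def test_compensatory_opposing_signs(self):
        assert self.case(False, [True, True, True], 0.001, 1.2, -0.8) == \
            "cis_x_trans"

    def test_reinforcing_same_signs(self):
        assert self.case(False, [True, True, True], 0.001, 1.2, 0.8) == \
            "cis_plus_trans"

    def test_sign_deadzone_falls_to_ambiguous(self):
        assert self.case(False, [True, True, True], 0.001, 1.2, 0.03) == \
            "ambiguous"

    def test_de_with_ase_and_trans_ambiguous(self):
        assert self.case(True, [True, True, True], 0.001, 1.0, 1.0) == \
            "ambiguous"

    def test_partial_ase_is_not_no_ase_by_default(self):
        # one of three hybrids significant: neither "ASE" nor "no ASE"
        # under the complement rule -> cannot be trans
        assert self.case(True, [True, False, False], 0.001, 0.5, 1.0) == \
            "trans"
        assert self.case(True, [True, False, False], 0.001, 0.5, 1.0,
                         ase_none_rule="no_hybrid") == "ambiguous"

    def test_cross_direction_symmetry(self):
        """Swapping maternal/paternal roles negates both log ratios and
        preserves the category."""
        cases = [
            (True, [True] * 3, 0.8, 1.0, 1.1),
            (True, [False] * 3, 0.001, 0.0, 1.2),
            (False, [True] * 3, 0.001, 1.2, -0.8),
            (False, [True] * 3, 0.001, 1.2, 0.8),
            (False, [False] * 3, 0.9, 0.0, 0.0),
        ]
        for de, flags, t_p, l2h, l2p in cases:
            assert self.case(de, flags, t_p, l2h, l2p) == \
                self.case(de, flags, t_p, -l2h, -l2p)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.booleans(),
           st.lists(st.booleans(), min_size=1, max_size=4),
           st.floats(min_value=0, max_value=1),
           st.floats(min_value=-3, max_value=3),
           st.floats(min_value=-3, max_value=3))
    def test_every_gene_gets_exactly_one_category(self, de, flags, t_p,
                                                  l2h, l2p):
        cat = self.case(de, flags, t_p, l2h, l2p)
        assert cat in CATEGORIES


class TestClassifyInheritance:
    def test_additive(self):
        call = classify_inheritance(True, True, True, 150, 100, 200)
        assert call.mode == "additive"

    def test_dominant_toward_maternal(self):
        # indistinguishable from the maternal parent, differs from paternal
        call = classify_inheritance(True, False, True, 105, 100, 200,
                                    maternal_population="molluscivore",
                                    paternal_population="scale-eater")
        assert call.mode == "dominant"
        assert call.dominant_toward == "molluscivore"

    def test_overdominant(self):
        call = classify_inheritance(False, True, True, 300, 100, 200)
        assert call.mode == "overdominant"

    def test_underdominant(self):
        call = classify_inheritance(False, True, True, 50, 100, 200)
        assert call.mode == "underdominant"

    def test_undetermined_when_nothing_significant(self):
        call = classify_inheritance(False, False, False, 150, 100, 200)
        assert call.mode == "undetermined"

    def test_transgressive_precedence_over_dominant(self):
        # hybrid above both parents: overdominant even though it also
        # differs from only... both contrasts significant here
        call = classify_inheritance(True, True, True, 400, 100, 200)
        assert call.mode == "overdominant"

    def test_midparent_hybrid_differing_from_both_is_additive(self):
        call = classify_inheritance(True, True, True, 150, 100, 200)
        assert call.mode == "additive"


class TestRecoveryOnTinyDataset:
    def test_classifier_recovers_planted_regimes(self, tiny_pipeline_result):
        res, _, _ = tiny_pipeline_result
        truth = res.table("truth")
        reg = res.table("regulatory_calls")
        m = reg.merge(truth, on="gene_id")
        cis = m[m["regime"] == "cis"]
        trans = m[m["regime"] == "trans"]
        cons = m[m["regime"] == "conserved"]
        assert (cis["category"] == "cis").mean() >= 0.9
        assert (trans["category"] == "trans").mean() >= 0.9
        divergent = cons["category"].isin(
            ["cis", "trans", "cis_x_trans", "cis_plus_trans"])
        assert divergent.mean() <= 0.05
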