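import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cistrans.config import FilterConfig
from cistrans.formats_io import (SVCallSet, HOM_REF, HET, HOM_ALT, MISSING)
from cistrans import popgen
from .conftest import make_matrix

R = HOM_REF
H = HET
A = HOM_ALT
M = MISSING


def site_fst(genotypes, populations):
    m = make_matrix([genotypes], populations)
    return popgen.wc_fst_site(None, matrix=m, index=0)


class TestWcFstSite:
    def test_complete_fixation(self):
        d = site_fst([A, A, A, A, R, R, R, R], ["p1"] * 4 + ["p2"] * 4)
        assert d.fst == pytest.approx(1.0)
        assert d.is_fixed

    def test_identical_populations_nonpositive(self):
        g = [R, H, H, A, R, H, H, A]
        d = site_fst(g, ["p1"] * 4 + ["p2"] * 4)
        assert d.fst <= 0
        assert not d.is_fixed

    def test_hand_evaluated_components(self):
        # p1 = 0.8 (3 hom-alt, 2 het), p2 = 0.2 (mirror); independently
        # evaluated from the variance-component formulas by hand:
        # a = 0.165, b = -0.025, c = 0.2 -> theta = 0.165/0.34
        g = [A, A, A, H, H, R, R, R, H, H]
        d = site_fst(g, ["p1"] * 5 + ["p2"] * 5)
        assert d.p1 == pytest.approx(0.8)
        assert d.p2 == pytest.approx(0.2)
        assert d.fst == pytest.approx(0.165 / 0.34, abs=1e-12)

    def test_small_population_undefined(self):
        d = site_fst([A, M, M, M, R, R, R, R], ["p1"] * 4 + ["p2"] * 4)
        assert np.isnan(d.fst)

    def test_negative_theta_not_clamped(self):
        g = [R, H, H, A, R, H, H, A]
        d = site_fst(g, ["p1"] * 4 + ["p2"] * 4)
        assert d.fst < 0


@settings(deadline=None, max_examples=300, derandomize=True)
@given(st.lists(st.integers(min_value=-1, max_value=2),
                min_size=8, max_size=8))
def test_theta_one_iff_fixed(gts):
    """theta-hat = 1 exactly when the site is a fixed difference."""
    pops = ["p1"] * 4 + ["p2"] * 4
    g1, g2 = gts[:4], gts[4:]
    if sum(g != M for g in g1) < 2 or sum(g != M for g in g2) < 2:
        return
    d = site_fst(gts, pops)
    called1 = [g for g in g1 if g != M]
    called2 = [g for g in g2 if g != M]
    brute_fixed = ((all(g == R for g in called1) and all(g == A for g in called2))
                   or (all(g == A for g in called1) and all(g == R for g in called2)))
    assert d.is_fixed == brute_fixed
    if brute_fixed:
        assert d.fst == pytest.approx(1.0)
    elif np.isfinite(d.fst):
        assert not np.isclose(d.fst, 1.0)


class TestDetectFixedSnps:
    def test_single_het_vetoes(self):
        m = make_matrix([[A, A, A, H, R, R, R, R]], ["p1"] * 4 + ["p2"] * 4)
        assert popgen.detect_fixed_snps(m) == []

    def test_partial_call_rate_still_fixed(self):
        # 60% called in pop1, all hom-alt; pop2 all hom-ref
        m = make_matrix([[A, A, A, M, M, R, R, R, R, R]],
                        ["p1"] * 5 + ["p2"] * 5)
        fixed = popgen.detect_fixed_snps(m)
        assert len(fixed) == 1 and fixed[0].is_fixed

    def test_matches_bruteforce_on_random_matrices(self, rng):
        pops = ["p1"] * 5 + ["p2"] * 5
        for _ in range(20):
            gt = rng.integers(-1, 3, size=(40, 10)).astype(np.int8)
            m = make_matrix(gt, pops)
            got = {s.position for s in popgen.detect_fixed_snps(m)}
            expected = set()
            for i in range(40):
                c1 = [g for g in gt[i, :5] if g != M]
                c2 = [g for g in gt[i, 5:] if g != M]
                if not c1 or not c2:
                    continue
                if (all(g == R for g in c1) and all(g == A for g in c2)) or \
                   (all(g == A for g in c1) and all(g == R for g in c2)):
                    expected.add(int(m.sites["position"].iloc[i]))
            assert got == expected


def brute_force_dxy(p1, p2):
    """Mean pairwise difference between inter-population haplotypes drawn
    from the allele-frequency model."""
    total = 0.0
    for a1, pr1 in ((1, p1), (0, 1 - p1)):
        for a2, pr2 in ((1, p2), (0, 1 - p2)):
            total += pr1 * pr2 * (a1 != a2)
    return total


class TestWindowDivergence:
    def test_balanced_site(self):
        m = make_matrix([[H, H, H, H, H, H, H, H]], ["p1"] * 4 + ["p2"] * 4)
        wins = popgen.window_divergence(m, window_bp=10_000)
        assert len(wins) == 1
        assert wins[0].dxy == pytest.approx(0.5)
        assert wins[0].fst_window <= 0.01

    def test_fixed_site(self):
        m = make_matrix([[A, A, A, A, R, R, R, R]], ["p1"] * 4 + ["p2"] * 4)
        wins = popgen.window_divergence(m, window_bp=10_000)
        assert wins[0].dxy == pytest.approx(1.0)
        assert wins[0].fst_window == pytest.approx(1.0)

    def test_dxy_matches_haplotype_enumeration(self):
        # three sites with p-vectors (0.9,0.1), (0.5,0.5), (1.0,0.0);
        # pop size 10 so the frequencies are exact
        rows = [
            [A] * 4 + [H] * 2 + [R] * 4 + [R] * 9 + [H],  # wrong sizes guard
        ]
        # build genotypes giving exactly those frequencies over 5 diploids
        def geno(p):
            n_alt = round(p * 10)
            g = [A] * (n_alt // 2) + [H] * (n_alt % 2)
            g += [R] * (5 - len(g))
            return g

        sites = [(0.9, 0.1), (0.5, 0.5), (1.0, 0.0)]
        rows = [geno(p1) + geno(p2) for p1, p2 in sites]
        m = make_matrix(rows, ["p1"] * 5 + ["p2"] * 5,
                        positions=[100, 200, 300])
        wins = popgen.window_divergence(m, window_bp=10_000)
        expected = np.mean([brute_force_dxy(p1, p2) for p1, p2 in sites])
        assert wins[0].dxy == pytest.approx(expected, abs=1e-12)
        assert wins[0].n_sites == 3

    def test_invariant_to_population_swap_and_order(self, rng):
        gt = rng.integers(-1, 3, size=(30, 10)).astype(np.int8)
        pops = ["p1"] * 5 + ["p2"] * 5
        m = make_matrix(gt, pops)
        w1 = popgen.windows_to_frame(popgen.window_divergence(m, window_bp=5000))
        # swap population labels
        m2 = make_matrix(gt, ["p2"] * 5 + ["p1"] * 5)
        w2 = popgen.windows_to_frame(popgen.window_divergence(m2, window_bp=5000))
        pd.testing.assert_series_equal(w1["dxy"], w2["dxy"])
        # permute individuals within populations
        perm = np.concatenate([rng.permutation(5), 5 + rng.permutation(5)])
        m3 = make_matrix(gt[:, perm], pops)
        w3 = popgen.windows_to_frame(popgen.window_divergence(m3, window_bp=5000))
        pd.testing.assert_frame_equal(w1, w3)

    def test_windows_tile_from_one(self):
        m = make_matrix([[H] * 8, [H] * 8], ["p1"] * 4 + ["p2"] * 4,
                        positions=[500, 15_000])
        wins = popgen.window_divergence(m, window_bp=10_000)
        assert [(w.start, w.end) for w in wins] == [(1, 10_000),
                                                    (10_001, 20_000)]


# ---------------------------------------------------------------------------
# structural variants


def make_call_set(source, records, genotypes, samples):
    recs = pd.DataFrame(records, columns=["scaffold", "start", "end",
                                          "sv_type", "length"])
    return SVCallSet(source, recs, np.asarray(genotypes, dtype=np.int8),
                     list(samples))


SAMPLES = ["A1", "A2", "A3", "A4", "B1", "B2", "B3", "B4"]
POPS = {s: s[0] for s in SAMPLES}


def del_record(start, end):
    return ("scaf1", start, end, "DEL", end - start + 1)


class TestFixedStructuralVariants:
    def test_fixed_deletion_across_all_call_sets(self, filters):
        gts = [[R, R, R, R, A, A, A, A]]
        sets = [make_call_set(f"cs{i}", [del_record(1000, 2255)], gts,
                              SAMPLES) for i in range(4)]
        fixed = popgen.fixed_structural_variants(sets, POPS, filters)
        assert len(fixed) == 1
        assert fixed[0].sv_type == "DEL"

    def test_one_carrier_short_not_fixed(self, filters):
        gts = [[R, R, R, R, A, A, A, R]]  # 3 of 4 B carriers
        sets = [make_call_set(f"cs{i}", [del_record(1000, 2255)], gts,
                              SAMPLES) for i in range(2)]
        assert popgen.fixed_structural_variants(sets, POPS, filters) == []

    def test_missing_from_one_call_set_not_fixed(self, filters):
        gts = [[R, R, R, R, A, A, A, A]]
        sets = [make_call_set(f"cs{i}", [del_record(1000, 2255)], gts,
                              SAMPLES) for i in range(3)]
        sets.append(make_call_set("cs3", [], np.empty((0, 8)), SAMPLES))
        assert popgen.fixed_structural_variants(sets, POPS, filters) == []

    def test_offset_breakpoints_matched(self, filters):
        gts = [[R, R, R, R, A, A, A, A]]
        s1 = make_call_set("cs0", [del_record(1000, 1500)], gts, SAMPLES)
        s2 = make_call_set("cs1", [del_record(1010, 1510)], gts, SAMPLES)
        # offset 10 bp, reciprocal overlap 491/501 ~ 0.98
        fixed = popgen.fixed_structural_variants([s1, s2], POPS, filters)
        assert len(fixed) == 1

    def test_call_set_order_invariance(self, filters, rng):
        sets = []
        base_gts = [[R, R, R, R, A, A, A, A],
                    [R, H, R, R, A, A, R, A],
                    [A, A, A, A, R, R, R, R]]
        records = [del_record(1000, 1500), del_record(5000, 5400),
                   del_record(9000, 9800)]
        for i in range(4):
            sets.append(make_call_set(f"cs{i}", records, base_gts, SAMPLES))
        fwd = popgen.fixed_structural_variants(sets, POPS, filters)
        rev = popgen.fixed_structural_variants(sets[::-1], POPS, filters)
        assert [(v.scaffold, v.start, v.end) for v in fwd] == \
               [(v.scaffold, v.start, v.end) for v in rev]
        assert len(fwd) == 2  # both oppositely fixed records qualify

    def test_unknown_sample_fails(self, filters):
        cs = make_call_set("cs0", [del_record(1, 100)],
                           [[R] * 8], SAMPLES)
        with pytest.raises(ValueError, match="unknown sample"):
            popgen.fixed_structural_variants([cs], {"A1": "A"}, filters)

    def test_matching_equals_bruteforce_pairs(self, filters, rng):
        """Greedy clustering agrees with exhaustive pairwise matching on a
        toy two-call-set instance."""
        starts = sorted(rng.choice(np.arange(1000, 100_000, 700), size=15,
                                   replace=False))
        records0, records1 = [], []
        for s in starts:
            length = int(rng.integers(80, 600))
            records0.append(del_record(int(s), int(s) + length - 1))
            jit = int(rng.integers(-8, 9))
            records1.append(del_record(int(s) + jit, int(s) + jit + length - 1))
        gts = [[R, R, R, R, A, A, A, A]] * 15
        s0 = make_call_set("cs0", records0, gts, SAMPLES)
        s1 = make_call_set("cs1", records1, gts, SAMPLES)
        clusters = popgen.match_sv_records(
            [s0, s1], filters.sv_breakpoint_tol,
            filters.sv_min_reciprocal_overlap)
        pairs = {tuple(sorted(c)) for c in clusters if len(c) == 2}
        expected = set()
        for i, r0 in enumerate(records0):
            for j, r1 in enumerate(records1):
                if popgen._sv_match((r0[0], r0[1], r0[2], r0[3]),
                                    (r1[0], r1[1], r1[2], r1[3]),
                                    filters.sv_breakpoint_tol,
                                    filters.sv_min_reciprocal_overlap):
                    expected.add(((0, i), (1, j)))
        assert pairs == expected
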