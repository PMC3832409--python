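"""Locus statistics, exact HWE, D' linkage, X-linkage and panel selection."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from ursa.panel_stats import (
    GenotypeMatrix,
    LocusStats,
    MonomorphicLocusError,
    PanelSpec,
    assign_mtdna_haplotype,
    detect_x_linked,
    determine_sex,
    dprime_from_codes,
    flag_linked_pairs,
    hwe_exact,
    ld_dprime,
    locus_stats,
    select_panel,
    x_typeI_error,
)
from ursa.simulate import SimConfig, make_pedigree_panel, simulate_ld_pair


def small_matrix(calls: dict, sex=None, classes=None):
    df = pd.DataFrame(calls)
    sex = sex or {i: "unknown" for i in df.index}
    classes = classes or {l: "autosomal" for l in df.columns}
    return GenotypeMatrix(df, sex, classes)


class TestGenotypeMatrix:
    def test_diploid_call_at_haploid_locus_rejected(self):
        with pytest.raises(ValueError, match="haploid"):
            small_matrix(
                {"mt1": {"i1": "AB"}}, classes={"mt1": "mtDNA"}
            )

    def test_heterozygous_male_x_rejected(self):
        with pytest.raises(ValueError, match="male"):
            small_matrix(
                {"x1": {"i1": "AB"}},
                sex={"i1": "M"},
                classes={"x1": "X"},
            )

    def test_invalid_call_named(self):
        with pytest.raises(ValueError, match="i1"):
            small_matrix({"l1": {"i1": "AC"}})


class TestLocusStats:
    def test_hand_counts(self):
        m = small_matrix({"l1": {"i1": "AA", "i2": "AB", "i3": "BB"}})
        s = locus_stats(m, "l1")
        assert (s.p, s.maf, s.He) == (0.5, 0.5, 0.5)
        assert s.Ho == pytest.approx(1 / 3)
        assert s.n_called == 3

    def test_monomorphic(self):
        m = small_matrix({"l1": {"i1": "AA", "i2": "AA"}})
        s = locus_stats(m, "l1")
        assert (s.maf, s.Ho, s.He) == (0, 0, 0)

    def test_haploid_calls_pool_single_alleles(self):
        m = small_matrix(
            {"l1": {"i1": "A", "i2": "B", "i3": "A", "i4": "A"}},
            classes={"l1": "mtDNA"},
        )
        s = locus_stats(m, "l1")
        assert s.p == 0.75 and s.maf == 0.25 and s.Ho == 0.0

    def test_all_missing_rejected(self):
        m = small_matrix({"l1": {"i1": "--", "i2": "--"}})
        with pytest.raises(ValueError):
            locus_stats(m, "l1")

    def test_random_matrix_matches_counting_oracle(self, rng):
        for _ in range(20):
            codes = rng.integers(0, 3, size=12)
            calls = {"l": {f"i{k}": ["BB", "AB", "AA"][c] for k, c in enumerate(codes)}}
            s = locus_stats(small_matrix(calls), "l")
            nA = sum(codes)
            fA = nA / 24
            assert s.maf == pytest.approx(min(fA, 1 - fA))
            assert s.Ho == pytest.approx((codes == 1).mean())
            assert s.He == pytest.approx(2 * fA * (1 - fA))

    def test_maf_he_invariant_random(self, rng):
        for _ in range(50):
            codes = rng.integers(0, 3, size=20)
            calls = {"l": {f"i{k}": ["BB", "AB", "AA"][c] for k, c in enumerate(codes)}}
            s = locus_stats(small_matrix(calls), "l")
            assert 0 <= s.maf <= 0.5
            assert s.He == pytest.approx(2 * s.maf * (1 - s.maf))


def hwe_exact_fraction_oracle(nAA: int, nAB: int, nBB: int) -> float:
    """Independent oracle with exact rational arithmetic.

    P(nAB | n, nA) = [n! / (nAA! nAB! nBB!)] 2^nAB nA! nB! / (2n)! computed
    as exact Fractions from integer combinatorics.
    """
    from math import factorial

    n = nAA + nAB + nBB
    nA, nB = 2 * nAA + nAB, 2 * nBB + nAB

    def prob(nab):
        naa, nbb = (nA - nab) // 2, (nB - nab) // 2
        return Fraction(
            factorial(n) * 2**nab * factorial(nA) * factorial(nB),
            factorial(naa) * factorial(nab) * factorial(nbb) * factorial(2 * n),
        )

    probs = {nab: prob(nab) for nab in range(nA % 2, min(nA, nB) + 1, 2)}
    obs = probs[nAB]
    return float(sum(p for p in probs.values() if p <= obs))


class TestHweExact:
    def test_monomorphic_p_one(self):
        assert hwe_exact(10, 0, 0) == 1.0

    def test_two_heterozygotes_enumeration(self):
        # 2 A and 2 B alleles over 2 individuals: nAB in {0, 2} with
        # P(2) = 2/3, P(0) = 1/3; observed 2 -> p = 1
        assert hwe_exact(0, 2, 0) == pytest.approx(1.0)
        assert hwe_exact(1, 0, 1) == pytest.approx(1 / 3)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact(-1, 2, 3)

    def test_matches_exact_rational_oracle(self, rng):
        for _ in range(50):
            nAA, nAB, nBB = (int(x) for x in rng.integers(0, 11, size=3))
            if nAA + nAB + nBB == 0:
                continue
            assert hwe_exact(nAA, nAB, nBB) == pytest.approx(
                hwe_exact_fraction_oracle(nAA, nAB, nBB), rel=1e-9
            )

    def test_p_values_approximately_uniform_under_hwe(self, rng):
        # simulated HWE genotypes: the discrete exact test is conservative,
        # so the rejection rate at alpha=0.05 should sit near/below 0.05
        n, maf, n_loci = 50, 0.3, 2000
        g = rng.binomial(2, maf, size=(n_loci, n))
        pvals = np.array(
            [hwe_exact(int((row == 2).sum()), int((row == 1).sum()), int((row == 0).sum()))
             for row in g]
        )
        frac = (pvals <= 0.05).mean()
        assert abs(frac - 0.05) < 0.03


class TestDprime:
    def test_duplicated_locus_perfect_linkage(self, rng):
        g = rng.binomial(2, 0.4, size=100)
        assert dprime_from_codes(g, g.copy()) == pytest.approx(1.0)

    def test_independent_loci_near_zero(self, rng):
        ga, gb = simulate_ld_pair(500, 0.6, 0.55, 0.0, rng)
        assert dprime_from_codes(ga, gb) < 0.15

    def test_planted_dprime_recovered(self, rng):
        ga, gb = simulate_ld_pair(500, 0.6, 0.55, 0.9, rng)
        assert dprime_from_codes(ga, gb) == pytest.approx(0.9, abs=0.05)

    def test_monomorphic_signalled(self):
        with pytest.raises(MonomorphicLocusError):
            dprime_from_codes(np.full(50, 2), np.array([0, 1, 2] * 17)[:50])

    def test_matrix_wrapper(self, rng):
        g = rng.binomial(2, 0.5, size=60)
        calls = {
            "l1": {f"i{k}": ["BB", "AB", "AA"][c] for k, c in enumerate(g)},
            "l2": {f"i{k}": ["BB", "AB", "AA"][c] for k, c in enumerate(g)},
        }
        assert ld_dprime(small_matrix(calls), "l1", "l2") == pytest.approx(1.0)


class TestFlagLinkedPairs:
    def test_duplicated_locus_flagged(self, rng):
        g = rng.binomial(2, 0.4, size=80)
        other = rng.binomial(2, 0.5, size=80)
        calls = {
            name: {f"i{k}": ["BB", "AB", "AA"][c] for k, c in enumerate(col)}
            for name, col in [("l1", g), ("l2", g), ("l3", other)]
        }
        flagged = flag_linked_pairs(small_matrix(calls), threshold=1.0)
        assert [(a, b) for a, b, _ in flagged] == [("l1", "l2")]

    def test_independent_loci_unflagged(self, rng):
        cols = {f"l{j}": rng.binomial(2, 0.5, size=300) for j in range(4)}
        calls = {
            name: {f"i{k}": ["BB", "AB", "AA"][c] for k, c in enumerate(col)}
            for name, col in cols.items()
        }
        assert flag_linked_pairs(small_matrix(calls), threshold=0.9) == []


class TestXLinkage:
    def test_type_one_error_printed_value(self):
        # all 36 males homozygous by chance at MAF 0.31: one in 535 million
        p = x_typeI_error(36, 0.31)
        assert round(1 / p / 1e6) == 535

    @pytest.mark.parametrize("n,maf,expected", [(5, 0.0, 1.0), (0, 0.4, 1.0)])
    def test_degenerate_cases(self, n, maf, expected):
        assert x_typeI_error(n, maf) == expected

    def test_matches_monte_carlo(self, rng):
        n_males, maf, reps = 5, 0.4, 1_000_000
        g = rng.binomial(2, maf, size=(reps, n_males))
        hom = ((g == 0) | (g == 2)).all(axis=1)
        # all homozygous AND for the same allele is the flagged signature;
        # the analytic value covers the all-homozygous event
        p_hat = hom.mean()
        p = x_typeI_error(n_males, maf)
        se = np.sqrt(p * (1 - p) / reps)
        assert abs(p_hat - p) < 3 * se

    def test_constructed_x_locus_flagged_with_error_prob(self):
        # eight males hemizygous for the same allele, one heterozygous female
        calls = {"xl": {f"m{k}": "A" for k in range(8)}}
        calls["xl"].update({"f1": "AB", "f2": "AA", "f3": "BB"})
        sex = {i: ("M" if i.startswith("m") else "F") for i in calls["xl"]}
        m = small_matrix(calls, sex=sex, classes={"xl": "X"})
        [(locus, type1)] = detect_x_linked(m)
        maf = locus_stats(m, "xl").maf
        assert locus == "xl"
        assert type1 == pytest.approx(x_typeI_error(8, maf))

    def test_no_false_flags_on_male_rich_panel(self):
        # with ~17 males, an autosomal locus where every male is homozygous
        # for one shared allele is essentially impossible
        matrix, _, truth = make_pedigree_panel(
            SimConfig(seed=5, n_unrelated=30)
        )
        x_loci = {l for l, c in truth.locus_class.items() if c == "X"}
        for locus, _ in detect_x_linked(matrix):
            assert locus in x_loci

    def test_heterozygous_male_blocks_flag(self):
        m = small_matrix(
            {"l1": {"m1": "AB", "m2": "AA", "f1": "AB"}},
            sex={"m1": "M", "m2": "M", "f1": "F"},
        )
        assert detect_x_linked(m) == []

    def test_monomorphic_not_flagged(self):
        m = small_matrix(
            {"l1": {"m1": "AA", "f1": "AA"}},
            sex={"m1": "M", "f1": "F"},
        )
        assert detect_x_linked(m) == []

    def test_missing_sex_annotation_rejected(self):
        m = small_matrix({"l1": {"i1": "AA", "i2": "AB"}})
        with pytest.raises(ValueError):
            detect_x_linked(m)


class TestHaplotypeAndSex:
    @pytest.mark.parametrize(
        "calls,label",
        [
            (("A", "B", "A", "A"), "NorthA"),
            (("A", "A", "A", "A"), "NorthB"),
            (("B", "B", "B", "B"), "South"),
            (("A", "B", "B", "A"), "unknown"),
            (("A", "B", "--", "A"), "unknown"),
        ],
    )
    def test_mtdna_haplotype_map(self, calls, label):
        assert assign_mtdna_haplotype(calls) == label

    def test_diploid_mtdna_call_rejected(self):
        with pytest.raises(ValueError):
            assign_mtdna_haplotype(("AB", "A", "A", "A"))

    @pytest.mark.parametrize(
        "c1,c2,expected",
        [("A", "A", "M"), ("--", "--", "F"), ("A", "--", "inconclusive")],
    )
    def test_sex_from_y_markers(self, c1, c2, expected):
        assert determine_sex(c1, c2) == expected


def make_stats(locus, maf, He=None):
    He = He if He is not None else 2 * maf * (1 - maf)
    return LocusStats(locus, 1 - maf, maf, He, He, 1.0, 50)


class TestSelectPanel:
    def test_reserved_plus_top_maf(self):
        cands = [make_stats(f"a{k}", maf) for k, maf in
                 enumerate([0.1, 0.5, 0.3, 0.45, 0.2, 0.05, 0.4, 0.25])]
        cands += [make_stats("mt1", 0.0), make_stats("y1", 0.0)]
        panel = select_panel(cands, PanelSpec(5, ("mt1", "y1")))
        assert panel == ["mt1", "y1", "a1", "a3", "a6"]

    def test_tie_break_lexicographic(self):
        cands = [make_stats(l, 0.3) for l in ("b", "a", "d", "c")]
        assert select_panel(cands, PanelSpec(2, ())) == ["a", "b"]

    def test_target_equals_reserved(self):
        cands = [make_stats("mt1", 0.0), make_stats("a1", 0.5)]
        assert select_panel(cands, PanelSpec(1, ("mt1",))) == ["mt1"]

    def test_insufficient_candidates_named_shortfall(self):
        with pytest.raises(ValueError, match="short by 3"):
            select_panel([make_stats("a1", 0.5)], PanelSpec(4, ()))

    def test_order_invariance_and_size(self, rng):
        cands = [make_stats(f"l{k}", float(m))
                 for k, m in enumerate(rng.uniform(0, 0.5, size=30))]
        p1 = select_panel(cands, PanelSpec(10, ("l0",)))
        shuffled = list(cands)
        rng.shuffle(shuffled)
        p2 = select_panel(shuffled, PanelSpec(10, ("l0",)))
        assert p1 == p2 and len(p1) == 10
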