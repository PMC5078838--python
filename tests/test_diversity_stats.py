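"""Diversity statistics against independent brute-force oracles."""

import math

import numpy as np
import pytest

from domscan.diversity_stats import (
    InsufficientSamplesError,
    fold_change,
    hudson_fst,
    nucleotide_diversity,
    per_site_stats,
    segregating_sites,
    tajimas_d,
    watterson_theta,
)

from conftest import make_alignment, random_alignment


# -- independent oracles (straight double loops, no shared code paths) -----


def oracle_pi(aln):
    seqs = aln.sequences()
    n = len(seqs)
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            d = c = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a in "N-" or b in "N-":
                    continue
                c += 1
                if a != b:
                    d += 1
            if c:
                vals.append(d / c)
    return sum(vals) / len(vals) if vals else 0.0


def oracle_watterson(aln):
    seqs = aln.sequences()
    n = len(seqs)
    S = L = 0
    for col in zip(*seqs):
        bases = [b for b in col if b not in "N-"]
        if len(bases) >= 2:
            L += 1
            if len(set(bases)) >= 2:
                S += 1
    if S == 0 or L == 0:
        return 0.0
    return S / (sum(1.0 / i for i in range(1, n)) * L)


def oracle_tajd(aln):
    """From-scratch evaluation of the D formula with hand-counted S and Pi."""
    seqs = aln.sequences()
    n = len(seqs)
    S = L = 0
    for col in zip(*seqs):
        bases = [b for b in col if b not in "N-"]
        if len(bases) >= 2:
            L += 1
            if len(set(bases)) >= 2:
                S += 1
    if S == 0:
        return float("nan")
    big_pi = oracle_pi(aln) * L
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (big_pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def oracle_fst(aln_a, aln_b):
    sa, sb = aln_a.sequences(), aln_b.sequences()

    def mean_pair(seqs_x, seqs_y, within):
        vals = []
        rng_pairs = (
            [(i, j) for i in range(len(seqs_x)) for j in range(i + 1, len(seqs_x))]
            if within
            else [(i, j) for i in range(len(seqs_x)) for j in range(len(seqs_y))]
        )
        for i, j in rng_pairs:
            x = seqs_x[i]
            y = seqs_x[j] if within else seqs_y[j]
            d = c = 0
            for a, b in zip(x, y):
                if a in "N-" or b in "N-":
                    continue
                c += 1
                if a != b:
                    d += 1
            if c:
                vals.append(d / c)
        return sum(vals) / len(vals) if vals else 0.0

    hw = 0.5 * (mean_pair(sa, sa, True) + mean_pair(sb, sb, True))
    hb = mean_pair(sa, sb, False)
    return 0.0 if hb == 0 else 1.0 - hw / hb


# -- tests -----------------------------------------------------------------


class TestNucleotideDiversity:
    def test_monomorphic_is_zero(self):
        aln = make_alignment(["ACGT"] * 5)
        assert nucleotide_diversity(aln) == 0.0

    def test_two_seqs_one_difference(self):
        aln = make_alignment(["A" * 100, "A" * 99 + "T"])
        assert nucleotide_diversity(aln) == pytest.approx(0.01)

    def test_requires_two_samples(self):
        with pytest.raises(InsufficientSamplesError):
            nucleotide_diversity(make_alignment(["ACGT"]))

    @pytest.mark.parametrize("missing", [0.0, 0.15])
    def test_matches_brute_force(self, rng, missing):
        for _ in range(25):
            aln = random_alignment(rng, 6, 50, missing_rate=missing, alphabet="AT")
            assert nucleotide_diversity(aln) == pytest.approx(
                oracle_pi(aln), rel=1e-12, abs=1e-15
            )

    def test_row_permutation_invariance(self, rng):
        aln = random_alignment(rng, 8, 40, alphabet="ACGT")
        perm = rng.permutation(8)
        shuffled = make_alignment([aln.sequences()[i] for i in perm])
        assert nucleotide_diversity(aln) == pytest.approx(
            nucleotide_diversity(shuffled), rel=1e-12
        )


class TestWattersonTheta:
    def test_n2_equals_s_over_l(self):
        aln = make_alignment(["AAAA", "AATT"])
        assert watterson_theta(aln) == pytest.approx(2 / 4)

    def test_direct_summation_example(self):
        # n=10, S=7 over L=1000: theta_w = 7 / (a1 * 1000)
        seqs = ["A" * 1000 for _ in range(10)]
        s9 = "".join("T" if j < 7 else "A" for j in range(1000))
        seqs[9] = s9
        aln = make_alignment(seqs)
        a1 = sum(1.0 / i for i in range(1, 10))
        assert watterson_theta(aln) == pytest.approx(7 / (a1 * 1000), rel=1e-12)

    def test_matches_brute_force(self, rng):
        for _ in range(25):
            aln = random_alignment(rng, 7, 60, missing_rate=0.1, alphabet="ACG")
            assert watterson_theta(aln) == pytest.approx(
                oracle_watterson(aln), rel=1e-12, abs=1e-15
            )


class TestTajimasD:
    def test_monomorphic_undefined(self):
        assert math.isnan(tajimas_d(make_alignment(["ACGT"] * 4)))

    def test_constructed_4x20_matches_formula(self):
        aln = make_alignment(
            ["AAAAAAAAAAAAAAAAAAAA",
             "AAAAAAAAAATAAAAAAAAA",
             "CCAAAAAAAATAAAAAAAAA",
             "CCAAAAAAAAAAAAAAAGGA"]
        )
        assert tajimas_d(aln) == pytest.approx(oracle_tajd(aln), rel=1e-12)

    def test_matches_independent_evaluation(self, rng):
        hits = 0
        for _ in range(30):
            aln = random_alignment(rng, 6, 40, missing_rate=0.05, alphabet="AG")
            got = tajimas_d(aln)
            want = oracle_tajd(aln)
            if math.isnan(want):
                assert math.isnan(got)
            else:
                hits += 1
                assert got == pytest.approx(want, rel=1e-12)
        assert hits > 10  # the comparison must actually exercise defined values

    def test_requires_three_samples(self):
        with pytest.raises(InsufficientSamplesError):
            tajimas_d(make_alignment(["AC", "AT"]))


class TestHudsonFst:
    def test_identical_monomorphic_populations(self):
        a = make_alignment(["ACGT"] * 3)
        b = make_alignment(["ACGT"] * 3)
        assert hudson_fst(a, b) == 0.0

    def test_fixed_difference_gives_one(self):
        a = make_alignment(["AAAA"] * 4)
        b = make_alignment(["TTTT"] * 4)
        assert hudson_fst(a, b) == 1.0

    def test_matches_brute_force(self, rng):
        for _ in range(25):
            a = random_alignment(rng, 4, 30, missing_rate=0.05, alphabet="AT")
            b = random_alignment(rng, 4, 30, missing_rate=0.05, alphabet="AT")
            assert hudson_fst(a, b) == pytest.approx(
                oracle_fst(a, b), rel=1e-9, abs=1e-12
            )


class TestPerSiteStats:
    def test_invariant_site(self):
        a = make_alignment(["AA", "AA"])
        b = make_alignment(["AA", "AA"])
        ps = per_site_stats(a, b)
        assert ps["div_a"][0] == 0.0 and ps["fst"][0] == 0.0

    def test_fixed_difference_site(self):
        a = make_alignment(["A", "A", "A"])
        b = make_alignment(["T", "T", "T"])
        assert per_site_stats(a, b)["fst"][0] == 1.0

    def test_mixed_site_counts(self):
        # pop a: A:3 T:1; pop b: A:1 T:3
        a = make_alignment(["A", "A", "A", "T"])
        b = make_alignment(["A", "T", "T", "T"])
        ps = per_site_stats(a, b)
        da = (4 / 3) * (1 - (0.75**2 + 0.25**2))
        dxy = 1 - (0.75 * 0.25 + 0.25 * 0.75)
        assert ps["div_a"][0] == pytest.approx(da, rel=1e-12)
        assert ps["dxy"][0] == pytest.approx(dxy, rel=1e-12)
        assert ps["fst"][0] == pytest.approx(1 - da / dxy, rel=1e-12)

    def test_aggregation_matches_gene_level_fst(self, rng):
        """Summing per-site numerators/denominators reproduces hudson_fst
        exactly on gap-free alignments."""
        for _ in range(10):
            a = random_alignment(rng, 5, 80, alphabet="ACGT")
            b = random_alignment(rng, 6, 80, alphabet="ACGT")
            ps = per_site_stats(a, b)
            hw = 0.5 * (ps["div_a"] + ps["div_b"])
            agg = 1.0 - np.nansum(hw) / np.nansum(ps["dxy"])
            assert agg == pytest.approx(hudson_fst(a, b), abs=1e-9)


class TestFoldChange:
    def test_printed_worked_example(self):
        # theta-pi 0.007699 over 0.0002358 is a 32.7-fold increase (1 dp)
        assert round(fold_change(0.007699, 0.0002358), 1) == 32.7

    def test_equal_inputs(self):
        assert fold_change(0.001, 0.001) == 1.0

    def test_zero_denominator_flags_infinite(self):
        assert math.isinf(fold_change(0.001, 0.0))
        assert math.isnan(fold_change(0.0, 0.0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fold_change(-0.1, 0.1)


def test_pi_thetaw_zero_iff_no_segregating_sites(rng):
    for _ in range(10):
        aln = random_alignment(rng, 5, 30, alphabet="AC")
        S, _ = segregating_sites(aln)
        pi = nucleotide_diversity(aln)
        w = watterson_theta(aln)
        assert (S == 0) == (pi == 0.0) == (w == 0.0)
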