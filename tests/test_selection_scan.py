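"""Empirical-quantile classification at gene and site level."""

import numpy as np
import pytest

from domscan.selection_scan import (
    ClassificationError,
    EmpiricalDistribution,
    annotate_codon_effects,
    classify_gene,
    classify_sites,
    detect_invariant_genes,
    detect_sweep,
    diversity_change_background,
    empirical_quantile,
)

from conftest import make_alignment


class TestEmpiricalQuantile:
    def test_maximum_is_100(self):
        d = EmpiricalDistribution("x", np.arange(10.0))
        assert empirical_quantile(d, 9.0) == 100.0

    def test_below_all_is_0(self):
        d = EmpiricalDistribution("x", np.arange(10.0))
        assert empirical_quantile(d, -1.0) == 0.0

    def test_first_order_statistic_of_20(self):
        vals = np.arange(1.0, 21.0)
        d = EmpiricalDistribution("x", vals)
        assert empirical_quantile(d, 1.0) == 5.0

    def test_ties_share_higher_rank(self):
        d = EmpiricalDistribution("x", np.array([1.0, 1.0, 1.0, 2.0]))
        assert empirical_quantile(d, 1.0) == 75.0

    def test_direct_rank_count_random(self, rng):
        for _ in range(50):
            vals = rng.normal(size=rng.integers(5, 40))
            d = EmpiricalDistribution("x", vals)
            v = float(rng.choice(vals))
            want = 100.0 * np.sum(np.sort(vals) <= v) / len(vals)
            assert empirical_quantile(d, v) == pytest.approx(want, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ClassificationError):
            EmpiricalDistribution("x", np.array([]))


def _background(pi_vals, w_vals, tajd_vals, fst_vals):
    return {
        "pi": EmpiricalDistribution("pi", np.array(pi_vals)),
        "theta_w": EmpiricalDistribution("theta_w", np.array(w_vals)),
        "tajd": EmpiricalDistribution("tajd", np.array(tajd_vals)),
        "fst": EmpiricalDistribution("fst", np.array(fst_vals)),
    }


def reference_background():
    """A stipulated 100-gene background placing the printed per-gene
    statistics of the five labelled genes in the stated quantile bands."""
    pi = np.linspace(0.0005, 0.0035, 100)
    w = np.linspace(0.0005, 0.0035, 100)
    tajd = np.linspace(-1.2, 1.8, 100)
    fst = np.linspace(0.05, 0.45, 100)
    return _background(pi, w, tajd, fst)


PRINTED_ROWS = [
    # gene_id, pi_desc, theta_w_desc (pi used: not printed), tajd_desc, fst, label
    ("Sobic.001G422300", 0.0, 0.0, float("nan"), 0.694667, "purifying"),
    ("Sobic.002G413100", 0.0, 0.0, float("nan"), 0.593150, "purifying"),
    ("Sobic.007G078500", 0.000026, 0.000026, -0.567739, 0.644061, "purifying"),
    ("Sobic.006G169500", 0.007699, 0.007699, 2.001733, 0.274193, "balancing"),
    ("Sobic.009G225700", 0.003671, 0.003671, 3.008451, 0.188190, "balancing"),
]


class TestClassifyGene:
    @pytest.mark.parametrize("row", PRINTED_ROWS, ids=[r[0] for r in PRINTED_ROWS])
    def test_published_gene_labels_reproduced(self, row):
        gid, pi, w, tajd, fst, label = row
        dists = reference_background()
        call = classify_gene(
            {"gene_id": gid, "pi": pi, "theta_w": w, "tajd": tajd, "fst": fst},
            dists,
        )
        assert call.call == label
        assert call.evidence["pi_pct"] >= 0

    def test_background_median_gene_is_none(self):
        dists = reference_background()
        call = classify_gene(
            {"gene_id": "g", "pi": 0.0035, "theta_w": 0.0035, "tajd": 0.2,
             "fst": 0.25},
            dists,
        )
        assert call.call == "none"

    def test_undefined_tajd_satisfies_purifying_clause(self):
        dists = reference_background()
        call = classify_gene(
            {"gene_id": "g", "pi": 0.0, "theta_w": 0.0, "tajd": float("nan"),
             "fst": 0.9},
            dists,
        )
        assert call.call == "purifying"

    def test_undefined_tajd_cannot_be_balancing(self):
        dists = reference_background()
        call = classify_gene(
            {"gene_id": "g", "pi": 0.0059, "theta_w": 0.0059,
             "tajd": float("nan"), "fst": 0.25},
            dists,
        )
        assert call.call == "none"

    def test_missing_statistic_rejected(self):
        with pytest.raises(ClassificationError):
            classify_gene({"gene_id": "g", "pi": 0.1}, reference_background())


class TestClassifySites:
    def _stats(self, div_a, div_b, fst):
        return {
            "div_a": np.array(div_a, dtype=float),
            "div_b": np.array(div_b, dtype=float),
            "fst": np.array(fst, dtype=float),
        }

    def test_monomorphic_site_not_called(self):
        calls = classify_sites(self._stats([0.0], [0.0], [0.0]), 0.1,
                               gene_tajd=-1.0)
        assert calls == []

    def test_forced_purifying_site(self):
        calls = classify_sites(
            self._stats([0.5], [0.0], [0.6]), 0.1, gene_tajd=-1.0, gene_id="g"
        )
        assert len(calls) == 1 and calls[0].call == "purifying"

    def test_balancing_requires_positive_tajd(self):
        stats = self._stats([0.0], [0.5], [0.6])
        assert classify_sites(stats, 0.1, gene_tajd=-0.5) == []
        calls = classify_sites(stats, 0.1, gene_tajd=1.5)
        assert len(calls) == 1 and calls[0].call == "balancing"

    def test_matches_clause_by_clause_oracle(self, rng):
        """Random per-site stats checked against a straight-line
        reimplementation of the three clauses."""
        for _ in range(20):
            L = 30
            div_a = rng.random(L)
            div_b = rng.random(L)
            fst = rng.uniform(-0.2, 1.0, L)
            bg = 0.3
            tajd = float(rng.normal())
            got = classify_sites(self._stats(div_a, div_b, fst), bg,
                                 gene_tajd=tajd)
            want = []
            for j in range(L):
                change = div_b[j] - div_a[j]
                if fst[j] <= 0 or abs(change) <= bg:
                    continue
                if change < 0 and tajd < 0:
                    want.append((j, "purifying"))
                elif change > 0 and tajd > 0:
                    want.append((j, "balancing"))
            assert [(c.site, c.call) for c in got] == want


class TestCodonEffects:
    def _call(self, site):
        from domscan.selection_scan import SiteSelectionCall

        return SiteSelectionCall(gene_id="g", site=site, call="purifying")

    def test_synonymous_third_position(self):
        aln = make_alignment(["GGTAAA", "GGCAAA", "GGTAAA"])
        out = annotate_codon_effects([self._call(2)], aln)
        assert out[0].effect == "synonymous"
        assert out[0].codon_index == 0

    def test_nonsynonymous_first_position_basic_residue(self):
        # GAA (Glu) <-> AAA (Lys): variant residue K is basic
        aln = make_alignment(["GAAGGG", "GAAGGG", "AAAGGG"])
        out = annotate_codon_effects([self._call(0)], aln)
        assert out[0].effect == "non-synonymous"
        assert out[0].residue_class == "basic"

    def test_site_outside_cds_marked_noncoding(self):
        aln = make_alignment(["GGTAAA", "GGCAAA"])
        out = annotate_codon_effects([self._call(10)], aln)
        assert out[0].effect == "noncoding"

    def test_simulated_codon_gene_annotations(self):
        """Annotations agree with direct codon translation on simulated CDS."""
        from domscan.kaks import GENETIC_CODE
        from domscan.synthetic_data import simulate_codon_pair

        a, b = simulate_codon_pair(300, omega=3.0, branch_length=0.1, seed=9)
        aln = make_alignment([a, a, a, b])
        diffs = [j for j in range(len(a)) if a[j] != b[j]]
        calls = annotate_codon_effects([self._call(j) for j in diffs], aln)
        for c in calls:
            ci = c.codon_index
            ca, cb = a[3 * ci:3 * ci + 3], b[3 * ci:3 * ci + 3]
            if sum(x != y for x, y in zip(ca, cb)) == 1:
                want = (
                    "synonymous"
                    if GENETIC_CODE[ca] == GENETIC_CODE[cb]
                    else "non-synonymous"
                )
                assert c.effect == want


class TestSweepDetection:
    def _calls(self, purifying_ids):
        from domscan.selection_scan import GeneSelectionCall

        return {
            g: GeneSelectionCall(g, "purifying" if g in purifying_ids else "none")
            for g in ("gA", "gB", "gC")
        }

    def _positions(self):
        return {
            "gA": ("chr1", 1, 2000),
            "gB": ("chr1", 10001, 12000),
            "gC": ("chr1", 20001, 22000),
        }

    def test_isolated_gene_span_is_focal_only(self):
        windows = [(1, 2000, 0.0), (10001, 12000, 0.01), (20001, 22000, 0.01)]
        region = detect_sweep("gA", self._calls({"gA"}), self._positions(),
                              windows, low_quantile=0.001)
        assert region.member_genes == ["gA"]
        assert region.span_kb == pytest.approx(2.0)

    def test_multi_window_sweep_recovered(self):
        windows = [(s, s + 1999, 0.0) for s in range(1, 10000, 2000)]
        windows += [(10001, 12000, 0.01)]
        region = detect_sweep("gA", self._calls({"gA"}), self._positions(),
                              windows, low_quantile=0.001)
        assert region.end == 10000
        assert region.span_kb == pytest.approx(10.0)

    def test_two_purifying_genes_share_membership(self):
        windows = [(1, 12000, 0.0)]
        calls = self._calls({"gA", "gB"})
        ra = detect_sweep("gA", calls, self._positions(), windows, 0.001)
        rb = detect_sweep("gB", calls, self._positions(), windows, 0.001)
        assert ra.member_genes == rb.member_genes == ["gA", "gB"]

    def test_non_purifying_focal_rejected(self):
        with pytest.raises(ValueError):
            detect_sweep("gB", self._calls({"gA"}), self._positions(), [], 0.0)


class TestInvariance:
    def test_forced_monomorphic_genes_recovered(self):
        from domscan.diversity_stats import summarize_gene

        alns = {
            "inv": make_alignment(["ACGT"] * 4, groups=["Landrace"] * 4,
                                  gene_id="inv"),
            "var": make_alignment(["ACGT", "ACGA", "ACGT", "ACGT"],
                                  groups=["Landrace"] * 4, gene_id="var"),
        }
        summaries = [summarize_gene(a, g, "Landrace") for g, a in alns.items()]
        out = detect_invariant_genes(summaries)
        assert out == {"Landrace": ["inv"]}

    def test_group_vs_overall_invariance(self):
        from domscan.diversity_stats import summarize_gene

        desc = make_alignment(["AAAA"] * 3, gene_id="g")
        anc = make_alignment(["AAAT", "AAAA", "AAAA"], gene_id="g")
        pooled = make_alignment(["AAAA"] * 3 + ["AAAT", "AAAA", "AAAA"],
                                gene_id="g")
        summaries = [
            summarize_gene(desc, "g", "Landrace"),
            summarize_gene(anc, "g", "WildWeedy"),
            summarize_gene(pooled, "g", "overall"),
        ]
        out = detect_invariant_genes(summaries)
        assert out.get("Landrace") == ["g"]
        assert "overall" not in out


def test_diversity_change_background_mean():
    assert diversity_change_background([0.1, -0.3, float("nan")]) == pytest.approx(0.2)
    with pytest.raises(ValueError):
        diversity_change_background([float("nan")])
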