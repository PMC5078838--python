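"""The Wright-Fisher panel generator: determinism, calibration, regimes."""

import numpy as np
import pytest

from domscan.diversity_stats import (
    nucleotide_diversity,
    segregating_sites,
)
from domscan.synthetic_data import (
    ConfigurationError,
    SENSE_CODONS,
    SimulationConfig,
    STOP_CODONS,
    generate_dataset,
    simulate_codon_pair,
    simulate_neutral_gene,
    simulate_selected_gene,
    write_dataset,
)


class TestConfigValidation:
    def test_bad_bottleneck_fraction(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(bottleneck_fraction=0.0)

    def test_unknown_regime(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(regimes=("neutral", "mystery"))

    def test_codon_gene_length_frame(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(gene_length=1000, regimes=("positive",))

    def test_outgroup_before_bottleneck(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(outgroup_divergence_time=10, bottleneck_duration=50)


class TestNeutralGene:
    def test_zero_mutation_rate_gives_identical_sequences(self, small_config):
        from dataclasses import replace

        cfg = replace(small_config, per_site_mutation_rate=0.0)
        anc, desc, og = simulate_neutral_gene(cfg, seed=1)
        assert nucleotide_diversity(anc) == 0.0
        assert nucleotide_diversity(desc) == 0.0
        assert len(set(anc.sequences() + desc.sequences() + [og])) == 1

    def test_determinism_byte_identical(self, small_config):
        a1, d1, o1 = simulate_neutral_gene(small_config, seed=42)
        a2, d2, o2 = simulate_neutral_gene(small_config, seed=42)
        assert a1 == a2 and d1 == d2 and o1 == o2

    def test_sample_names_and_labels(self, small_config):
        anc, desc, og = simulate_neutral_gene(small_config, seed=3)
        assert anc.population_labels == ["WildWeedy"] * small_config.n_ancestral
        assert desc.population_labels == ["Landrace"] * small_config.n_descendant
        assert len(og) == small_config.gene_length

    def test_segregating_sites_match_neutral_expectation(self, small_config):
        """Mean S over replicates within 3 standard errors of theta*a1*L."""
        Ss = []
        for seed in range(200):
            anc, _, _ = simulate_neutral_gene(small_config, seed=10_000 + seed)
            Ss.append(segregating_sites(anc)[0])
        theta = (
            4
            * small_config.effective_size_ancestral
            * small_config.per_site_mutation_rate
        )
        a1 = sum(1.0 / i for i in range(1, small_config.n_ancestral))
        expected = theta * a1 * small_config.gene_length
        se = np.std(Ss, ddof=1) / np.sqrt(len(Ss))
        assert abs(np.mean(Ss) - expected) < 3 * se


class TestSelectedGenes:
    def test_complete_sweep_gives_zero_descendant_diversity(self, small_config):
        anc, desc, og, truth = simulate_selected_gene(
            small_config, "purifying", seed=5, sweep_completeness=1.0
        )
        assert nucleotide_diversity(desc) == 0.0
        assert truth["regime"] == "purifying"

    def test_balancing_mean_pairwise_near_half_distance(self, small_config):
        """Two classes at ~50/50 differing at d sites give mean pairwise
        differences ~ d * n / (2(n-1)) (brute-force pairwise count)."""
        anc, desc, og, truth = simulate_selected_gene(
            small_config, "balancing", seed=6
        )
        seqs = desc.sequences()
        uniq = sorted(set(seqs))
        assert len(uniq) == 2
        d = sum(a != b for a, b in zip(uniq[0], uniq[1]))
        n = len(seqs)
        k = seqs.count(uniq[0])
        expected = d * k * (n - k) / (n * (n - 1) / 2)
        total = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                total += sum(a != b for a, b in zip(seqs[i], seqs[j]))
        got = total / (n * (n - 1) / 2)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(d / 2, rel=0.15)

    def test_unknown_regime_rejected(self, small_config):
        with pytest.raises(ConfigurationError):
            simulate_selected_gene(small_config, "neutral-ish", seed=1)

    def test_positive_regime_enriches_nonsynonymous(self, small_config):
        from dataclasses import replace

        from domscan.kaks import kaks_ng86

        cfg = replace(small_config, regimes=("positive",))
        hits = 0
        for seed in range(10):
            anc, desc, og, truth = simulate_selected_gene(cfg, "positive",
                                                          seed=600 + seed)
            res = kaks_ng86(anc.sequences()[0], desc.sequences()[0])
            if res.ratio > 1:
                hits += 1
        assert hits >= 9


class TestCodonPair:
    def test_zero_branch_identical(self):
        a, b = simulate_codon_pair(300, omega=1.0, branch_length=0.0, seed=1)
        assert a == b

    def test_no_internal_stops(self):
        for seed in range(5):
            a, b = simulate_codon_pair(900, omega=3.0, branch_length=0.5,
                                       seed=seed)
            for cds in (a, b):
                codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
                assert not any(c in STOP_CODONS for c in codons)
                assert all(c in SENSE_CODONS for c in codons)

    def test_negative_branch_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_codon_pair(300, omega=1.0, branch_length=-0.1, seed=1)

    def test_neutral_estimator_consistency(self):
        """NG86 on kappa=1, omega=1 pairs averages within 15% of 1."""
        from domscan.kaks import kaks_ng86

        ratios = []
        for seed in range(25):
            a, b = simulate_codon_pair(1200, omega=1.0, branch_length=0.2,
                                       seed=700 + seed)
            r = kaks_ng86(a, b).ratio
            if np.isfinite(r):
                ratios.append(r)
        assert abs(np.mean(ratios) - 1.0) < 0.15


class TestDataset:
    def test_truth_table_structure(self, small_config):
        from dataclasses import replace

        cfg = replace(small_config, regimes=("neutral",) * 10)
        ds = generate_dataset(cfg)
        assert len(ds.truth) == 10
        assert all(v == "neutral" for v in ds.truth.values())

    def test_same_seed_identical_truth_and_alignments(self, small_config):
        from dataclasses import replace

        cfg = replace(small_config,
                      regimes=("neutral", "purifying", "balancing"))
        d1, d2 = generate_dataset(cfg), generate_dataset(cfg)
        assert d1.truth == d2.truth
        for g in d1.gene_ids():
            assert d1.ancestral[g] == d2.ancestral[g]
            assert d1.descendant[g] == d2.descendant[g]
            assert d1.outgroup[g] == d2.outgroup[g]

    def test_written_dataset_files(self, small_config, tmp_path):
        from dataclasses import replace

        cfg = replace(small_config, regimes=("neutral", "balancing"))
        ds = generate_dataset(cfg)
        write_dataset(ds, tmp_path)
        assert (tmp_path / "metadata.tsv").exists()
        truth = (tmp_path / "truth.tsv").read_text().splitlines()
        assert truth[0] == "gene_id\tregime\tomega"
        assert len(truth) == 3

    def test_default_bottleneck_hits_genomewide_reduction_band(self):
        """Neutral-background descendant/ancestral mean theta-pi ratio on
        the default configuration falls in [1/2.2, 1/1.3] (the ~1.7-fold
        genome-wide reduction the bottleneck is calibrated to)."""
        anc_pis, desc_pis = [], []
        for seed in (11, 12):
            ds = generate_dataset(SimulationConfig(seed=seed))
            for g, regime in ds.truth.items():
                if regime != "neutral":
                    continue
                anc_pis.append(nucleotide_diversity(ds.ancestral[g]))
                desc_pis.append(nucleotide_diversity(ds.descendant[g]))
        ratio = np.mean(desc_pis) / np.mean(anc_pis)
        assert 1 / 2.2 <= ratio <= 1 / 1.3

    def test_bottleneck_monotonicity(self):
        """Lowering the bottleneck fraction does not raise descendant
        diversity (replicate means)."""
        from dataclasses import replace

        base = SimulationConfig(
            effective_size_ancestral=50,
            bottleneck_duration=25,
            per_site_mutation_rate=3e-5,
            gene_length=600,
            outgroup_divergence_time=300,
            selected_allele_age=200,
            regimes=("neutral",),
            burn_in_factor=12,
        )
        means = []
        for frac in (0.9, 0.4):
            cfg = replace(base, bottleneck_fraction=frac)
            vals = [
                nucleotide_diversity(
                    simulate_neutral_gene(cfg, seed=900 + s)[1]
                )
                for s in range(40)
            ]
            means.append(np.mean(vals))
        assert means[1] <= means[0]
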