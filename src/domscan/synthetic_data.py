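"""Forward Wright-Fisher simulation of a two-population domestication panel.

The generator emulates the statistical structure of a resequenced crop
panel: an equilibrium wild (ancestral) population, a domesticated
(descendant) population derived from it through a recent bottleneck, an
outgroup lineage for divergence-based tests, and per-gene selection regimes
with exact truth labels.

Model choices
-------------
* Discrete-generation haploid Wright-Fisher resampling of ``2N`` haplotype
  lineages (N diploid individuals), run to approximate equilibrium from a
  monomorphic start (burn-in of ``burn_in_factor * N`` generations).
* Infinite-sites mutation for non-coding genes: every mutation hits a fresh
  site; positions are assigned at the end so only mutations visible in the
  sampled haplotypes or the outgroup consume sites.
* The outgroup diverges ``outgroup_divergence_time`` generations before
  sampling: one lineage is copied out of the ancestral population at that
  generation and accumulates Poisson(mu * L * T) private mutations.
* The descendant population is founded ``bottleneck_duration`` generations
  before sampling with ``bottleneck_fraction * N`` diploids and is sampled
  at the end of the bottleneck.  Expected descendant diversity follows the
  transient pi_t = theta_b + (pi_0 - theta_b) * exp(-t / (2 * N_b)) with
  theta_b the bottleneck-size equilibrium; the defaults (fraction 0.25,
  duration 50, N = 100) solve this for the ~1.7-fold genome-wide reduction
  typical of a domestication bottleneck.
* Selection regimes are imposed phenomenologically so truth labels stay
  exact: a purifying gene experiences a post-bottleneck sweep (one
  haplotype raised to ``sweep_completeness`` frequency in the descendant
  population); a balancing gene has two ancestral haplotype classes
  maintained at intermediate frequency in the descendant sample; a positive
  gene is a coding gene evolved under a codon model with omega > 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from domscan.gene_io import HaplotypeAlignment, SampleMetadata
from domscan.kaks import (
    CODONS,
    GENETIC_CODE,
    STOP_CODONS,
    substitution_class,
)

REGIMES = ("neutral", "purifying", "balancing", "positive")

SENSE_CODONS = [c for c in CODONS if c not in STOP_CODONS]


class ConfigurationError(ValueError):
    """Invalid simulation parameters."""


def _default_regimes() -> tuple[str, ...]:
    return ("neutral",) * 50 + ("purifying",) * 10 + ("balancing",) * 10


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the two-population panel simulation.

    Sample counts are haplotypes: the defaults (14 ancestral, 36
    descendant) mirror a panel of 7 wild and 18 landrace inbred
    (effectively homozygous) accessions.
    """

    n_ancestral: int = 14
    n_descendant: int = 36
    effective_size_ancestral: int = 100  # diploid individuals
    bottleneck_fraction: float = 0.25
    bottleneck_duration: int = 50
    per_site_mutation_rate: float = 1.5e-5
    n_genes: int = 70
    gene_length: int = 1500
    regimes: tuple[str, ...] = field(default_factory=_default_regimes)
    outgroup_divergence_time: int = 1000  # tau=5: a true outgroup, well outside the species
    seed: int = 0
    sweep_completeness: float = 1.0  # swept genes are descendant-invariant
    selected_allele_age: int = 800  # deep standing variation, younger than the outgroup split
    positive_omega: float = 3.0
    burn_in_factor: int = 16  # ~8 coalescent units: deep branches unbiased

    def __post_init__(self):
        if not (0.0 < self.bottleneck_fraction <= 1.0):
            raise ConfigurationError("bottleneck_fraction must be in (0, 1]")
        for name in (
            "n_ancestral", "n_descendant", "effective_size_ancestral",
            "bottleneck_duration", "n_genes", "gene_length",
            "outgroup_divergence_time",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.per_site_mutation_rate < 0:
            raise ConfigurationError("per_site_mutation_rate must be >= 0")
        if len(self.regimes) != self.n_genes:
            object.__setattr__(self, "n_genes", len(self.regimes))
        for r in self.regimes:
            if r not in REGIMES:
                raise ConfigurationError(f"unknown regime {r!r}")
        if "positive" in self.regimes and self.gene_length % 3 != 0:
            raise ConfigurationError(
                "gene_length must be divisible by 3 when codon genes are simulated"
            )
        if self.outgroup_divergence_time < self.bottleneck_duration:
            raise ConfigurationError(
                "outgroup must diverge before the domestication bottleneck"
            )
        if not (0.0 <= self.sweep_completeness <= 1.0):
            raise ConfigurationError("sweep_completeness must be in [0, 1]")
        total = max(self.burn_in_factor * self.effective_size_ancestral,
                    self.outgroup_divergence_time
                    + 8 * self.effective_size_ancestral)
        if not (0 < self.selected_allele_age < total):
            raise ConfigurationError(
                "selected_allele_age must lie within the simulated history"
            )


@dataclass
class SimulatedDataset:
    """Fully labelled synthetic panel."""

    config: SimulationConfig
    ancestral: dict[str, HaplotypeAlignment]
    descendant: dict[str, HaplotypeAlignment]
    outgroup: dict[str, str]
    truth: dict[str, str]  # gene_id -> regime
    truth_omega: dict[str, float]  # codon genes only
    metadata: SampleMetadata
    gene_positions: dict[str, tuple[str, int, int]]  # chrom, start, end (1-based)

    def combined(self, gene_id: str) -> HaplotypeAlignment:
        a, d = self.ancestral[gene_id], self.descendant[gene_id]
        return HaplotypeAlignment(
            a.sample_names + d.sample_names,
            a.population_labels + d.population_labels,
            np.vstack([a.matrix, d.matrix]),
            gene_id,
            a.feature,
        )

    def gene_ids(self) -> list[str]:
        return sorted(self.truth)


# -- Wright-Fisher core ----------------------------------------------------


class _HaploTree:
    """Haplotype classes as nodes of a mutation tree.

    Node 0 is the mutation-free root; every other node adds exactly one new
    mutation on top of its parent.
    """

    def __init__(self):
        self.parent = [-1]

    def add(self, parent: int) -> int:
        self.parent.append(parent)
        return len(self.parent) - 1

    def chain(self, node: int) -> list[int]:
        out = []
        while node > 0:
            out.append(node)
            node = self.parent[node]
        return out


def _drift_and_mutate(rng, tree: _HaploTree, nodes: list[int],
                      counts: np.ndarray, size: int, mu_seq: float):
    """One WF generation: multinomial resampling then Poisson mutation."""
    counts = rng.multinomial(size, counts / size).astype(np.int64)
    nmut = rng.poisson(size * mu_seq)
    if nmut:
        cum = np.cumsum(counts)
        js = np.searchsorted(cum, rng.integers(size, size=nmut), side="right")
        for j in js:
            j = int(j)
            if counts[j] == 0:  # slot stale after an earlier decrement
                j = int(np.argmax(counts))
            counts[j] -= 1
            nodes.append(tree.add(nodes[j]))
        counts = np.concatenate([counts, np.ones(nmut, dtype=np.int64)])
    return nodes, counts


def _prune(nodes, counts):
    keep = counts > 0
    return [n for n, k in zip(nodes, keep) if k], counts[keep]


def _run_wf_gene(config: SimulationConfig, gene_length: int, rng,
                 snapshot_age: int | None = None):
    """Run one gene; returns (tree, anc nodes/counts, desc nodes/counts,
    outgroup node, n outgroup private mutations, snapshot node).

    ``snapshot_age`` optionally records one random lineage that many
    generations before sampling (used to seed selected-allele lineages).
    """
    M = 2 * config.effective_size_ancestral
    mu_seq = config.per_site_mutation_rate * gene_length
    # equilibrium must be reached before the outgroup branch point, so the
    # burn-in extends past deep-history events
    total = max(config.burn_in_factor * config.effective_size_ancestral,
                config.outgroup_divergence_time
                + 8 * config.effective_size_ancestral)
    g_branch = total - config.outgroup_divergence_time
    g_snap = total - snapshot_age if snapshot_age else -1

    g_split = total - config.bottleneck_duration

    tree = _HaploTree()
    nodes, counts = [0], np.array([M], dtype=np.int64)
    og_node = 0
    snap_node = 0
    desc_nodes: list[int] = []
    desc_counts = np.array([], dtype=np.int64)
    Mb = max(2, round(M * config.bottleneck_fraction))

    def draw_node():
        cum = np.cumsum(counts)
        j = int(np.searchsorted(cum, rng.integers(counts.sum()), side="right"))
        return nodes[j]

    for g in range(total):
        nodes, counts = _drift_and_mutate(rng, tree, nodes, counts, M, mu_seq)
        if len(nodes) > 256:
            nodes, counts = _prune(nodes, counts)
        if g + 1 == g_branch:
            og_node = draw_node()
        if g + 1 == g_snap:
            snap_node = draw_node()
        if g + 1 == g_split:
            founder = rng.multinomial(Mb, counts / counts.sum())
            desc_nodes = list(nodes)
            desc_counts = founder.astype(np.int64)
            desc_nodes, desc_counts = _prune(desc_nodes, desc_counts)
    for _ in range(config.bottleneck_duration):
        desc_nodes, desc_counts = _drift_and_mutate(
            rng, tree, desc_nodes, desc_counts, Mb, mu_seq
        )
    nodes, counts = _prune(nodes, counts)
    desc_nodes, desc_counts = _prune(desc_nodes, desc_counts)
    n_og_private = int(rng.poisson(mu_seq * config.outgroup_divergence_time))
    return tree, nodes, counts, desc_nodes, desc_counts, og_node, n_og_private, snap_node


def _sample_classes(rng, nodes, counts, n):
    """Sample n haplotypes without replacement; returns node id per sample."""
    draw = rng.multivariate_hypergeometric(counts, min(n, int(counts.sum())))
    out = []
    for node, k in zip(nodes, draw):
        out.extend([node] * int(k))
    while len(out) < n:  # sample larger than population: sample with replacement
        cum = np.cumsum(counts)
        j = int(np.searchsorted(cum, rng.integers(counts.sum()), side="right"))
        out.append(nodes[j])
    return out


def _materialize(
    rng,
    tree: _HaploTree,
    gene_length: int,
    anc_sample: list[int],
    desc_sample: list[int],
    og_node: int,
    n_og_private: int,
):
    """Assign sites and bases to mutations; build sequence strings."""
    needed: set[int] = set()
    for node in anc_sample + desc_sample + [og_node]:
        needed.update(tree.chain(node))
    muts = sorted(needed)
    total_sites = len(muts) + n_og_private
    if total_sites > gene_length:
        raise ConfigurationError(
            f"{total_sites} mutations exceed {gene_length} available sites; "
            "lower the mutation rate or divergence time"
        )
    root = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=gene_length)
    positions = rng.choice(gene_length, size=total_sites, replace=False)
    mut_pos = dict(zip(muts, positions[: len(muts)].tolist()))
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    mut_base = {}
    for m in muts:
        p = mut_pos[m]
        alts = bases[bases != root[p]]
        mut_base[m] = rng.choice(alts)

    def build(node: int) -> np.ndarray:
        seq = root.copy()
        for m in tree.chain(node):
            seq[mut_pos[m]] = mut_base[m]
        return seq

    anc = np.vstack([build(n) for n in anc_sample])
    desc = np.vstack([build(n) for n in desc_sample])
    og = build(og_node)
    for p in positions[len(muts):]:
        alts = bases[bases != og[p]]
        og[p] = rng.choice(alts)
    return anc, desc, og


def _sample_names(config):
    anc = [f"WW{i + 1:03d}" for i in range(config.n_ancestral)]
    desc = [f"LR{i + 1:03d}" for i in range(config.n_descendant)]
    return anc, desc


def _wrap(config, gene_id, anc_mat, desc_mat, feature="gene"):
    anc_names, desc_names = _sample_names(config)
    anc = HaplotypeAlignment(
        anc_names, ["WildWeedy"] * config.n_ancestral, anc_mat, gene_id, feature
    )
    desc = HaplotypeAlignment(
        desc_names, ["Landrace"] * config.n_descendant, desc_mat, gene_id, feature
    )
    return anc, desc


# -- public operations -----------------------------------------------------


def simulate_neutral_gene(
    config: SimulationConfig,
    gene_length: int | None = None,
    seed: int | None = None,
    gene_id: str = "gene",
):
    """Simulate one neutral gene.

    Returns (ancestral alignment, descendant alignment, outgroup sequence).
    """
    L = gene_length if gene_length is not None else config.gene_length
    if L < 1:
        raise ConfigurationError("gene_length must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    tree, nodes, counts, dnodes, dcounts, og_node, n_og, _ = _run_wf_gene(
        config, L, rng
    )
    anc_sample = _sample_classes(rng, nodes, counts, config.n_ancestral)
    desc_sample = _sample_classes(rng, dnodes, dcounts, config.n_descendant)
    anc_mat, desc_mat, og = _materialize(
        rng, tree, L, anc_sample, desc_sample, og_node, n_og
    )
    anc, desc = _wrap(config, gene_id, anc_mat, desc_mat)
    return anc, desc, og.tobytes().decode("ascii")


def simulate_selected_gene(
    config: SimulationConfig,
    regime: str,
    seed: int | None = None,
    gene_id: str = "gene",
    sweep_completeness: float | None = None,
):
    """Simulate one gene under a selection regime.

    Returns (ancestral, descendant, outgroup sequence, truth record).
    Purifying: a post-bottleneck sweep raises one haplotype to
    ``sweep_completeness`` frequency in the descendant population.
    Balancing: two distinct ancestral haplotype classes are maintained at
    ~50/50 in the descendant sample.  Positive: codon-model simulation with
    ``config.positive_omega``.
    """
    if regime not in ("purifying", "balancing", "positive"):
        raise ConfigurationError(f"unknown selected regime {regime!r}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    truth: dict = {"gene_id": gene_id, "regime": regime}

    if regime == "positive":
        anc, desc, og = _simulate_positive_gene(config, rng, gene_id)
        truth["omega"] = config.positive_omega
        return anc, desc, og, truth

    L = config.gene_length
    tree, nodes, counts, dnodes, dcounts, og_node, n_og, snap = _run_wf_gene(
        config, L, rng, snapshot_age=config.selected_allele_age
    )
    anc_sample = _sample_classes(rng, nodes, counts, config.n_ancestral)

    # The selected allele is an old lineage: a snapshot taken
    # selected_allele_age generations back, carrying its own private
    # mutations since then.  Callable selection signatures involve
    # haplotypes well differentiated from the extant wild pool (deep
    # standing variation or wild introgression, both documented routes in
    # crop domestication); a sweep of a run-of-the-mill recent haplotype is
    # statistically indistinguishable from neutral post-bottleneck drift.
    sel_node = snap
    for _ in range(int(rng.poisson(
            config.per_site_mutation_rate * L * config.selected_allele_age))):
        sel_node = tree.add(sel_node)

    if regime == "purifying":
        c = (config.sweep_completeness
             if sweep_completeness is None else sweep_completeness)
        k = int(round(c * config.n_descendant))
        rest = config.n_descendant - k
        others = []
        if rest > 0:
            others = _sample_classes(rng, list(dnodes), dcounts.copy(), rest)
        desc_sample = [sel_node] * k + others
        truth["swept_haplotype"] = sel_node
    else:  # balancing
        # the common extant class and the old allele are both maintained at
        # intermediate frequency
        cum = np.cumsum(dcounts)
        j = int(np.searchsorted(cum, rng.integers(dcounts.sum()), side="right"))
        a_node = dnodes[j]
        half = config.n_descendant // 2
        desc_sample = [a_node] * (config.n_descendant - half) + [sel_node] * half
        truth["balanced_haplotypes"] = (a_node, sel_node)

    anc_mat, desc_mat, og = _materialize(
        rng, tree, L, anc_sample, desc_sample, og_node, n_og
    )
    anc, desc = _wrap(config, gene_id, anc_mat, desc_mat)
    return anc, desc, og.tobytes().decode("ascii"), truth


# -- codon-model simulation ------------------------------------------------


def _codon_rates(omega: float, kappa_R: float, kappa_Y: float):
    """Target codons and rates for every sense codon; normalized so the
    neutral expected substitution rate is ~1 per nucleotide site per unit
    branch length."""
    table = {}
    for codon in SENSE_CODONS:
        targets, rates = [], []
        aa = GENETIC_CODE[codon]
        for pos in range(3):
            for alt in "ACGT":
                if alt == codon[pos]:
                    continue
                mut = codon[:pos] + alt + codon[pos + 1:]
                if mut in STOP_CODONS:
                    continue
                cls = substitution_class(codon[pos], alt)
                r = kappa_R if cls == "tsR" else (kappa_Y if cls == "tsY" else 1.0)
                if GENETIC_CODE[mut] != aa:
                    r *= omega
                targets.append(mut)
                rates.append(r)
        table[codon] = (targets, np.array(rates))
    # normalization: mean total leave-rate per nucleotide site over sense codons
    rho = sum(table[c][1].sum() for c in SENSE_CODONS) / (len(SENSE_CODONS) * 3.0)
    return table, rho


def _evolve_codons(codons: list[str], branch_length: float, table, rho, rng):
    """Gillespie evolution of each codon independently for the branch."""
    out = []
    for codon in codons:
        cur = codon
        t = 0.0
        while True:
            targets, rates = table[cur]
            # normalized so a neutral sequence accrues ~1 sub/site/unit time
            total = rates.sum() / rho
            if total <= 0:
                break
            t += rng.exponential(1.0 / total)
            if t > branch_length:
                break
            k = rng.choice(len(targets), p=rates / rates.sum())
            cur = targets[k]
        out.append(cur)
    return out


def simulate_codon_pair(
    gene_length: int,
    omega: float,
    kappa_R: float = 1.0,
    kappa_Y: float = 1.0,
    branch_length: float = 0.1,
    seed: int = 0,
):
    """Two coding sequences diverged under a codon model.

    ``branch_length`` is the total expected substitutions per nucleotide
    site separating the pair under the neutral normalization.  No internal
    stop codons are generated (mutations into stops have rate zero).
    """
    if gene_length % 3 != 0:
        raise ConfigurationError("gene_length must be divisible by 3")
    if branch_length < 0:
        raise ConfigurationError("branch_length must be >= 0")
    rng = np.random.default_rng(seed)
    table, rho = _codon_rates(omega, kappa_R, kappa_Y)
    root = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS),
                                                  size=gene_length // 3)]
    a = _evolve_codons(root, branch_length / 2.0, table, rho, rng)
    b = _evolve_codons(root, branch_length / 2.0, table, rho, rng)
    return "".join(a), "".join(b)


def _simulate_positive_gene(config: SimulationConfig, rng, gene_id):
    """Codon gene with omega > 1 divergence between the two populations."""
    omega = config.positive_omega
    table, rho = _codon_rates(omega, 1.0, 1.0)
    ncod = config.gene_length // 3
    root = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=ncod)]
    wild = _evolve_codons(root, 0.05, table, rho, rng)
    land = _evolve_codons(wild, 0.05, table, rho, rng)
    og = _evolve_codons(root, 0.15, table, rho, rng)

    def population(consensus, n):
        rows = []
        for _ in range(n):
            tip = _evolve_codons(consensus, 0.002, table, rho, rng)
            rows.append(
                np.frombuffer("".join(tip).encode(), dtype=np.uint8)
            )
        return np.vstack(rows)

    anc_mat = population(wild, config.n_ancestral)
    desc_mat = population(land, config.n_descendant)
    anc, desc = _wrap(config, gene_id, anc_mat, desc_mat, feature="CDS")
    return anc, desc, "".join(og)


# -- whole-dataset generation ---------------------------------------------


GEOGRAPHIES_CYCLE = ("EastAfrica", "WestAfrica", "SouthAfrica", "Asia", "NewWorld")
RACES_CYCLE = ("caudatum", "durra", "guinea", "kafir", "complex")


def _panel_metadata(config: SimulationConfig, rng) -> SampleMetadata:
    anc_names, desc_names = _sample_names(config)
    table = {}
    for i, s in enumerate(anc_names):
        table[s] = ("WildWeedy",
                    GEOGRAPHIES_CYCLE[rng.integers(3)],  # wilds are African
                    "wild")
    for i, s in enumerate(desc_names):
        table[s] = ("Landrace",
                    GEOGRAPHIES_CYCLE[rng.integers(len(GEOGRAPHIES_CYCLE))],
                    RACES_CYCLE[rng.integers(len(RACES_CYCLE))])
    return SampleMetadata(table)


def generate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate the full labelled panel described by ``config``.

    Gene ids are ``g0001`` ... in regime order; genes are laid out head to
    tail on a synthetic chromosome with 10 kb spacing for sweep-extent
    analyses.  Identical config and seed give byte-identical output.
    """
    root_ss = np.random.SeedSequence(config.seed)
    gene_seeds = root_ss.spawn(config.n_genes + 1)
    meta_rng = np.random.default_rng(gene_seeds[-1])
    metadata = _panel_metadata(config, meta_rng)

    ancestral, descendant, outgroup = {}, {}, {}
    truth, truth_omega, positions = {}, {}, {}
    spacing = 10_000
    for i, regime in enumerate(config.regimes):
        gene_id = f"g{i + 1:04d}"
        seed = gene_seeds[i]
        rng_seed = int(seed.generate_state(1)[0] % (2**31))
        if regime == "neutral":
            anc, desc, og = simulate_neutral_gene(
                config, seed=rng_seed, gene_id=gene_id
            )
            truth[gene_id] = "neutral"
        else:
            anc, desc, og, rec = simulate_selected_gene(
                config, regime, seed=rng_seed, gene_id=gene_id
            )
            truth[gene_id] = regime
            if "omega" in rec:
                truth_omega[gene_id] = rec["omega"]
        ancestral[gene_id] = anc
        descendant[gene_id] = desc
        outgroup[gene_id] = og
        start = 1 + i * spacing
        positions[gene_id] = ("chr1", start, start + config.gene_length - 1)

    return SimulatedDataset(
        config=config,
        ancestral=ancestral,
        descendant=descendant,
        outgroup=outgroup,
        truth=truth,
        truth_omega=truth_omega,
        metadata=metadata,
        gene_positions=positions,
    )


def write_dataset(dataset: SimulatedDataset, outdir) -> None:
    """Write per-gene FASTA alignments, metadata TSV and the truth table."""
    import os

    from domscan.gene_io import write_alignment_fasta

    os.makedirs(outdir, exist_ok=True)
    for gid in dataset.gene_ids():
        write_alignment_fasta(
            dataset.combined(gid), os.path.join(outdir, f"{gid}.fasta")
        )
        with open(os.path.join(outdir, f"{gid}.outgroup.fasta"), "w") as fh:
            fh.write(f">outgroup\n{dataset.outgroup[gid]}\n")
    dataset.metadata.to_tsv(os.path.join(outdir, "metadata.tsv"))
    with open(os.path.join(outdir, "truth.tsv"), "w") as fh:
        fh.write("gene_id\tregime\tomega\n")
        for gid in dataset.gene_ids():
            om = dataset.truth_omega.get(gid, "")
            fh.write(f"{gid}\t{dataset.truth[gid]}\t{om}\n")
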