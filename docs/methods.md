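# Methods

`domscan` implements a domestication selection scan for a panel of
candidate genes resequenced in two population groups — a wild ancestral
group and a domesticated descendant group — plus an outgroup species for
divergence-based validation. This note documents the statistical models,
the synthetic-data generator that stands in for a real resequencing panel,
the numerical choices, and the known limitations.

## Diversity statistics

For each gene (and, where a coding model is available, each CDS) and each
population the package computes:

- **Nucleotide diversity θπ** (Nei–Li): the mean over all C(n,2) sequence
  pairs of per-pair differences divided by per-pair comparable sites.
  Missing data are handled by *pairwise deletion*: a site enters a pair's
  comparison only when both sequences carry a called base. Each pair is
  therefore normalised by its own usable length.
- **Watterson's estimator θω** = S / (a₁ L), where S counts sites with at
  least two distinct called bases, L counts sites with at least two called
  bases, and a₁ = Σ_{i=1}^{n−1} 1/i.
- **Tajima's D** with the standard constants (a₁, a₂, b₁, b₂, c₁, c₂, e₁,
  e₂). The mean pairwise difference count Π is the pairwise-deletion θπ
  scaled by the used length L, keeping the numerator consistent with θπ
  under missing data. A monomorphic gene (S = 0) has no defined D and is
  reported "NA".
- **Hudson-style F_ST** = 1 − H_w/H_b with H_w the unweighted mean of the
  two within-population θπ values and H_b the between-population mean
  pairwise difference per site (d_xy). When H_b = 0 the statistic is 0 by
  convention. Negative values (possible under this estimator) are reported
  as computed, because the classifier ranks raw values. The estimator
  choice is recorded in the run manifest.
- **Per-site statistics**: unbiased per-site diversity
  (n/(n−1))(1 − Σ p²) over called bases, per-site d_xy, and the per-site
  Hudson F_ST. Summing per-site numerators and denominators over a
  gap-free region reproduces the gene-level F_ST exactly; the test suite
  asserts this equivalence.

## Ka/Ks

Two pairwise estimators are provided.

**NG86** counts each codon as three mutation-opportunity sites split by the
fraction of its nine single-nucleotide neighbours that are synonymous
(changes into stop codons count as non-synonymous, so the three sites are
conserved). Codons differing at k > 1 positions average the
synonymous/non-synonymous classification over all k! substitution
orderings, skipping orderings that pass through a stop codon (falling back
to all orderings when every one does). Proportions are corrected with the
Jukes–Cantor transform d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 renders the
distance inestimable ("NA").

**MYN-style estimation** refines NG86 with distinct purine (κ_R) and
pyrimidine (κ_Y) transition weights under a Tamura–Nei substitution model:

1. κ_R and κ_Y are estimated by inverting the Tamura–Nei distance
   components computed from the pooled nucleotide mismatch proportions of
   the pair (the published protocol estimates them from degeneracy-classed
   sites; pooling all sites is this implementation's simplification,
   validated against the NG86 symmetric limit below).
2. Sites are counted weighting each possible change by its rate class
   (κ_R, κ_Y, or 1) and the position-specific frequency of the target
   nucleotide.
3. Differences are counted with pathway weighting: each stop-free ordering
   is weighted by the product of its steps' rate factors, with
   non-synonymous steps additionally weighted by the current ω.
4. Synonymous and non-synonymous distances are corrected with the
   Tamura–Nei multiple-hit formula; ω = Ka/Ks is updated and steps 3–4
   iterate until both Ka and Ks move by less than 1e-8 (at most 100
   rounds). Non-convergence or saturation is flagged on the result, never
   raised.

In the symmetric limit (κ = 1, uniform base composition) MYN reduces to
NG86 up to the distance correction; the suite asserts mean agreement within
10%. Significance of Ka ≠ Ks uses a two-sided Fisher exact test on the 2×2
table of rounded substitution counts against intact sites. The direction
rule is literal: ratio > 1 positive, < 1 purifying, = 1 (±1e-9) neutral,
inestimable "NA".

Population-level ratios are means over sequence pairs — within-group pairs
for the per-group columns, between-group pairs for the domestication
column — with the ratio formed from mean Ka and mean Ks (ratio of means),
which stays defined when many individual pairs have Ks = 0.

## Selection-signature classification

Gene-level calls use empirical quantiles over a configurable gene universe
(the analysed panel itself, or the panel pooled with a genome-wide
surrogate panel). Percentiles use inclusive rank — 100·#{x ≤ v}/N, ties
sharing the higher rank — which is deterministic and conservative in the
lower tail. With thresholds in percent (defaults in parentheses):

- **purifying**: descendant θπ and θω in the lower tail (5), F_ST above
  the upper quantile (95), and negative descendant Tajima's D. An
  *undefined* D (invariant descendant gene) satisfies the negative clause:
  total loss of diversity is the extreme of the signature, and the
  published gene tables call such genes purifying.
- **balancing**: descendant θπ and θω in the upper quartile (75), D in the
  upper tail (95), and F_ST strictly inside the (10, 90) band.

Purifying is evaluated first; the disjoint diversity bands make double
calls impossible. Site-level calls compare the per-site diversity change
(descendant − ancestral) against the mean per-gene diversity-change
magnitude of the background set, require per-site F_ST > 0, and take the
D-sign clause at gene level in the descendant population, since a per-site
D is not meaningful. Site calls in coding regions are annotated as
synonymous or non-synonymous by translating the variant allele in the
majority codon context, with non-synonymous residues classed as nonpolar /
polar / acidic / basic.

Sweep extents are delimited by extending from a purifying gene in 10-kb
steps while window descendant θπ stays below the genome lower-5% quantile;
the kb span and overlapped genes are reported. The delimitation algorithm
is this package's own construction (published spans name no method).

## HKA-family validation

Candidate genes are validated against a neutral locus panel by contrasting
within-species polymorphism S with divergence D to the outgroup, counted
between the outgroup sequence and the within-species majority consensus
(polymorphic sites still count toward S, avoiding double counting).

The **classic moment test** solves E[S_i] = θ_i a₁(n_i) L_i and
E[D_i] = θ_i L_i (τ+1) by fixed point and sums the standardised squared
deviations with the neutral coalescent variances
Var[S] = E[S] + (θ_i L_i)² a₂(n_i) and Var[D] = E[D] + (θ_i L_i)²;
X² is referred to χ² with 2·L − (L+1) degrees of freedom. Simulation-based
calibration uses exact-coalescent panels (msprime, one ingroup population
plus an outgroup split at τ): at the package defaults (10 loci of 1.5 kb,
n = 14, θ = 0.006, τ = 5) the suite verifies that the rejection rate at
the 5% level lies in [0.02, 0.09] (measured ≈ 0.04). Forward-simulated panels with modest haplotype counts show
slightly deflated deep-branch variance (a discrete-generation effect), so
the calibration substrate is the coalescent sampler, which matches the
test's distributional assumptions exactly.

The **likelihood-ratio variant** models S_i ~ Poisson(k_i θ_i a₁ L_i) and
D_i ~ Poisson(θ_i L_i (τ+1)) with a free selection parameter k_i > 0 at
designated loci (k < 1: polymorphism deficit, as after a sweep; k > 1:
excess). The original formulation samples this model by MCMC; this package
maximises the same likelihood deterministically — θ_i and k_i have
closed-form conditional maxima, leaving a bounded one-dimensional profile
search over τ run from five geometric starting points. The LRT
2(logL₁ − logL₀) is referred to χ² with df = number of selected loci.
Because the Poisson observation model ignores the coalescent
overdispersion of S (a factor of ~5 at θL ≈ 9), the LRT is calibrated
under its own observation law, where its type-I error is nominal (≈ 0.05 measured at the defaults);
against full coalescent/forward-simulated data it is anticonservative and
its p-values should be read as relative evidence, not frequentist error
rates. This is a known property of moment-style Poisson approximations and
is inherited from the model choice, which trades exactness for
deterministic desk-scale behaviour.

## Haplotype networks

Columns containing any N or gap are removed before collapsing (complete
deletion) so haplotype identity is transitive — deliberately different
from the pairwise deletion used by the diversity statistics. Haplotypes
are ordered canonically (descending frequency, then sequence), which makes
ids and tie-breaking independent of input order. The network is a minimum
spanning tree (Kruskal, ties broken by haplotype order) plus every
non-tree edge whose length equals the maximum edge on the tree path
between its endpoints, flagged as an alternative link — a minimum spanning
network in the usual sense. Exports are JSON and DOT; node size encodes
carrier count and per-node composition can be stratified by population
group, geography, or race.

## The synthetic panel generator

No desk-scale public dataset reproduces the original panel, so the
generator emulates its statistical structure with exact truth labels:

- **Demography.** A haploid Wright–Fisher population of 2N lineages
  (N = 100 diploids) at mutation–drift equilibrium (burn-in 16N
  generations; long enough that deep-branch variance is unbiased at the
  outgroup branch point), with per-site mutation rate μ = 1.5e-5
  (θ = 4Nμ = 0.006, in the range of per-gene diversities the scan
  targets). The descendant population is founded 50 generations before
  sampling at fraction 0.25 of N and sampled at the end of the bottleneck.
  These values solve the transient-heterozygosity equation
  π_t = θ_b + (π_0 − θ_b)e^{−t/2N_b} for the ~1.7-fold genome-wide
  diversity reduction expected of a domestication bottleneck; replicate
  means land at 1.6–1.9-fold. Samples default to 14 ancestral and 36
  descendant haplotypes, mirroring a panel of 7 wild and 18 domesticated
  inbred (effectively homozygous) accessions.
- **Mutation.** Infinite sites for non-coding genes: every mutation hits a
  fresh position; positions are assigned after sampling so only mutations
  visible in the sample consume sites.
- **Outgroup.** A single lineage copied out of the ancestral population
  1000 generations (τ = 5) before sampling, accumulating Poisson(μLT)
  private mutations — a true outgroup well outside the within-species
  coalescent, as appropriate for a sister species.
- **Selection regimes** are imposed phenomenologically so truth labels are
  exact, not inferred. The selected allele in both non-neutral regimes is
  an *old lineage*: a snapshot taken 800 generations back plus its private
  mutations since. A purifying gene undergoes a complete post-bottleneck
  sweep of that lineage (descendant-invariant, matching the published
  swept genes); a balancing gene maintains the common extant class and the
  old allele at ~50/50 in the descendant sample. The allele-age choice is
  substantive: a sweep of a run-of-the-mill recent haplotype is
  statistically indistinguishable from neutral post-bottleneck drift at
  this panel size, whereas callable selection signatures involve
  haplotypes well differentiated from the extant wild pool (deep standing
  variation or wild introgression, both documented in crop domestication).
  A positive-selection gene is coding and evolves under a Goldman–Yang-style
  codon model with ω = 3 between the two population consensuses, with
  small within-population codon variation on top.
- **Codon pairs** for estimator tests evolve each codon independently by
  Gillespie simulation under rates κ-weighted by substitution class and
  multiplied by ω for non-synonymous changes, normalised so one unit of
  branch length is one expected substitution per site under neutrality;
  mutations into stop codons have rate zero.

What the generator does **not** emulate: within-gene recombination,
linkage between genes, indels and alignment error, genotype-calling error
and missingness patterns, population structure within groups, and gene
conversion. Passing recovery tests on these panels therefore demonstrates
the correctness and calibration of the statistical machinery under the
stated model, not performance on real resequencing data — in particular,
the no-recombination choice makes per-gene statistics noisier than real
multi-kilobase genes, which is the conservative direction for classifier
calibration.

## Reporting conventions

Statistics print at six decimal places with "NA" for undefined values.
Fold changes are rounded to one decimal; headline percentages are
truncated (not rounded) to one decimal, matching common reporting practice
for "x% of genes" statements. Empirical backgrounds include the gene being
classified (self-inclusive ranking, recorded in the manifest). All
randomness flows from a single seed through `numpy.random.SeedSequence`;
identical configuration and seed give byte-identical reports, and the run
manifest records package version, seed, thresholds, and estimator choices.

## Known limitations

- The mlHKA-style LRT inherits the Poisson observation model's
  anticonservatism on coalescent data (see above).
- MYN's κ estimation pools all sites rather than degeneracy classes; at
  extreme base-composition skew or very high divergence the distances will
  drift from the published protocol's.
- The sweep delimiter assumes a dense, regularly spaced gene layout when
  run on synthetic panels; on sparse real annotations its spans are lower
  bounds.
- Population-level Ka/Ks pairing (ratio of mean Ka to mean Ks over pairs)
  is one of several defensible aggregation schemes; alternatives (mean of
  ratios, concatenated pairs) can differ when divergence is very low.
- Heterozygous VCF genotypes are resolved to the first-listed allele with
  a warning — adequate for inbred panels, wrong for outbred data.
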