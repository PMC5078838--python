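"""HKA-family tests: classic moment/chi-square HKA and a likelihood-ratio
test with a per-locus selection parameter.

Both tests contrast within-species polymorphism (S, segregating sites) with
divergence to an outgroup (D, differences between the outgroup sequence and
the within-species majority consensus) across loci.  Under neutrality the
two are proportional locus by locus; a selected locus shows an excess or
deficit of polymorphism captured by the parameter k (k < 1: deficit, as
after a sweep; k > 1: excess, as under balancing selection).

The likelihood version models S_i ~ Poisson(k_i * theta_i * a1(n_i) * L_i)
and D_i ~ Poisson(theta_i * L_i * (tau + 1)), with k_i = 1 at neutral loci.
The original formulation samples the posterior by MCMC; this implementation
maximizes the same likelihood deterministically — theta_i and k_i have
closed-form conditional maxima, leaving a bounded one-dimensional profile
search over tau run from multiple starts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from domscan.diversity_stats import harmonic_a1, harmonic_a2


class DegenerateDataError(ValueError):
    """All-zero counts: no information to fit."""


class FittingError(RuntimeError):
    """No optimization start converged."""


@dataclass(frozen=True)
class LocusCounts:
    """Polymorphism and divergence summary for one locus."""

    locus_id: str
    n: int  # within-species sample size
    L: int  # sites
    S: int  # segregating sites within species
    D: float  # divergence differences to the outgroup
    selected_flag: bool = False

    def __post_init__(self):
        if self.S < 0 or self.D < 0 or self.L <= 0 or self.n < 2:
            raise ValueError(f"{self.locus_id}: invalid counts")
        if self.S > self.L or self.D > self.L:
            raise ValueError(f"{self.locus_id}: counts exceed locus length")


@dataclass
class HkaModel:
    """Parameters of the HKA observation model."""

    theta: dict[str, float]  # per-locus scaled mutation parameter (per site)
    tau: float  # scaled divergence time
    k: dict[str, float]  # selection parameter; 1 for neutral loci

    def __post_init__(self):
        if self.tau <= 0 or any(t <= 0 for t in self.theta.values()) or any(
            v <= 0 for v in self.k.values()
        ):
            raise ValueError("theta_i, tau and k_i must all be positive")


def count_locus(aln, outgroup_seq: str, locus_id: str = "",
                selected_flag: bool = False) -> LocusCounts:
    """Build LocusCounts from an alignment and an outgroup sequence.

    D is counted between the outgroup and the within-species majority
    consensus; polymorphic sites still count toward S (no double counting
    of a site in both S and D unless the consensus itself differs).
    """
    from domscan.diversity_stats import _BASE_CODES, base_counts, segregating_sites

    S, L = segregating_sites(aln)
    og = np.frombuffer(outgroup_seq.upper().encode(), dtype=np.uint8)
    if len(og) != aln.length:
        raise ValueError("outgroup length does not match alignment")
    counts = base_counts(aln)
    called = counts.sum(axis=0) > 0
    # majority consensus; ties resolved toward the lexically smallest base
    cons = _BASE_CODES[np.argmax(counts, axis=0)]
    og_called = np.isin(og, _BASE_CODES)
    D = int((called & og_called & (og != cons)).sum())
    return LocusCounts(
        locus_id=locus_id or aln.gene_id, n=aln.n, L=L, S=S, D=D,
        selected_flag=selected_flag,
    )


def sample_locus_counts(
    model: HkaModel,
    sizes: dict[str, tuple[int, int]],
    rng: np.random.Generator,
    selected: set[str] | frozenset[str] = frozenset(),
) -> list[LocusCounts]:
    """Draw (S, D) panels from the HKA observation model.

    ``sizes`` maps locus_id -> (n, L).  Used for simulation-based
    calibration and parameter-recovery checks of the likelihood machinery.
    """
    out = []
    for locus_id, (n, L) in sizes.items():
        th = model.theta[locus_id]
        k = model.k.get(locus_id, 1.0)
        S = int(rng.poisson(k * th * harmonic_a1(n) * L))
        D = int(rng.poisson(th * L * (model.tau + 1.0)))
        out.append(
            LocusCounts(
                locus_id=locus_id, n=n, L=L, S=min(S, L), D=min(D, L),
                selected_flag=locus_id in selected,
            )
        )
    return out


def coalescent_neutral_panel(
    n_loci: int,
    n: int,
    L: int,
    theta: float,
    tau: float,
    rng: np.random.Generator,
) -> list[LocusCounts]:
    """Neutral (S, D) panel under the exact Kingman coalescent with outgroup.

    One ingroup population of sample size ``n`` haplotypes and a single
    outgroup haplotype that split ``tau`` (units of 2N generations) ago;
    ``theta`` is the per-site population mutation rate.  D is counted
    against the ingroup majority consensus, matching :func:`count_locus`.
    This sampler matches the distributional assumptions of the classic
    moment test exactly (no discrete-generation artefacts) and is the
    substrate for its statistical calibration.
    """
    import msprime

    M = 2000  # haploid population size (arbitrary scale; theta = 2*M*mu)
    mu = theta / (2 * M)
    dem = msprime.Demography()
    dem.add_population(name="ing", initial_size=M)
    dem.add_population(name="out", initial_size=M)
    dem.add_population(name="anc", initial_size=M)
    # one coalescent unit (2N diploid generations) = M haploid generations
    dem.add_population_split(time=tau * M, derived=["ing", "out"],
                             ancestral="anc")
    loci = []
    for i in range(n_loci):
        ts = msprime.sim_ancestry(
            samples={"ing": n, "out": 1}, demography=dem, sequence_length=L,
            ploidy=1, recombination_rate=0,
            random_seed=int(rng.integers(1, 2**31)),
        )
        ts = msprime.sim_mutations(
            ts, rate=mu, random_seed=int(rng.integers(1, 2**31))
        )
        G = ts.genotype_matrix()
        ing, out = G[:, :n], G[:, n]
        S = int((ing.max(axis=1) != ing.min(axis=1)).sum())
        D = 0
        for row, o in zip(ing, out):
            vals, cnt = np.unique(row, return_counts=True)
            if vals[np.argmax(cnt)] != o:
                D += 1
        loci.append(
            LocusCounts(locus_id=f"L{i}", n=n, L=L, S=min(S, L), D=min(D, L))
        )
    return loci


# -- classic HKA -----------------------------------------------------------


def classic_hka(loci: list[LocusCounts]) -> tuple[float, int, float]:
    """Classic moment/chi-square HKA test.

    Moment estimates solve E[S_i] = theta_i a1(n_i) L_i and
    E[D_i] = theta_i L_i (tau + 1) by fixed point; the statistic sums the
    standardized squared deviations of every S_i and D_i with the neutral
    coalescent variances Var[S] = E[S] + (theta_i L_i)^2 a2(n_i) and
    Var[D] = E[D] + (theta_i L_i)^2; df = 2 * n_loci - (n_loci + 1).

    Returns (X2, df, p).
    """
    if len(loci) < 2:
        raise ValueError("classic HKA needs at least 2 loci")
    if all(l.S == 0 and l.D == 0 for l in loci):
        raise DegenerateDataError("all loci have zero counts")
    a1 = {l.locus_id: harmonic_a1(l.n) for l in loci}
    a2 = {l.locus_id: harmonic_a2(l.n) for l in loci}

    tau = 1.0
    theta = {l.locus_id: max(l.S + l.D, 0.5) / (l.L * (a1[l.locus_id] + 2.0))
             for l in loci}
    for _ in range(200):
        theta_new = {
            l.locus_id: max(l.S + l.D, 1e-9)
            / (l.L * (a1[l.locus_id] + tau + 1.0))
            for l in loci
        }
        denom = sum(theta_new[l.locus_id] * l.L for l in loci)
        tau_new = sum(l.D for l in loci) / denom - 1.0
        tau_new = max(tau_new, 1e-6)
        if abs(tau_new - tau) < 1e-12 and all(
            abs(theta_new[k] - theta[k]) < 1e-15 for k in theta
        ):
            theta, tau = theta_new, tau_new
            break
        theta, tau = theta_new, tau_new

    x2 = 0.0
    for l in loci:
        th = theta[l.locus_id]
        es = th * a1[l.locus_id] * l.L
        ed = th * l.L * (tau + 1.0)
        var_s = es + (th * l.L) ** 2 * a2[l.locus_id]
        var_d = ed + (th * l.L) ** 2
        if var_s > 0:
            x2 += (l.S - es) ** 2 / var_s
        if var_d > 0:
            x2 += (l.D - ed) ** 2 / var_d
    df = 2 * len(loci) - (len(loci) + 1)
    p = float(stats.chi2.sf(x2, df))
    return float(x2), df, p


# -- likelihood HKA --------------------------------------------------------


def _poisson_logpmf(x: float, mean: float) -> float:
    if mean <= 0.0:
        return 0.0 if x == 0 else float("-inf")
    return x * math.log(mean) - mean - math.lgamma(x + 1.0)


def mlhka_loglik(model: HkaModel, loci: list[LocusCounts]) -> float:
    """Log-likelihood of the Poisson observation model.

    A zero expectation with a nonzero count yields -inf (returned, not
    raised).
    """
    ll = 0.0
    for l in loci:
        k = model.k.get(l.locus_id, 1.0)
        th = model.theta[l.locus_id]
        ll += _poisson_logpmf(l.S, k * th * harmonic_a1(l.n) * l.L)
        ll += _poisson_logpmf(l.D, th * l.L * (model.tau + 1.0))
    return ll


_K_BOUNDS = (1e-3, 1e3)


def _profile_loglik(tau: float, loci: list[LocusCounts],
                    selected: set[str]) -> tuple[float, dict, dict]:
    """Maximize over theta_i (and k_i at selected loci) for fixed tau.

    Neutral locus:  theta_i = (S_i + D_i) / (L_i (a1 + tau + 1)).
    Selected locus: theta_i = D_i / (L_i (tau + 1)) and
                    k_i = S_i / (theta_i a1 L_i), both clipped to bounds.
    """
    theta, kk = {}, {}
    for l in loci:
        a1 = harmonic_a1(l.n)
        if l.locus_id in selected:
            th = max(l.D, 0.5) / (l.L * (tau + 1.0))
            k = l.S / (th * a1 * l.L) if th > 0 else _K_BOUNDS[1]
            kk[l.locus_id] = min(max(k, _K_BOUNDS[0]), _K_BOUNDS[1])
        else:
            th = max(l.S + l.D, 1e-9) / (l.L * (a1 + tau + 1.0))
            kk[l.locus_id] = 1.0
        theta[l.locus_id] = max(th, 1e-12)
    model = HkaModel(theta=theta, tau=tau, k=kk)
    return mlhka_loglik(model, loci), theta, kk


def _maximize(loci: list[LocusCounts], selected: set[str],
              n_starts: int = 5) -> tuple[float, HkaModel, list[float]]:
    """Bounded multi-start maximization of the profile likelihood over tau."""
    starts = list(np.geomspace(0.05, 50.0, n_starts))
    best = (-math.inf, None)
    bounds = (1e-4, 1e4)
    for s in starts:
        lo = max(bounds[0], s / 10.0)
        hi = min(bounds[1], s * 10.0)
        res = optimize.minimize_scalar(
            lambda t: -_profile_loglik(t, loci, selected)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if res.success and -res.fun > best[0]:
            best = (-res.fun, float(res.x))
    if best[1] is None:
        raise FittingError("no optimization start converged")
    ll, theta, kk = _profile_loglik(best[1], loci, selected)
    return ll, HkaModel(theta=theta, tau=best[1], k=kk), starts


def fit_and_test(
    loci: list[LocusCounts], selected_ids: list[str]
) -> dict:
    """mlHKA-style likelihood-ratio test.

    Fits the neutral model (all k_i = 1) and the selection model (free
    k_i > 0 at ``selected_ids``); the LRT statistic 2(logL1 - logL0) is
    referred to chi-square with df = number of selected loci.

    Returns a dict with logL0, logL1, lrt, df, p, tau0, tau1, k_hat.
    """
    ids = {l.locus_id for l in loci}
    unknown = set(selected_ids) - ids
    if unknown:
        raise ValueError(f"selected ids not among loci: {sorted(unknown)}")
    ll0, model0, _ = _maximize(loci, set())
    if not selected_ids:
        return {
            "logL0": ll0, "logL1": ll0, "lrt": 0.0, "df": 0, "p": 1.0,
            "tau0": model0.tau, "tau1": model0.tau, "k_hat": {},
        }
    ll1, model1, _ = _maximize(loci, set(selected_ids))
    lrt = max(0.0, 2.0 * (ll1 - ll0))
    df = len(selected_ids)
    p = float(stats.chi2.sf(lrt, df))
    return {
        "logL0": ll0,
        "logL1": ll1,
        "lrt": lrt,
        "df": df,
        "p": p,
        "tau0": model0.tau,
        "tau1": model1.tau,
        "k_hat": {i: model1.k[i] for i in selected_ids},
    }
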