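"""Within- and between-population diversity statistics.

All per-site quantities use pairwise deletion: a site contributes to a
sequence pair's comparison only when both members carry a called base
(not N, not a gap).  theta-pi is the mean over sample pairs of
(differences / comparable sites), so each pair is normalized by its own
usable length.  Watterson's theta and Tajima's D count a site as used when
at least two non-missing calls are present.

Undefined statistics (Tajima's D on a monomorphic gene, F_ST with zero
between-population diversity at a site) are returned as NaN and rendered
"NA" by the table writer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from domscan.gene_io import HaplotypeAlignment


class InsufficientSamplesError(ValueError):
    """Fewer sequences than the statistic requires."""


@dataclass
class DiversitySummary:
    """Per-gene, per-population summary row."""

    gene_id: str
    population: str
    n: int
    L: int
    S: int
    pi: float
    theta_w: float
    tajimas_d: float  # NaN when undefined (S == 0)


@dataclass
class PairwisePopStats:
    """Between-population summary for one gene and one population pair."""

    gene_id: str
    pop_a: str
    pop_b: str
    fst: float
    dxy: float
    fold_change: float  # pi_a / pi_b; inf when pi_b == 0 < pi_a; NaN for 0/0


# -- internal helpers -----------------------------------------------------


def _called_mask(aln: HaplotypeAlignment) -> np.ndarray:
    return ~aln.missing_mask()


def _pair_diff_stats(mat: np.ndarray, called: np.ndarray):
    """Per-pair (differences, comparable sites) over all sample pairs.

    Returns two arrays of length C(n, 2) in (i < j) lexicographic order.
    """
    n = mat.shape[0]
    diffs, comps = [], []
    for i in range(n - 1):
        both = called[i] & called[i + 1:]
        d = (mat[i] != mat[i + 1:]) & both
        diffs.extend(d.sum(axis=1).tolist())
        comps.extend(both.sum(axis=1).tolist())
    return np.array(diffs, dtype=float), np.array(comps, dtype=float)


def harmonic_a1(n: int) -> float:
    """a1 = sum_{i=1}^{n-1} 1/i."""
    return float(sum(1.0 / i for i in range(1, n)))


def harmonic_a2(n: int) -> float:
    """a2 = sum_{i=1}^{n-1} 1/i^2."""
    return float(sum(1.0 / (i * i) for i in range(1, n)))


_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


def base_counts(aln: HaplotypeAlignment) -> np.ndarray:
    """(4, L) counts of A, C, G, T per site (missing calls excluded)."""
    return np.stack([(aln.matrix == b).sum(axis=0) for b in _BASE_CODES])


def segregating_sites(aln: HaplotypeAlignment) -> tuple[int, int]:
    """(S, L): S = sites with >=2 distinct non-missing bases,
    L = sites with >=2 non-missing calls."""
    counts = base_counts(aln)
    ncalled = counts.sum(axis=0)
    usable = ncalled >= 2
    L = int(usable.sum())
    S = int((((counts > 0).sum(axis=0) >= 2) & usable).sum())
    return S, L


# -- operations -----------------------------------------------------------


def nucleotide_diversity(aln: HaplotypeAlignment) -> float:
    """Per-site nucleotide diversity theta-pi (Nei & Li form).

    Mean over all C(n,2) sample pairs of per-pair differences divided by
    per-pair comparable sites; pairs with zero comparable sites are skipped.
    """
    if aln.n < 2:
        raise InsufficientSamplesError("theta-pi requires n >= 2")
    diffs, comps = _pair_diff_stats(aln.matrix, _called_mask(aln))
    ok = comps > 0
    if not ok.any():
        return 0.0
    return float(np.mean(diffs[ok] / comps[ok]))


def watterson_theta(aln: HaplotypeAlignment) -> float:
    """Per-site Watterson estimator: S / (a1 * L)."""
    if aln.n < 2:
        raise InsufficientSamplesError("Watterson's theta requires n >= 2")
    S, L = segregating_sites(aln)
    if S == 0 or L == 0:
        return 0.0
    return S / (harmonic_a1(aln.n) * L)


def tajimas_d(aln: HaplotypeAlignment) -> float:
    """Tajima's D; NaN when the gene is monomorphic (S = 0).

    Pi (mean pairwise difference count, not per site) is the
    pairwise-deletion theta-pi scaled to the used length L, keeping the
    numerator consistent with theta-pi under missing data.
    """
    if aln.n < 3:
        raise InsufficientSamplesError("Tajima's D requires n >= 3")
    n = aln.n
    S, L = segregating_sites(aln)
    if S == 0:
        return float("nan")
    pi_site = nucleotide_diversity(aln)
    big_pi = pi_site * L
    a1 = harmonic_a1(n)
    a2 = harmonic_a2(n)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (big_pi - S / a1) / math.sqrt(var)


def dxy(aln_a: HaplotypeAlignment, aln_b: HaplotypeAlignment) -> float:
    """Per-site mean between-population pairwise difference (pairwise deletion)."""
    if aln_a.length != aln_b.length:
        raise ValueError("alignments must cover the same region")
    ca, cb = _called_mask(aln_a), _called_mask(aln_b)
    vals = []
    for i in range(aln_a.n):
        both = ca[i] & cb
        d = (aln_a.matrix[i] != aln_b.matrix) & both
        comp = both.sum(axis=1)
        ok = comp > 0
        vals.extend((d.sum(axis=1)[ok] / comp[ok]).tolist())
    if not vals:
        return 0.0
    return float(np.mean(vals))


def hudson_fst(aln_a: HaplotypeAlignment, aln_b: HaplotypeAlignment) -> float:
    """Hudson-style F_ST = 1 - H_w / H_b for two populations.

    H_w is the unweighted mean of the two within-population per-site
    diversities; H_b is d_xy.  Returns 0 when H_b = 0 (both populations
    identical and monomorphic).  Values below 0 are reported as computed.
    """
    if aln_a.n < 2 or aln_b.n < 2:
        raise InsufficientSamplesError("Hudson F_ST requires n >= 2 per population")
    hw = 0.5 * (nucleotide_diversity(aln_a) + nucleotide_diversity(aln_b))
    hb = dxy(aln_a, aln_b)
    if hb == 0.0:
        return 0.0
    return 1.0 - hw / hb


def _per_site_within(aln: HaplotypeAlignment) -> np.ndarray:
    """Unbiased per-site diversity (n/(n-1)) * (1 - sum p^2) on non-missing calls.

    Sites with fewer than two calls are NaN.
    """
    counts = base_counts(aln).astype(float)
    m = counts.sum(axis=0)
    out = np.full(aln.length, np.nan)
    ok = m >= 2
    p2 = np.zeros(aln.length)
    p2[ok] = (counts[:, ok] ** 2).sum(axis=0) / m[ok] ** 2
    out[ok] = (m[ok] / (m[ok] - 1.0)) * (1.0 - p2[ok])
    return out


def _per_site_dxy(aln_a: HaplotypeAlignment, aln_b: HaplotypeAlignment) -> np.ndarray:
    """Per-site probability that one allele from each population differs."""
    ca = base_counts(aln_a).astype(float)
    cb = base_counts(aln_b).astype(float)
    ma, mb = ca.sum(axis=0), cb.sum(axis=0)
    out = np.full(aln_a.length, np.nan)
    ok = (ma > 0) & (mb > 0)
    same = (ca[:, ok] / ma[ok] * cb[:, ok] / mb[ok]).sum(axis=0)
    out[ok] = 1.0 - same
    return out


def per_site_stats(
    aln_a: HaplotypeAlignment, aln_b: HaplotypeAlignment
) -> dict[str, np.ndarray]:
    """Per-site within-population diversities, d_xy, and Hudson F_ST.

    Returns arrays keyed ``div_a``, ``div_b``, ``dxy``, ``fst``.  A site
    missing in a whole population is NaN throughout; a site with H_b = 0 has
    F_ST = 0 (matching the gene-level rule).
    """
    if aln_a.length != aln_b.length:
        raise ValueError("alignments must cover the same region")
    div_a = _per_site_within(aln_a)
    div_b = _per_site_within(aln_b)
    hb = _per_site_dxy(aln_a, aln_b)
    hw = 0.5 * (div_a + div_b)
    fst = np.full(aln_a.length, np.nan)
    defined = ~np.isnan(hw) & ~np.isnan(hb)
    zero_hb = defined & (hb == 0.0)
    pos_hb = defined & (hb > 0.0)
    fst[zero_hb] = 0.0
    fst[pos_hb] = 1.0 - hw[pos_hb] / hb[pos_hb]
    return {"div_a": div_a, "div_b": div_b, "dxy": hb, "fst": fst}


def fold_change(pi_a: float, pi_b: float) -> float:
    """Diversity ratio pi_a / pi_b.

    Returns inf when pi_b = 0 with pi_a > 0, NaN for 0/0; report rounded to
    one decimal place.  Negative inputs are a domain error.
    """
    if pi_a < 0 or pi_b < 0:
        raise ValueError("diversities must be non-negative")
    if pi_b == 0.0:
        return float("inf") if pi_a > 0 else float("nan")
    return pi_a / pi_b


def summarize_gene(
    aln: HaplotypeAlignment, gene_id: str | None = None, population: str | None = None
) -> DiversitySummary:
    """Bundle S, L, theta-pi, Watterson's theta and Tajima's D for one gene."""
    S, L = segregating_sites(aln)
    return DiversitySummary(
        gene_id=gene_id if gene_id is not None else aln.gene_id,
        population=population if population is not None else (
            aln.population_labels[0] if aln.population_labels else ""
        ),
        n=aln.n,
        L=L,
        S=S,
        pi=nucleotide_diversity(aln),
        theta_w=watterson_theta(aln),
        tajimas_d=tajimas_d(aln) if aln.n >= 3 else float("nan"),
    )


def summarize_pair(
    aln_a: HaplotypeAlignment,
    aln_b: HaplotypeAlignment,
    gene_id: str = "",
    pop_a: str = "",
    pop_b: str = "",
) -> PairwisePopStats:
    return PairwisePopStats(
        gene_id=gene_id or aln_a.gene_id,
        pop_a=pop_a or (aln_a.population_labels[0] if aln_a.population_labels else "a"),
        pop_b=pop_b or (aln_b.population_labels[0] if aln_b.population_labels else "b"),
        fst=hudson_fst(aln_a, aln_b),
        dxy=dxy(aln_a, aln_b),
        fold_change=fold_change(nucleotide_diversity(aln_a), nucleotide_diversity(aln_b)),
    )
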