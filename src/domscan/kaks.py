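"""Pairwise Ka/Ks estimation (NG86 and MYN) and selection-direction calls.

NG86 counts synonymous/non-synonymous sites as physical mutation
opportunities (each codon contributes three sites split by the fraction of
synonymous single-nucleotide neighbours) and averages multi-hit codons over
all substitution pathways, skipping pathways through stop codons.  Distances
are Jukes-Cantor corrected.

MYN refines this with distinct purine (kappa_R) and pyrimidine (kappa_Y)
transition weights estimated from the data under a Tamura-Nei substitution
model: sites are counted weighted by mutation rates and position-specific
target-nucleotide frequencies, pathways are weighted by their model
probability, and the synonymous/non-synonymous distances are corrected with
the Tamura-Nei multi-hit formula.  Iteration alternates between the omega
used for pathway weighting and the resulting (Ka, Ks) until both change by
less than 1e-8 (at most 100 rounds); non-convergence is flagged on the
result, never raised.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

BASES = "TCAG"
CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]

# standard genetic code, the only table exercised by this package
GENETIC_CODE = dict(
    zip(
        CODONS,
        "FFLLSSSSYY**CC*W"
        "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG",
    )
)
STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


class FrameError(ValueError):
    """Sequence length not divisible by 3."""


class StopCodonError(ValueError):
    """Internal stop codon in a coding sequence."""


def substitution_class(a: str, b: str) -> str:
    """'tsR' (purine transition), 'tsY' (pyrimidine transition), or 'tv'."""
    if a in PURINES and b in PURINES:
        return "tsR"
    if a in PYRIMIDINES and b in PYRIMIDINES:
        return "tsY"
    return "tv"


@dataclass
class KaKsResult:
    """Ka, Ks, their ratio and supporting counts for one sequence pair."""

    ka: float
    ks: float
    ratio: float  # NaN when Ks == 0 or a distance is inestimable
    method: str
    syn_sites: float = 0.0
    nonsyn_sites: float = 0.0
    syn_diffs: float = 0.0
    nonsyn_diffs: float = 0.0
    kappa_R: float = float("nan")
    kappa_Y: float = float("nan")
    p_value: float = float("nan")
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)


# -- codon alignment preparation ------------------------------------------


def _clean_codon_pairs(cds_a: str, cds_b: str) -> list[tuple[str, str]]:
    """Split into codon pairs, dropping (from both) codons with gaps or N.

    Raises on frame violations and on internal stop codons in either clean
    codon.  A trailing stop codon pair is dropped silently.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) != len(cds_b):
        raise FrameError("coding sequences must have equal aligned length")
    if len(cds_a) % 3 != 0:
        raise FrameError(f"length {len(cds_a)} not divisible by 3")
    pairs = []
    ncod = len(cds_a) // 3
    for i in range(ncod):
        ca = cds_a[3 * i: 3 * i + 3]
        cb = cds_b[3 * i: 3 * i + 3]
        if any(ch not in "ACGT" for ch in ca + cb):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            if i == ncod - 1:
                continue
            raise StopCodonError(f"internal stop codon at codon {i + 1}")
        pairs.append((ca, cb))
    return pairs


# -- NG86 ------------------------------------------------------------------


def _ng86_codon_sites(codon: str) -> float:
    """Synonymous site count of one codon: fraction of the 9 single-nt
    neighbours that are synonymous, scaled to 3 sites.  Changes to stop
    codons count as non-synonymous."""
    aa = GENETIC_CODE[codon]
    syn = 0.0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1:]
            if mut not in STOP_CODONS and GENETIC_CODE[mut] == aa:
                syn += 1.0
    return syn / 3.0


def _pathways(ca: str, cb: str) -> list[list[tuple[str, str, int]]]:
    """All orderings of the differing positions as step lists.

    Each step is (codon_before, codon_after, position).
    """
    diff = [i for i in range(3) if ca[i] != cb[i]]
    paths = []
    for order in itertools.permutations(diff):
        cur = ca
        steps = []
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            steps.append((cur, nxt, pos))
            cur = nxt
        paths.append(steps)
    return paths


def _path_valid(steps) -> bool:
    """A pathway is valid when no intermediate codon is a stop codon."""
    return all(after not in STOP_CODONS for _, after, _ in steps[:-1])


def count_ng86(cds_a: str, cds_b: str) -> tuple[float, float, float, float]:
    """NG86 site and difference counts.

    Returns (syn_sites, nonsyn_sites, syn_diffs, nonsyn_diffs).  Site counts
    are averaged over the two sequences; multi-hit codons average the
    synonymous/non-synonymous classification over all substitution orderings
    that avoid stop codons (all orderings when every one passes through a
    stop).
    """
    pairs = _clean_codon_pairs(cds_a, cds_b)
    syn_sites = nonsyn_sites = syn_diffs = nonsyn_diffs = 0.0
    for ca, cb in pairs:
        s = 0.5 * (_ng86_codon_sites(ca) + _ng86_codon_sites(cb))
        syn_sites += s
        nonsyn_sites += 3.0 - s
        if ca == cb:
            continue
        paths = _pathways(ca, cb)
        usable = [p for p in paths if _path_valid(p)] or paths
        sd = nd = 0.0
        for steps in usable:
            for before, after, _pos in steps:
                if GENETIC_CODE[before] == GENETIC_CODE[after]:
                    sd += 1.0
                else:
                    nd += 1.0
        syn_diffs += sd / len(usable)
        nonsyn_diffs += nd / len(usable)
    return syn_sites, nonsyn_sites, syn_diffs, nonsyn_diffs


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction; NaN when p >= 3/4 (inestimable)."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def kaks_ng86(cds_a: str, cds_b: str) -> KaKsResult:
    """NG86 Ka/Ks with Jukes-Cantor correction."""
    ss, ns, sd, nd = count_ng86(cds_a, cds_b)
    ka = jukes_cantor(nd / ns) if ns > 0 else float("nan")
    ks = jukes_cantor(sd / ss) if ss > 0 else float("nan")
    if math.isnan(ka) or math.isnan(ks) or ks == 0.0:
        ratio = float("nan")
    else:
        ratio = ka / ks
    return KaKsResult(
        ka=ka, ks=ks, ratio=ratio, method="NG86",
        syn_sites=ss, nonsyn_sites=ns, syn_diffs=sd, nonsyn_diffs=nd,
    )


# -- MYN -------------------------------------------------------------------


def _nucleotide_freqs(seqs: list[str]) -> dict[str, float]:
    counts = {b: 1.0 for b in "ACGT"}  # +1 pseudocount keeps freqs positive
    for s in seqs:
        for ch in s:
            if ch in counts:
                counts[ch] += 1.0
    tot = sum(counts.values())
    return {b: c / tot for b, c in counts.items()}


def tn93_distance(P1: float, P2: float, Q: float, pi: dict[str, float]):
    """Tamura-Nei (1993) distance and transition/transversion components.

    P1/P2/Q are observed proportions of purine transitions, pyrimidine
    transitions and transversions.  Returns (d, kappa_R, kappa_Y); all NaN
    when the log arguments leave the admissible region (saturation).
    """
    piA, piC, piG, piT = pi["A"], pi["C"], pi["G"], pi["T"]
    piR, piY = piA + piG, piC + piT
    k1 = 2.0 * piA * piG / piR
    k2 = 2.0 * piT * piC / piY
    k3 = 2.0 * (piR * piY - piA * piG * piY / piR - piT * piC * piR / piY)
    w1 = 1.0 - P1 / k1 - Q / (2.0 * piR)
    w2 = 1.0 - P2 / k2 - Q / (2.0 * piY)
    w3 = 1.0 - Q / (2.0 * piR * piY)
    if min(w1, w2, w3) <= 0.0:
        return float("nan"), float("nan"), float("nan")
    d = -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)
    bt = -0.5 * math.log(w3)
    aRt = (-0.5 * math.log(w1) - piY * bt) / piR
    aYt = (-0.5 * math.log(w2) - piR * bt) / piY
    if bt <= 0.0:
        return d, float("nan"), float("nan")
    return d, aRt / bt, aYt / bt


def _estimate_kappas(pairs: list[tuple[str, str]], pi: dict[str, float]):
    """kappa_R, kappa_Y from pooled nucleotide mismatch proportions."""
    n = 0
    cnt = {"tsR": 0, "tsY": 0, "tv": 0}
    for ca, cb in pairs:
        for x, y in zip(ca, cb):
            n += 1
            if x != y:
                cnt[substitution_class(x, y)] += 1
    if n == 0:
        return 1.0, 1.0
    _, kR, kY = tn93_distance(cnt["tsR"] / n, cnt["tsY"] / n, cnt["tv"] / n, pi)
    if not math.isfinite(kR) or kR <= 0:
        kR = 1.0
    if not math.isfinite(kY) or kY <= 0:
        kY = 1.0
    return min(max(kR, 0.01), 100.0), min(max(kY, 0.01), 100.0)


def _rate_weight(a: str, b: str, kR: float, kY: float, pi_target: float) -> float:
    cls = substitution_class(a, b)
    k = kR if cls == "tsR" else (kY if cls == "tsY" else 1.0)
    return k * pi_target


def _myn_codon_sites(codon: str, kR: float, kY: float,
                     pos_freqs: list[dict[str, float]]) -> float:
    """Rate-weighted synonymous site count of one codon (out of 3)."""
    aa = GENETIC_CODE[codon]
    syn = 0.0
    for pos in range(3):
        wsum = 0.0
        wsyn = 0.0
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            w = _rate_weight(codon[pos], alt, kR, kY, pos_freqs[pos][alt])
            mut = codon[:pos] + alt + codon[pos + 1:]
            wsum += w
            if mut not in STOP_CODONS and GENETIC_CODE[mut] == aa:
                wsyn += w
        if wsum > 0:
            syn += wsyn / wsum
    return syn


def _myn_count_diffs(pairs, kR, kY, omega, pos_freqs):
    """Pathway-weighted difference counts split by substitution class.

    Returns dicts syn[cls], nonsyn[cls] for cls in {tsR, tsY, tv}.
    """
    syn = {"tsR": 0.0, "tsY": 0.0, "tv": 0.0}
    nonsyn = {"tsR": 0.0, "tsY": 0.0, "tv": 0.0}
    for ca, cb in pairs:
        if ca == cb:
            continue
        paths = _pathways(ca, cb)
        weights, contribs = [], []
        for steps in paths:
            if not _path_valid(steps):
                weights.append(0.0)
                contribs.append(None)
                continue
            w = 1.0
            contrib = []
            for before, after, pos in steps:
                cls = substitution_class(before[pos], after[pos])
                is_syn = GENETIC_CODE[before] == GENETIC_CODE[after]
                sw = _rate_weight(before[pos], after[pos], kR, kY,
                                  pos_freqs[pos][after[pos]])
                if not is_syn:
                    sw *= omega
                w *= sw
                contrib.append((cls, is_syn))
            weights.append(w)
            contribs.append(contrib)
        total = sum(weights)
        if total <= 0.0:  # every path passes a stop: fall back to uniform
            weights = [1.0] * len(paths)
            contribs = []
            for steps in paths:
                contrib = []
                for before, after, pos in steps:
                    contrib.append(
                        (substitution_class(before[pos], after[pos]),
                         GENETIC_CODE[before] == GENETIC_CODE[after])
                    )
                contribs.append(contrib)
            total = float(len(paths))
        for w, contrib in zip(weights, contribs):
            if contrib is None or w == 0.0:
                continue
            for cls, is_syn in contrib:
                if is_syn:
                    syn[cls] += w / total
                else:
                    nonsyn[cls] += w / total
    return syn, nonsyn


def kaks_myn(cds_a: str, cds_b: str) -> KaKsResult:
    """MYN-style Ka/Ks under a Tamura-Nei codon mutation model.

    See the module docstring for the algorithm.  When Ks is inestimable or
    zero the ratio is NaN; when iteration fails to converge the result
    carries ``converged=False`` with diagnostics.
    """
    pairs = _clean_codon_pairs(cds_a, cds_b)
    if not pairs:
        return KaKsResult(
            ka=float("nan"), ks=float("nan"), ratio=float("nan"),
            method="MYN", converged=False,
            diagnostics={"reason": "no usable codons"},
        )
    seqs = ["".join(p[0] for p in pairs), "".join(p[1] for p in pairs)]
    pi = _nucleotide_freqs(seqs)
    pos_freqs = []
    for pos in range(3):
        pos_freqs.append(
            _nucleotide_freqs(
                ["".join(p[0][pos] + p[1][pos] for p in pairs)]
            )
        )
    kR, kY = _estimate_kappas(pairs, pi)

    # rate-weighted site counts (independent of omega)
    S = N = 0.0
    for ca, cb in pairs:
        s = 0.5 * (
            _myn_codon_sites(ca, kR, kY, pos_freqs)
            + _myn_codon_sites(cb, kR, kY, pos_freqs)
        )
        S += s
        N += 3.0 - s

    omega = 1.0
    ka = ks = float("nan")
    converged = False
    for _ in range(100):
        syn_d, nonsyn_d = _myn_count_diffs(pairs, kR, kY, omega, pos_freqs)
        sd = sum(syn_d.values())
        nd = sum(nonsyn_d.values())
        if S <= 0 or N <= 0:
            break
        ks_new, _, _ = tn93_distance(
            syn_d["tsR"] / S, syn_d["tsY"] / S, syn_d["tv"] / S, pi
        )
        ka_new, _, _ = tn93_distance(
            nonsyn_d["tsR"] / N, nonsyn_d["tsY"] / N, nonsyn_d["tv"] / N, pi
        )
        if math.isnan(ks_new) or math.isnan(ka_new):
            ka, ks = ka_new, ks_new
            break
        if (
            not math.isnan(ka)
            and abs(ka_new - ka) < 1e-8
            and abs(ks_new - ks) < 1e-8
        ):
            ka, ks = ka_new, ks_new
            converged = True
            break
        ka, ks = ka_new, ks_new
        omega = ka / ks if ks > 0 and ka >= 0 else 1.0
        omega = min(max(omega, 1e-4), 100.0)
    else:
        converged = False

    if math.isnan(ka) or math.isnan(ks) or ks == 0.0:
        ratio = float("nan")
    else:
        ratio = ka / ks
    sdiffs = sum(syn_d.values()) if S > 0 else 0.0
    ndiffs = sum(nonsyn_d.values()) if N > 0 else 0.0
    return KaKsResult(
        ka=ka, ks=ks, ratio=ratio, method="MYN",
        syn_sites=S, nonsyn_sites=N, syn_diffs=sdiffs, nonsyn_diffs=ndiffs,
        kappa_R=kR, kappa_Y=kY, converged=converged,
        diagnostics={} if converged else {"reason": "iteration limit or saturation"},
    )


# -- significance and direction -------------------------------------------


def kaks_significance(result: KaKsResult) -> float:
    """Two-sided Fisher exact test of Ka != Ks from rounded count tables.

    The 2x2 table contrasts substitutions vs. intact sites in the synonymous
    and non-synonymous classes.  Undefined counts give NaN.
    """
    ss, ns = result.syn_sites, result.nonsyn_sites
    sd, nd = result.syn_diffs, result.nonsyn_diffs
    if not all(math.isfinite(v) for v in (ss, ns, sd, nd)) or ss <= 0 or ns <= 0:
        return float("nan")
    table = [
        [round(sd), round(ss) - round(sd)],
        [round(nd), round(ns) - round(nd)],
    ]
    if min(table[0][1], table[1][1]) < 0:
        return float("nan")
    _, p = _stats.fisher_exact(table, alternative="two-sided")
    return float(p)


def classify_direction(ratio: float) -> str:
    """Map a Ka/Ks ratio to {positive, purifying, neutral, NA}."""
    if ratio is None or (isinstance(ratio, float) and math.isnan(ratio)):
        return "NA"
    if abs(ratio - 1.0) <= 1e-9:
        return "neutral"
    return "positive" if ratio > 1.0 else "purifying"


# -- population-level aggregation -----------------------------------------


def kaks_between_groups(
    cds_by_sample: dict[str, str],
    groups: dict[str, str],
    group_a: str,
    group_b: str | None = None,
    method: str = "MYN",
    max_pairs: int | None = 40,
    rng: np.random.Generator | None = None,
) -> KaKsResult:
    """Mean pairwise Ka/Ks within one group or between two groups.

    With ``group_b=None`` all within-``group_a`` pairs are used; otherwise
    all between-group pairs.  Mean Ka and mean Ks are averaged over pairs
    with estimable distances and the ratio is formed from the means (ratio
    of means, which is stable when many pairs have Ks = 0).  ``max_pairs``
    caps the number of pairs by deterministic subsampling.
    """
    fn = kaks_myn if method == "MYN" else kaks_ng86
    names_a = [s for s, g in groups.items() if g == group_a and s in cds_by_sample]
    if group_b is None:
        pairs = list(itertools.combinations(sorted(names_a), 2))
    else:
        names_b = [s for s, g in groups.items() if g == group_b and s in cds_by_sample]
        pairs = list(itertools.product(sorted(names_a), sorted(names_b)))
    if max_pairs is not None and len(pairs) > max_pairs:
        rng = rng or np.random.default_rng(0)
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in sorted(idx)]
    kas, kss = [], []
    ss = ns = sd = nd = 0.0
    for sa, sb in pairs:
        res = fn(cds_by_sample[sa], cds_by_sample[sb])
        if math.isfinite(res.ka) and math.isfinite(res.ks):
            kas.append(res.ka)
            kss.append(res.ks)
            ss += res.syn_sites
            ns += res.nonsyn_sites
            sd += res.syn_diffs
            nd += res.nonsyn_diffs
    if not kas:
        return KaKsResult(
            ka=float("nan"), ks=float("nan"), ratio=float("nan"), method=method,
            diagnostics={"n_pairs": 0},
        )
    ka = float(np.mean(kas))
    ks = float(np.mean(kss))
    ratio = ka / ks if ks > 0 else float("nan")
    npairs = len(kas)
    return KaKsResult(
        ka=ka, ks=ks, ratio=ratio, method=method,
        syn_sites=ss / npairs, nonsyn_sites=ns / npairs,
        syn_diffs=sd / npairs, nonsyn_diffs=nd / npairs,
        diagnostics={"n_pairs": npairs},
    )
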