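"""Empirical-distribution selection-signature calls at gene and site level.

Gene-level criteria (descendant population = the domesticated group):

* purifying — theta-pi and Watterson's theta both in the lower 5% of the
  empirical distribution over the gene universe, F_ST above the 95th
  percentile of the pairwise distribution, and a negative Tajima's D.  An
  undefined Tajima's D (invariant descendant gene) satisfies the negative
  clause: total loss of diversity is the extreme of the signature.
* balancing — theta-pi and Watterson's theta in the upper 25%, Tajima's D
  in the upper 5%, and F_ST between the 10th and 90th percentiles.

Site-level criteria compare per-site diversity change (descendant minus
ancestral) against the mean per-gene diversity-change magnitude of the
background, require per-site F_ST > 0, and take the Tajima's D sign clause
at gene level in the descendant population (a per-site D is not
meaningful).

Percentiles use inclusive rank: percentile(v) = 100 * #{x <= v} / N, so
tied values share the higher rank — deterministic and conservative in the
lower tail.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from domscan.gene_io import GeneModel, HaplotypeAlignment
from domscan.kaks import GENETIC_CODE

RESIDUE_CLASSES = {
    **{aa: "nonpolar" for aa in "AVLIPFMWG"},
    **{aa: "polar" for aa in "STCYNQ"},
    **{aa: "acidic" for aa in "DE"},
    **{aa: "basic" for aa in "KRH"},
}

DEFAULT_THRESHOLDS = {
    "purifying_diversity_pct": 5.0,
    "purifying_fst_pct": 95.0,
    "balancing_diversity_pct": 75.0,  # upper 25%
    "balancing_tajd_pct": 95.0,  # upper 5%
    "balancing_fst_low_pct": 10.0,
    "balancing_fst_high_pct": 90.0,
}


class ClassificationError(ValueError):
    """A required statistic is missing."""


@dataclass
class EmpiricalDistribution:
    """Sorted empirical distribution with inclusive-rank percentile lookup."""

    name: str
    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise ClassificationError(f"empirical distribution {self.name!r} is empty")
        self.values = np.sort(vals)

    def percentile(self, value: float) -> float:
        """100 * #{x <= value} / N (ties share the higher rank)."""
        if math.isnan(value):
            return float("nan")
        rank = bisect_right(self.values.tolist(), value)
        return 100.0 * rank / self.values.size


def empirical_quantile(dist: EmpiricalDistribution, value: float) -> float:
    return dist.percentile(value)


@dataclass
class GeneSelectionCall:
    gene_id: str
    call: str  # purifying | balancing | none
    evidence: dict = field(default_factory=dict)


@dataclass
class SiteSelectionCall:
    gene_id: str
    site: int  # 0-based within the region
    call: str  # purifying | balancing
    codon_index: int = -1  # 0-based; -1 outside any CDS
    effect: str = ""  # synonymous | non-synonymous | noncoding
    residue_class: str = ""  # for non-synonymous calls
    diversity_change: float = float("nan")
    fst: float = float("nan")


@dataclass
class SweepRegion:
    focal_gene: str
    span_kb: float
    start: int
    end: int
    member_genes: list[str] = field(default_factory=list)


# -- gene-level classification --------------------------------------------


def classify_gene(
    stats: dict,
    dists: dict[str, EmpiricalDistribution],
    thresholds: dict | None = None,
) -> GeneSelectionCall:
    """Classify one gene as purifying / balancing / none.

    ``stats`` must carry ``pi`` (descendant theta-pi), ``theta_w``
    (descendant Watterson), ``tajd`` (descendant Tajima's D; NaN allowed)
    and ``fst``; ``dists`` the matching empirical distributions keyed
    ``pi``, ``theta_w``, ``tajd``, ``fst``.  Purifying is evaluated first;
    the two diversity bands are disjoint so both cannot hold.
    """
    th = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    for key in ("pi", "theta_w", "fst"):
        if key not in stats or stats[key] is None or (
            isinstance(stats[key], float) and math.isnan(stats[key])
        ):
            raise ClassificationError(f"statistic {key!r} missing for classification")
        if key not in dists:
            raise ClassificationError(f"distribution {key!r} missing")
    tajd = stats.get("tajd", float("nan"))

    pi_pct = dists["pi"].percentile(stats["pi"])
    w_pct = dists["theta_w"].percentile(stats["theta_w"])
    fst_pct = dists["fst"].percentile(stats["fst"])
    tajd_pct = dists["tajd"].percentile(tajd) if "tajd" in dists else float("nan")

    evidence = {
        "pi_pct": pi_pct,
        "theta_w_pct": w_pct,
        "fst_pct": fst_pct,
        "tajd": tajd,
        "tajd_pct": tajd_pct,
    }

    tajd_negative = math.isnan(tajd) or tajd < 0.0  # NA counts as negative
    if (
        pi_pct <= th["purifying_diversity_pct"]
        and w_pct <= th["purifying_diversity_pct"]
        and fst_pct > th["purifying_fst_pct"]
        and tajd_negative
    ):
        return GeneSelectionCall(stats.get("gene_id", ""), "purifying", evidence)

    if (
        pi_pct >= th["balancing_diversity_pct"]
        and w_pct >= th["balancing_diversity_pct"]
        and not math.isnan(tajd)
        and tajd_pct >= th["balancing_tajd_pct"]
        and th["balancing_fst_low_pct"] < fst_pct < th["balancing_fst_high_pct"]
    ):
        return GeneSelectionCall(stats.get("gene_id", ""), "balancing", evidence)

    return GeneSelectionCall(stats.get("gene_id", ""), "none", evidence)


def build_distributions(rows: list[dict]) -> dict[str, EmpiricalDistribution]:
    """Build the four gene-level empirical distributions from stat rows."""
    out = {}
    for key in ("pi", "theta_w", "tajd", "fst"):
        vals = np.array([r.get(key, float("nan")) for r in rows], dtype=float)
        out[key] = EmpiricalDistribution(key, vals)
    return out


# -- site-level classification --------------------------------------------


def classify_sites(
    site_stats: dict[str, np.ndarray],
    genome_background: float,
    gene_id: str = "",
    gene_tajd: float = float("nan"),
) -> list[SiteSelectionCall]:
    """Call purifying/balancing base pairs for one gene.

    ``site_stats`` is the output of
    :func:`domscan.diversity_stats.per_site_stats` with ``div_a`` the
    ancestral and ``div_b`` the descendant per-site diversity;
    ``genome_background`` is the mean per-gene diversity-change magnitude
    over the background gene set.
    """
    div_a = site_stats["div_a"]
    div_b = site_stats["div_b"]
    fst = site_stats["fst"]
    if not (len(div_a) == len(div_b) == len(fst)):
        raise ValueError("per-site vectors must have equal length")
    change = div_b - div_a
    tajd_neg = math.isnan(gene_tajd) or gene_tajd < 0.0
    tajd_pos = (not math.isnan(gene_tajd)) and gene_tajd > 0.0
    calls = []
    for j in range(len(change)):
        if math.isnan(change[j]) or math.isnan(fst[j]) or fst[j] <= 0.0:
            continue
        if abs(change[j]) <= genome_background:
            continue
        if change[j] < 0.0 and tajd_neg:
            call = "purifying"
        elif change[j] > 0.0 and tajd_pos:
            call = "balancing"
        else:
            continue
        calls.append(
            SiteSelectionCall(
                gene_id=gene_id,
                site=j,
                call=call,
                diversity_change=float(change[j]),
                fst=float(fst[j]),
            )
        )
    return calls


def diversity_change_background(per_gene_changes: list[float]) -> float:
    """Mean |descendant - ancestral| gene diversity over the background set."""
    arr = np.array(per_gene_changes, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no background genes")
    return float(np.mean(np.abs(arr)))


# -- codon-effect annotation ----------------------------------------------


def _majority(col: np.ndarray) -> int:
    vals, counts = np.unique(col, return_counts=True)
    order = np.lexsort((vals, -counts))  # most frequent, ties by byte value
    return int(vals[order[0]])


def annotate_codon_effects(
    site_calls: list[SiteSelectionCall],
    cds_alignment: HaplotypeAlignment,
    gene_model: GeneModel | None = None,
) -> list[SiteSelectionCall]:
    """Attach codon index, synonymous/non-synonymous effect and residue class.

    Site indices are taken to lie on the CDS alignment's own coordinates
    (frame anchored at position 1 of the alignment).  A site outside the
    CDS span (possible when calls were made on the whole gene) is annotated
    ``noncoding``.  The variant's effect is judged in the majority codon
    context; the residue class comes from the amino acid encoded by the
    minority (variant) allele.
    """
    mat = cds_alignment.matrix
    L = cds_alignment.length
    if L % 3 != 0:
        raise ValueError("CDS alignment length must be divisible by 3")
    miss = cds_alignment.missing_mask()
    out = []
    for call in site_calls:
        j = call.site
        if j < 0 or j >= L:
            call.effect = "noncoding"
            out.append(call)
            continue
        codon_idx = j // 3
        call.codon_index = codon_idx
        col = mat[~miss[:, j], j]
        alleles = np.unique(col)
        maj = _majority(col)
        # majority codon context
        ctx = []
        for k in range(3 * codon_idx, 3 * codon_idx + 3):
            ck = mat[~miss[:, k], k]
            ctx.append(chr(_majority(ck)) if ck.size else "N")
        pos_in_codon = j % 3
        effect = "synonymous"
        variant_aa = ""
        for a in alleles:
            if int(a) == maj:
                continue
            maj_codon = ctx.copy()
            maj_codon[pos_in_codon] = chr(maj)
            var_codon = ctx.copy()
            var_codon[pos_in_codon] = chr(int(a))
            cm, cv = "".join(maj_codon), "".join(var_codon)
            if "N" in cm or "N" in cv or "-" in cm or "-" in cv:
                continue
            aam = GENETIC_CODE.get(cm, "X")
            aav = GENETIC_CODE.get(cv, "X")
            if aam != aav:
                effect = "non-synonymous"
                variant_aa = aav
        call.effect = effect
        if effect == "non-synonymous" and variant_aa in RESIDUE_CLASSES:
            call.residue_class = RESIDUE_CLASSES[variant_aa]
        out.append(call)
    return out


# -- sweep delimitation ----------------------------------------------------


def detect_sweep(
    focal_gene: str,
    gene_calls: dict[str, GeneSelectionCall],
    gene_positions: dict[str, tuple[str, int, int]],
    positional_diversity: list[tuple[int, int, float]],
    low_quantile: float,
    window_kb: float = 10.0,
) -> SweepRegion:
    """Delimit the low-diversity sweep region around a purifying gene.

    ``positional_diversity`` lists (start, end, descendant theta-pi) windows
    on the focal gene's chromosome, 1-based inclusive.  Starting from
    windows overlapping the focal gene, the span extends left and right in
    ``window_kb`` steps while window diversity stays below ``low_quantile``
    (the genome lower-5% theta-pi quantile).  Member genes are all genes
    overlapping the final span.
    """
    if focal_gene not in gene_calls or gene_calls[focal_gene].call != "purifying":
        raise ValueError(f"{focal_gene} is not called purifying")
    chrom, gstart, gend = gene_positions[focal_gene]
    windows = sorted(positional_diversity)
    in_sweep = [w for w in windows if not math.isnan(w[2]) and w[2] <= low_quantile]

    def overlaps(a_start, a_end, b_start, b_end):
        return a_start <= b_end and b_start <= a_end

    start, end = gstart, gend
    step = int(window_kb * 1000)
    # extend left
    moved = True
    while moved:
        moved = False
        for ws, we, _ in in_sweep:
            if overlaps(ws, we, start - step, start - 1):
                start = min(start, ws)
                moved = True
        for ws, we, _ in in_sweep:
            if overlaps(ws, we, end + 1, end + step):
                end = max(end, we)
                moved = True
    members = [
        g
        for g, (c, s, e) in sorted(gene_positions.items(), key=lambda kv: kv[1][1])
        if c == chrom and overlaps(s, e, start, end)
    ]
    return SweepRegion(
        focal_gene=focal_gene,
        span_kb=(end - start + 1) / 1000.0,
        start=start,
        end=end,
        member_genes=members,
    )


# -- invariance ------------------------------------------------------------


def detect_invariant_genes(summaries: list) -> dict[str, list[str]]:
    """Genes with S = 0 per population group plus pooled ("overall").

    ``summaries`` are :class:`domscan.diversity_stats.DiversitySummary`
    rows; the pooled group must be supplied as population label "overall"
    by the caller (the pipeline pools all samples before summarizing).
    """
    out: dict[str, list[str]] = {}
    for s in summaries:
        if s.S == 0:
            out.setdefault(s.population, []).append(s.gene_id)
    for k in out:
        out[k] = sorted(set(out[k]))
    return out
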