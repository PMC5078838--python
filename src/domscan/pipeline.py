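"""End-to-end scan orchestration and report assembly.

``run_scan`` executes the full workflow over a labelled panel: per-gene
diversity summaries in both populations, Hudson F_ST, Ka/Ks for coding
genes, empirical background construction, gene- and site-level
classification, sweep delimitation, HKA validation of called genes against
a neutral panel, and haplotype networks for called genes.  All randomness
derives from the pipeline seed; identical config + seed gives
byte-identical reports.

Reporting conventions: statistics print at 6 decimal places with "NA" for
undefined values; fold changes are rounded to 1 decimal place; headline
percentages are truncated (not rounded) to 1 decimal place.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from domscan.diversity_stats import (
    fold_change,
    hudson_fst,
    per_site_stats,
    summarize_gene,
)
from domscan.gene_io import write_results_table
from domscan.haplonet import build_network, collapse_haplotypes, hamming_matrix, network_report
from domscan.hka import count_locus, fit_and_test
from domscan.kaks import kaks_between_groups, kaks_significance
from domscan.selection_scan import (
    annotate_codon_effects,
    build_distributions,
    classify_gene,
    classify_sites,
    detect_invariant_genes,
    detect_sweep,
    diversity_change_background,
)
from domscan.synthetic_data import SimulationConfig, SimulatedDataset, generate_dataset


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Scan configuration.

    ``thresholds`` follow the empirical-quantile criteria (percent):
    purifying diversity tail 5, purifying F_ST 95, balancing diversity band
    75 (upper 25%), balancing Tajima's D 95, balancing F_ST band (10, 90).
    ``background_scope`` selects the gene universe behind the empirical
    distributions: "geneset" ranks each gene within the analyzed panel
    (self-inclusive); "genome" uses an external genome-wide surrogate
    supplied to :func:`run_scan`.
    """

    ancestral_group: str = "WildWeedy"
    descendant_group: str = "Landrace"
    thresholds: dict = field(default_factory=dict)
    background_scope: str = "geneset"
    neutral_panel_size: int = 34
    sweep_window_kb: float = 10.0
    kaks_max_pairs: int = 8
    run_hka: bool = True
    run_networks: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.background_scope not in ("geneset", "genome"):
            raise ValueError("background_scope must be 'geneset' or 'genome'")
        if self.ancestral_group == self.descendant_group:
            raise ValueError("ancestral and descendant groups must differ")


@dataclass
class ScanReport:
    """All outputs of one scan."""

    gene_rows: list[dict]  # per-gene diversity/F_ST/call rows
    kaks_rows: list[dict]  # per coding gene Ka:Ks rows
    site_calls: dict[str, list]
    sweeps: dict[str, dict]
    hka: dict
    networks: dict[str, dict]
    invariant: dict[str, list[str]]
    headline: dict
    family_means: dict
    manifest: dict

    def called(self, call: str) -> list[str]:
        return [r["gene_id"] for r in self.gene_rows if r["call"] == call]

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        def clean(x):
            if isinstance(x, dict):
                return {k: clean(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [clean(v) for v in x]
            if isinstance(x, (float, np.floating)) and not math.isfinite(x):
                return None
            return x

        return json.dumps(
            clean({
                "manifest": self.manifest,
                "gene_rows": self.gene_rows,
                "kaks_rows": self.kaks_rows,
                "site_calls": {
                    g: [c.__dict__ for c in calls]
                    for g, calls in self.site_calls.items()
                },
                "sweeps": self.sweeps,
                "hka": self.hka,
                "networks": self.networks,
                "invariant": self.invariant,
                "headline": self.headline,
                "family_means": self.family_means,
            }),
            indent=1,
            sort_keys=True,
            default=default,
            allow_nan=False,
        )

    def write(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        cols = [
            "gene_id", "call", "sweep_kb", "pi_descendant", "pi_ancestral",
            "theta_w_descendant", "tajd_descendant", "tajd_ancestral", "fst",
            "fold_change",
        ]
        write_results_table(
            self.gene_rows, os.path.join(outdir, "gene_scan.tsv"), columns=cols
        )
        if self.kaks_rows:
            write_results_table(
                self.kaks_rows, os.path.join(outdir, "kaks.tsv")
            )
        site_rows = []
        for g, calls in sorted(self.site_calls.items()):
            for c in calls:
                site_rows.append(
                    {
                        "chrom": self.manifest["gene_positions"].get(g, ("NA",))[0],
                        "start": c.site,
                        "end": c.site + 1,
                        "gene_id": g,
                        "call": c.call,
                        "effect": c.effect or "NA",
                    }
                )
        write_results_table(
            site_rows,
            os.path.join(outdir, "site_calls.tsv"),
            columns=["chrom", "start", "end", "gene_id", "call", "effect"],
        )
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            fh.write(self.to_json())


def _nan_to_none(x):
    if isinstance(x, float) and (math.isnan(x) or math.isinf(x)):
        return None
    return x


def truncate_pct(count: int, total: int) -> float:
    """Percentage truncated (not rounded) to 1 decimal place."""
    if total == 0:
        return 0.0
    return math.floor(1000.0 * count / total) / 10.0


def rounded_fold(ratio: float) -> float:
    """Fold change rounded to 1 decimal place for reporting."""
    if math.isnan(ratio) or math.isinf(ratio):
        return ratio
    return round(ratio, 1)


def family_summary(
    summaries: list, family_map: dict[str, str]
) -> dict[str, dict[str, float]]:
    """Unweighted mean per-gene theta-pi per family per population."""
    acc: dict[tuple[str, str], list[float]] = {}
    for s in summaries:
        if s.gene_id not in family_map:
            raise PipelineError(f"gene {s.gene_id} missing from family map")
        acc.setdefault((family_map[s.gene_id], s.population), []).append(s.pi)
    out: dict[str, dict[str, float]] = {}
    for (fam, pop), vals in sorted(acc.items()):
        out.setdefault(fam, {})[pop] = float(np.mean(vals))
    return out


def headline_counts(gene_rows: list[dict]) -> dict:
    """Headline counts and percentages over the scanned gene universe."""
    total = len(gene_rows)
    decreased = sum(
        1
        for r in gene_rows
        if r["pi_descendant"] is not None
        and r["pi_ancestral"] is not None
        and r["pi_descendant"] < r["pi_ancestral"]
    )
    folds = [
        r["fold_change"]
        for r in gene_rows
        if r["fold_change"] is not None and math.isfinite(r["fold_change"])
    ]
    return {
        "n_genes": total,
        "n_diversity_decreased": decreased,
        "pct_diversity_decreased": truncate_pct(decreased, total),
        "n_purifying": sum(1 for r in gene_rows if r["call"] == "purifying"),
        "n_balancing": sum(1 for r in gene_rows if r["call"] == "balancing"),
        "max_fold_change": rounded_fold(max(folds)) if folds else None,
    }


def _gene_stats(dataset: SimulatedDataset, config: PipelineConfig):
    """Stage 1: per-gene summaries for both populations plus F_ST."""
    stats = {}
    for gid in dataset.gene_ids():
        anc = dataset.ancestral[gid]
        desc = dataset.descendant[gid]
        s_anc = summarize_gene(anc, gid, config.ancestral_group)
        s_desc = summarize_gene(desc, gid, config.descendant_group)
        stats[gid] = {
            "anc": s_anc,
            "desc": s_desc,
            "fst": hudson_fst(desc, anc),
        }
    return stats


def run_scan(
    config: PipelineConfig,
    dataset: SimulatedDataset | None = None,
    sim_config: SimulationConfig | None = None,
    background: SimulatedDataset | None = None,
) -> ScanReport:
    """Execute the full scan.  See the module docstring for the stages.

    ``background`` supplies the genome-wide surrogate panel when
    ``config.background_scope == "genome"``; gene-level empirical
    distributions then pool the analyzed genes with the background genes
    (self-inclusive ranking over the union).
    """
    if dataset is None:
        dataset = generate_dataset(sim_config or SimulationConfig(seed=config.seed))
    gene_ids = dataset.gene_ids()
    if not gene_ids:
        return ScanReport(
            gene_rows=[], kaks_rows=[], site_calls={}, sweeps={}, hka={},
            networks={}, invariant={}, headline=headline_counts([]),
            family_means={},
            manifest=_manifest(config, dataset, background),
        )

    try:
        stats = _gene_stats(dataset, config)
    except Exception as e:  # pragma: no cover - defensive
        raise PipelineError(f"diversity stage failed: {e}") from e

    # empirical backgrounds (descendant population statistics)
    rows_for_dist = [
        {
            "pi": stats[g]["desc"].pi,
            "theta_w": stats[g]["desc"].theta_w,
            "tajd": stats[g]["desc"].tajimas_d,
            "fst": stats[g]["fst"],
        }
        for g in gene_ids
    ]
    if config.background_scope == "genome":
        if background is None:
            raise PipelineError(
                "background_scope='genome' requires a background dataset"
            )
        bg_stats = _gene_stats(background, config)
        rows_for_dist += [
            {
                "pi": v["desc"].pi,
                "theta_w": v["desc"].theta_w,
                "tajd": v["desc"].tajimas_d,
                "fst": v["fst"],
            }
            for v in bg_stats.values()
        ]
    dists = build_distributions(rows_for_dist)

    # gene-level classification
    calls = {}
    for g in gene_ids:
        calls[g] = classify_gene(
            {
                "gene_id": g,
                "pi": stats[g]["desc"].pi,
                "theta_w": stats[g]["desc"].theta_w,
                "tajd": stats[g]["desc"].tajimas_d,
                "fst": stats[g]["fst"],
            },
            dists,
            config.thresholds,
        )

    # site-level classification
    per_gene_change = [
        stats[g]["desc"].pi - stats[g]["anc"].pi for g in gene_ids
    ]
    bg_mean = diversity_change_background(per_gene_change)
    site_calls = {}
    for g in gene_ids:
        ps = per_site_stats(dataset.ancestral[g], dataset.descendant[g])
        ps = {"div_a": ps["div_a"], "div_b": ps["div_b"], "fst": ps["fst"]}
        sc = classify_sites(
            ps, bg_mean, gene_id=g, gene_tajd=stats[g]["desc"].tajimas_d
        )
        if sc and dataset.ancestral[g].feature == "CDS":
            sc = annotate_codon_effects(sc, dataset.combined(g))
        site_calls[g] = sc

    # sweep delimitation around purifying genes
    low_q = float(np.quantile([stats[g]["desc"].pi for g in gene_ids], 0.05))
    windows = [
        (dataset.gene_positions[g][1], dataset.gene_positions[g][2],
         stats[g]["desc"].pi)
        for g in gene_ids
    ]
    sweeps = {}
    for g in gene_ids:
        if calls[g].call != "purifying":
            continue
        region = detect_sweep(
            g, calls, dataset.gene_positions, windows, low_q,
            config.sweep_window_kb,
        )
        sweeps[g] = {
            "span_kb": region.span_kb,
            "start": region.start,
            "end": region.end,
            "member_genes": region.member_genes,
        }

    # Ka:Ks for coding genes
    kaks_rows = []
    rng = np.random.default_rng(config.seed)
    for g in gene_ids:
        if dataset.ancestral[g].feature != "CDS":
            continue
        comb = dataset.combined(g)
        cds = dict(zip(comb.sample_names, comb.sequences()))
        groups = dict(zip(comb.sample_names, comb.population_labels))
        row = {"gene_id": g}
        for label, ga, gb in (
            ("descendant", config.descendant_group, None),
            ("ancestral", config.ancestral_group, None),
            ("domestication", config.descendant_group, config.ancestral_group),
        ):
            res = kaks_between_groups(
                cds, groups, ga, gb, method="MYN",
                max_pairs=config.kaks_max_pairs, rng=rng,
            )
            row[f"kaks_{label}"] = _nan_to_none(res.ratio)
            row[f"p_{label}"] = _nan_to_none(kaks_significance(res))
        kaks_rows.append(row)

    # HKA validation of called genes against a neutral panel
    hka_out = {}
    if config.run_hka:
        # polymorphism is counted in the descendant population: the calls
        # concern selection during domestication, and a swept gene shows its
        # polymorphism deficit (k << 1) only there
        called = [g for g in gene_ids if calls[g].call != "none"]
        not_called = [g for g in gene_ids if calls[g].call == "none"]
        panel_ids = not_called[: config.neutral_panel_size]
        loci_panel = [
            count_locus(dataset.descendant[g], dataset.outgroup[g], g)
            for g in panel_ids
            if len(dataset.outgroup[g]) == dataset.descendant[g].length
        ]
        per_gene = {}
        for g in called:
            if len(dataset.outgroup[g]) != dataset.descendant[g].length:
                continue
            locus = count_locus(
                dataset.descendant[g], dataset.outgroup[g], g, selected_flag=True
            )
            fit = fit_and_test(loci_panel + [locus], [g])
            per_gene[g] = {
                "lrt": fit["lrt"], "p": fit["p"],
                "k_hat": fit["k_hat"][g], "df": fit["df"],
            }
        hka_out = {
            "per_gene": per_gene,
            "mean_lrt": (
                float(np.mean([v["lrt"] for v in per_gene.values()]))
                if per_gene else None
            ),
            "neutral_panel": panel_ids,
        }

    # haplotype networks for called genes
    networks = {}
    if config.run_networks:
        for g in gene_ids:
            if calls[g].call == "none":
                continue
            table = collapse_haplotypes(dataset.combined(g), dataset.metadata)
            edges = build_network(hamming_matrix(table), table.haplotype_ids)
            networks[g] = network_report(table, edges, "group")

    # report rows
    gene_rows = []
    for g in gene_ids:
        fc = fold_change(stats[g]["desc"].pi, stats[g]["anc"].pi)
        gene_rows.append(
            {
                "gene_id": g,
                "call": calls[g].call,
                "sweep_kb": sweeps.get(g, {}).get("span_kb"),
                "pi_descendant": stats[g]["desc"].pi,
                "pi_ancestral": stats[g]["anc"].pi,
                "theta_w_descendant": stats[g]["desc"].theta_w,
                "tajd_descendant": _nan_to_none(stats[g]["desc"].tajimas_d),
                "tajd_ancestral": _nan_to_none(stats[g]["anc"].tajimas_d),
                "fst": stats[g]["fst"],
                "fold_change": _nan_to_none(fc),
                "evidence": calls[g].evidence,
            }
        )

    pooled = [
        summarize_gene(dataset.combined(g), g, "overall") for g in gene_ids
    ]
    invariant = detect_invariant_genes(
        [stats[g]["anc"] for g in gene_ids]
        + [stats[g]["desc"] for g in gene_ids]
        + pooled
    )

    family_map = {g: dataset.truth.get(g, "unassigned") for g in gene_ids}
    fam = family_summary(
        [stats[g]["anc"] for g in gene_ids]
        + [stats[g]["desc"] for g in gene_ids],
        family_map,
    )

    return ScanReport(
        gene_rows=gene_rows,
        kaks_rows=kaks_rows,
        site_calls=site_calls,
        sweeps=sweeps,
        hka=hka_out,
        networks=networks,
        invariant=invariant,
        headline=headline_counts(gene_rows),
        family_means=fam,
        manifest=_manifest(config, dataset, background),
    )


def _manifest(config, dataset, background):
    import importlib.metadata

    try:
        version = importlib.metadata.version("domscan")
    except importlib.metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    return {
        "package_version": version,
        "seed": config.seed,
        "thresholds": {**config.thresholds},
        "background_scope": config.background_scope,
        "fst_estimator": "hudson_1-Hw/Hb_unweighted",
        "kaks_pairing": "within-group and between-group pair means",
        "gene_positions": dict(dataset.gene_positions) if dataset else {},
        "n_genes": len(dataset.truth) if dataset else 0,
        "background_genes": len(background.truth) if background else 0,
    }
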