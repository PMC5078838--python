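"""Haplotype collapsing and minimum-spanning haplotype networks.

Columns containing any N or gap are removed before collapsing (complete
deletion) so that haplotype identity is a transitive relation; this differs
deliberately from the pairwise-deletion policy of the diversity statistics.

The network is a minimum spanning tree built by Kruskal's rule with
deterministic lexicographic tie-breaking on haplotype ids; every non-tree
edge whose distance equals the largest distance on the tree path between
its endpoints is additionally emitted with ``alternative=True``, giving a
minimum-spanning network in the usual sense.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import networkx as nx
import numpy as np

from domscan.gene_io import HaplotypeAlignment, SampleMetadata

STRATIFIERS = ("group", "geography", "race")


@dataclass
class HaplotypeTable:
    """Unique haplotypes with frequencies and sample membership."""

    haplotype_ids: list[str]  # "H1", "H2", ... by descending frequency
    sequences: dict[str, str]
    frequency: dict[str, int]
    members: dict[str, list[str]]
    strata: dict[str, dict[str, dict[str, int]]]  # stratifier -> hap -> counts

    @property
    def n_samples(self) -> int:
        return sum(self.frequency.values())


@dataclass(frozen=True)
class NetworkEdge:
    hap_a: str
    hap_b: str
    distance: int
    in_spanning_tree: bool
    alternative: bool = False


def collapse_haplotypes(
    aln: HaplotypeAlignment, metadata: SampleMetadata | None = None
) -> HaplotypeTable:
    """Collapse an alignment into unique haplotypes.

    Sequences identical over the columns free of N/gap in *all* samples
    share a haplotype.  Stratified counts by group/geography/race are
    attached when metadata is given (group falls back to the alignment's
    population labels).
    """
    if aln.n < 1:
        raise ValueError("empty alignment")
    keep = ~aln.missing_mask().any(axis=0)
    core = aln.matrix[:, keep] if keep.any() else aln.matrix[:, :0]
    groups: dict[bytes, list[str]] = {}
    for i, name in enumerate(aln.sample_names):
        groups.setdefault(core[i].tobytes(), []).append(name)
    # canonical haplotype order: H1 is the most frequent; ties by sequence.
    # This keeps ids (and the network's tie-breaking) independent of the
    # input sample order.
    canonical = sorted(groups, key=lambda k: (-len(groups[k]), k))
    order = [f"H{i + 1}" for i in range(len(canonical))]
    members = {hid: groups[key] for hid, key in zip(order, canonical)}
    sequences = {hid: key.decode("ascii") for hid, key in zip(order, canonical)}
    frequency = {hid: len(m) for hid, m in members.items()}

    strata: dict[str, dict[str, dict[str, int]]] = {s: {} for s in STRATIFIERS}
    label_of = dict(zip(aln.sample_names, aln.population_labels))
    for hid, names in members.items():
        for strat in STRATIFIERS:
            counts: dict[str, int] = {}
            for name in names:
                if metadata is not None and name in metadata:
                    value = {
                        "group": metadata.group,
                        "geography": metadata.geography,
                        "race": metadata.race,
                    }[strat](name)
                elif strat == "group":
                    value = label_of[name]
                else:
                    value = "unknown"
                counts[value] = counts.get(value, 0) + 1
            strata[strat][hid] = counts

    return HaplotypeTable(
        haplotype_ids=order,
        sequences=sequences,
        frequency=frequency,
        members=members,
        strata=strata,
    )


def hamming_matrix(table: HaplotypeTable) -> np.ndarray:
    """Symmetric matrix of substitution counts between haplotypes."""
    ids = table.haplotype_ids
    seqs = [np.frombuffer(table.sequences[h].encode(), dtype=np.uint8)
            for h in ids]
    k = len(ids)
    out = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            d = int((seqs[i] != seqs[j]).sum())
            out[i, j] = out[j, i] = d
    return out


def build_network(
    dist: np.ndarray, haplotype_ids: list[str] | None = None
) -> list[NetworkEdge]:
    """Minimum spanning tree plus equal-length alternative links.

    Edges are considered in ascending (distance, id_a, id_b) order
    (Kruskal with lexicographic tie-breaking).  A rejected edge is emitted
    with ``alternative=True`` when its distance equals the maximum edge
    distance on the tree path between its endpoints.
    """
    k = dist.shape[0]
    ids = haplotype_ids or [f"H{i + 1}" for i in range(k)]
    if k == 1:
        return []
    candidates = sorted(
        (int(dist[i, j]), i, j, ids[i], ids[j])
        for i in range(k)
        for j in range(i + 1, k)
    )
    tree = nx.Graph()
    tree.add_nodes_from(range(k))
    edges: list[NetworkEdge] = []
    rejected = []
    for d, i, j, ida, idb in candidates:
        if nx.has_path(tree, i, j):
            rejected.append((d, i, j, ida, idb))
        else:
            tree.add_edge(i, j, weight=d)
            edges.append(NetworkEdge(ida, idb, d, in_spanning_tree=True))
    for d, i, j, ida, idb in rejected:
        path = nx.shortest_path(tree, i, j)
        max_on_path = max(
            tree[u][v]["weight"] for u, v in zip(path, path[1:])
        )
        if d == max_on_path:
            edges.append(
                NetworkEdge(ida, idb, d, in_spanning_tree=False, alternative=True)
            )
    return edges


def network_report(
    table: HaplotypeTable,
    edges: list[NetworkEdge],
    stratify_by: str = "group",
) -> dict:
    """Plot-ready network export: nodes sized by frequency with per-stratum
    composition, edges with distances.  Serializable as JSON; see
    :func:`to_dot` for DOT output."""
    if stratify_by not in STRATIFIERS:
        raise ValueError(
            f"stratify_by must be one of {STRATIFIERS}, got {stratify_by!r}"
        )
    nodes = [
        {
            "id": hid,
            "frequency": table.frequency[hid],
            "composition": table.strata[stratify_by][hid],
            "members": table.members[hid],
        }
        for hid in table.haplotype_ids
    ]
    return {
        "stratify_by": stratify_by,
        "nodes": nodes,
        "edges": [
            {
                "a": e.hap_a,
                "b": e.hap_b,
                "distance": e.distance,
                "in_spanning_tree": e.in_spanning_tree,
                "alternative": e.alternative,
            }
            for e in edges
        ],
    }


def to_dot(report: dict) -> str:
    """Render a network report as Graphviz DOT."""
    lines = ["graph haplonet {", "  node [shape=circle];"]
    for node in report["nodes"]:
        comp = ", ".join(f"{k}:{v}" for k, v in sorted(node["composition"].items()))
        lines.append(
            f'  {node["id"]} [label="{node["id"]}\\n{comp}", '
            f'width={0.3 + 0.1 * node["frequency"]:.2f}];'
        )
    for e in report["edges"]:
        style = "solid" if e["in_spanning_tree"] else "dashed"
        lines.append(
            f'  {e["a"]} -- {e["b"]} [label="{e["distance"]}", style={style}];'
        )
    lines.append("}")
    return "\n".join(lines)


def save_network(report: dict, json_path, dot_path=None) -> None:
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    if dot_path is not None:
        with open(dot_path, "w") as fh:
            fh.write(to_dot(report))
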