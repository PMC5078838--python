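"""Readers, writers, and the core alignment container.

Coordinate convention: 1-based inclusive externally (FASTA headers, GFF,
VCF, reports), 0-based half-open internally.  The conversion happens in
exactly one place per format boundary.

Missing-data policy for diversity statistics is *pairwise deletion*: a site
enters a pair's comparison only when both members carry a called base.  The
haplotype-network module applies complete deletion instead (see
:mod:`domscan.haplonet`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

VALID_CHARS = frozenset(b"ACGTN-")
#: characters treated as "no call" by pairwise statistics
MISSING_CHARS = frozenset(b"N-")

GENE_FAMILIES = (
    "AMT1", "AMT2", "NRT1/PTR", "NRT2", "NRT3", "NR", "NiR",
    "GS", "GOGAT", "GDH", "AST", "AS", "ASPG", "AAL",
)

POPULATION_GROUPS = (
    "InbredLine", "Landrace", "WildWeedy", "Gmargaritiferum", "Spropinquum",
)

GEOGRAPHIES = ("EastAfrica", "WestAfrica", "SouthAfrica", "Asia", "NewWorld")


class FormatError(ValueError):
    """Malformed input file (ragged alignment, bad frame, bad VCF record)."""


class MetadataError(KeyError):
    """A sample present in sequence data is missing from the metadata table."""


@dataclass(frozen=True)
class GeneModel:
    """A gene with optional CDS segments, GFF-style 1-based inclusive coords.

    ``cds_segments`` are stored in transcript (5'->3') order: ascending
    genomic coordinates on the plus strand, descending on the minus strand.
    """

    gene_id: str
    family: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    cds_segments: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end or self.start < 1:
            raise ValueError(f"{self.gene_id}: bad gene span {self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        genomic = sorted(self.cds_segments)
        for s, e in genomic:
            if s > e:
                raise ValueError(f"{self.gene_id}: bad CDS segment {s}-{e}")
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping CDS segments")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if list(self.cds_segments) != expected:
            raise ValueError(
                f"{self.gene_id}: CDS segments not in transcript order"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)


@dataclass
class SampleMetadata:
    """Per-sample population group / geography / race assignments."""

    table: dict[str, tuple[str, str, str]] = field(default_factory=dict)

    def group(self, sample: str) -> str:
        try:
            return self.table[sample][0]
        except KeyError:
            raise MetadataError(f"sample {sample!r} absent from metadata") from None

    def geography(self, sample: str) -> str:
        return self.table[sample][1]

    def race(self, sample: str) -> str:
        return self.table[sample][2]

    def __contains__(self, sample: str) -> bool:
        return sample in self.table

    @classmethod
    def from_tsv(cls, path) -> "SampleMetadata":
        table: dict[str, tuple[str, str, str]] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {name: i for i, name in enumerate(header)}
            for line in fh:
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                table[parts[idx["sample"]]] = (
                    parts[idx["group"]],
                    parts[idx["geography"]],
                    parts[idx["race"]],
                )
        return cls(table)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\tgroup\tgeography\trace\n")
            for sample, (group, geo, race) in self.table.items():
                fh.write(f"{sample}\t{group}\t{geo}\t{race}\n")


class HaplotypeAlignment:
    """Rectangular matrix of aligned haplotype sequences with population labels.

    The matrix is stored as a ``uint8`` array of ASCII codes over the
    alphabet ``{A, C, G, T, N, -}``.
    """

    def __init__(
        self,
        sample_names: list[str],
        population_labels: list[str],
        matrix: np.ndarray,
        gene_id: str = "",
        feature: str = "gene",
    ):
        matrix = np.asarray(matrix, dtype=np.uint8)
        if matrix.ndim != 2:
            raise FormatError("alignment matrix must be 2-dimensional")
        if len(sample_names) != matrix.shape[0]:
            raise FormatError("sample_names length does not match matrix rows")
        if len(population_labels) != matrix.shape[0]:
            raise FormatError("population_labels length does not match matrix rows")
        if matrix.shape[1] < 1:
            raise FormatError("alignment must have at least one site")
        self.sample_names = list(sample_names)
        self.population_labels = list(population_labels)
        self.matrix = matrix
        self.gene_id = gene_id
        self.feature = feature

    # -- construction -----------------------------------------------------

    @classmethod
    def from_sequences(
        cls,
        sample_names: list[str],
        population_labels: list[str],
        sequences: list[str],
        gene_id: str = "",
        feature: str = "gene",
    ) -> "HaplotypeAlignment":
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            raise FormatError(f"ragged sequence lengths: {sorted(lengths)}")
        mat = np.frombuffer(
            "".join(s.upper() for s in sequences).encode("ascii"), dtype=np.uint8
        ).reshape(len(sequences), lengths.pop())
        mat = mat.copy()
        bad = ~np.isin(mat, np.frombuffer(b"ACGTN-", dtype=np.uint8))
        if bad.any():
            logger.warning(
                "%d non-ACGTN- characters normalized to N", int(bad.sum())
            )
            mat[bad] = ord("N")
        return cls(sample_names, population_labels, mat, gene_id, feature)

    # -- views ------------------------------------------------------------

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def sequences(self) -> list[str]:
        return [row.tobytes().decode("ascii") for row in self.matrix]

    def missing_mask(self) -> np.ndarray:
        """Boolean (n x L) mask, True where the call is N or a gap."""
        return (self.matrix == ord("N")) | (self.matrix == ord("-"))

    def subset_population(self, group: str) -> "HaplotypeAlignment":
        idx = [i for i, g in enumerate(self.population_labels) if g == group]
        if not idx:
            raise ValueError(f"no samples with population label {group!r}")
        return HaplotypeAlignment(
            [self.sample_names[i] for i in idx],
            [self.population_labels[i] for i in idx],
            self.matrix[idx],
            self.gene_id,
            self.feature,
        )

    def subset_samples(self, names: list[str]) -> "HaplotypeAlignment":
        pos = {s: i for i, s in enumerate(self.sample_names)}
        idx = [pos[s] for s in names]
        return HaplotypeAlignment(
            names,
            [self.population_labels[i] for i in idx],
            self.matrix[idx],
            self.gene_id,
            self.feature,
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, HaplotypeAlignment)
            and self.sample_names == other.sample_names
            and self.population_labels == other.population_labels
            and np.array_equal(self.matrix, other.matrix)
        )

    def __repr__(self) -> str:
        return (
            f"HaplotypeAlignment({self.gene_id or '<anon>'}, "
            f"n={self.n}, L={self.length})"
        )


# -- FASTA ----------------------------------------------------------------


def read_alignment_fasta(path, metadata: SampleMetadata,
                         gene_id: str = "", feature: str = "gene") -> HaplotypeAlignment:
    """Read a multi-FASTA alignment, attaching population labels from metadata.

    Lowercase is normalized to uppercase; characters outside ``ACGTN-`` are
    mapped to N with a logged warning; ragged records raise
    :class:`FormatError`; a sample absent from metadata raises
    :class:`MetadataError`.
    """
    names, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        seqs.append(str(rec.seq))
    if not names:
        raise FormatError(f"{path}: no FASTA records")
    labels = [metadata.group(s) for s in names]
    return HaplotypeAlignment.from_sequences(names, labels, seqs, gene_id, feature)


def write_alignment_fasta(aln: HaplotypeAlignment, path) -> None:
    """Write an alignment as multi-FASTA with the population in the header."""
    with open(path, "w") as fh:
        for name, group, seq in zip(
            aln.sample_names, aln.population_labels, aln.sequences()
        ):
            fh.write(f">{name} group={group}\n{seq}\n")


# -- GFF3 subset ----------------------------------------------------------


def read_gene_models(path, family_map: dict[str, str] | None = None) -> list[GeneModel]:
    """Parse a GFF3 subset (gene + CDS features) into :class:`GeneModel` rows.

    Only ``gene`` and ``CDS`` feature lines are used; CDS lines are linked
    to their gene via the ``Parent``/``ID`` attributes (transcript level is
    collapsed: a CDS whose Parent is ``<gene>.1`` style is attached to
    ``<gene>``).
    """
    genes: dict[str, dict] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}: short GFF line: {line.rstrip()}")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attr.get("ID", "")
                genes[gid] = {
                    "chromosome": chrom,
                    "start": int(start),
                    "end": int(end),
                    "strand": strand,
                }
            elif ftype == "CDS":
                parent = attr.get("Parent", "")
                root = parent.split(".")[0] if parent else ""
                key = parent if parent in genes else root
                cds.setdefault(key, []).append((int(start), int(end)))
    models = []
    for gid, info in genes.items():
        segs = sorted(cds.get(gid, []))
        if info["strand"] == "-":
            segs = segs[::-1]
        models.append(
            GeneModel(
                gene_id=gid,
                family=(family_map or {}).get(gid, "unassigned"),
                chromosome=info["chromosome"],
                start=info["start"],
                end=info["end"],
                strand=info["strand"],
                cds_segments=tuple(segs),
            )
        )
    return models


# -- VCF region extraction ------------------------------------------------


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_region(
    vcf_path,
    reference_fasta,
    gene_model: GeneModel,
    samples: list[str],
    metadata: SampleMetadata,
    feature: str = "gene",
) -> HaplotypeAlignment:
    """Reconstruct per-sample haplotypes over a gene (or its CDS) from a VCF.

    For each sample the reference sequence over the region is copied and the
    sample's variant alleles substituted.  Heterozygous genotypes (rare in
    an inbred panel) are resolved to the first-listed allele with a warning.
    Missing genotypes become N over the REF span.  For ``feature="CDS"`` the
    per-segment sequences are concatenated in transcript order, with
    minus-strand genes reverse-complemented.
    """
    from cyvcf2 import VCF
    from pyfaidx import Fasta

    ref = Fasta(str(reference_fasta))
    vcf = VCF(str(vcf_path), samples=samples)
    present = set(vcf.samples)
    for s in samples:
        if s not in present:
            raise MetadataError(f"sample {s!r} absent from VCF")
    order = [vcf.samples.index(s) for s in samples]

    span0 = (gene_model.start - 1, gene_model.end)  # 0-based half-open
    refseq = str(ref[gene_model.chromosome][span0[0]:span0[1]]).upper()
    rows = [list(refseq) for _ in samples]

    # iterate all records and filter by span: avoids requiring a tabix index
    # on plain-text VCFs, and gene-scale files are small
    for var in vcf:
        if var.CHROM != gene_model.chromosome:
            continue
        pos0 = var.POS - 1 - span0[0]
        if pos0 < 0 or pos0 >= len(refseq):
            continue
        rlen = len(var.REF)
        if refseq[pos0:pos0 + rlen] != var.REF.upper():
            raise FormatError(
                f"{gene_model.gene_id}: VCF REF {var.REF!r} at {var.POS} "
                f"disagrees with reference"
            )
        if rlen != 1 or any(len(a) != 1 for a in var.ALT):
            # indels are outside the SNP-matrix scope; mask the span
            for r in rows:
                r[pos0:pos0 + rlen] = ["N"] * rlen
            continue
        alleles = [var.REF.upper()] + [a.upper() for a in var.ALT]
        gts = var.genotypes  # [allele_a, allele_b, phased]
        for out_i, vcf_i in enumerate(order):
            g = gts[vcf_i]
            calls = [a for a in g[:-1] if a is not None and a >= 0]
            if not calls:
                rows[out_i][pos0] = "N"
                continue
            if len(set(calls)) > 1:
                logger.warning(
                    "%s: heterozygous call for %s at %s:%d resolved to "
                    "first-listed allele",
                    gene_model.gene_id, samples[out_i],
                    gene_model.chromosome, var.POS,
                )
            rows[out_i][pos0] = alleles[calls[0]]

    gene_seqs = ["".join(r) for r in rows]
    if feature == "CDS":
        out = []
        for seq in gene_seqs:
            parts = []
            for s, e in gene_model.cds_segments:
                sub = seq[s - gene_model.start: e - gene_model.start + 1]
                parts.append(_revcomp(sub) if gene_model.strand == "-" else sub)
            out.append("".join(parts))
        gene_seqs = out
    labels = [metadata.group(s) for s in samples]
    return HaplotypeAlignment.from_sequences(
        samples, labels, gene_seqs, gene_model.gene_id, feature
    )


# -- results tables -------------------------------------------------------


def format_stat(value) -> str:
    """Render a statistic at 6 decimal places; NaN/None becomes "NA"."""
    if value is None:
        return "NA"
    if isinstance(value, str):
        return value
    if isinstance(value, float) and (math.isnan(value) or math.isinf(value)):
        return "Inf" if math.isinf(value) and value > 0 else (
            "-Inf" if math.isinf(value) else "NA"
        )
    if isinstance(value, float):
        return f"{value:.6f}"
    return str(value)


def write_results_table(records: list[dict], path, columns: list[str] | None = None) -> None:
    """Write records as a TSV with one header row.

    Floats are printed at 6 decimal places; ``None``/NaN render as "NA".
    An empty record list yields a header-only file (columns required then).
    """
    if columns is None:
        if not records:
            raise ValueError("columns must be given when records is empty")
        columns = list(records[0].keys())
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for rec in records:
            fh.write("\t".join(format_stat(rec.get(c)) for c in columns) + "\n")


def write_vcf(
    aln: HaplotypeAlignment,
    reference: str,
    path,
    chromosome: str = "chr1",
    offset: int = 0,
) -> None:
    """Export the variant sites of an alignment as a homozygous-diploid VCF.

    ``reference`` supplies the REF allele at every site; ``offset`` is the
    0-based genomic start of the alignment on ``chromosome``.  Samples are
    written as homozygous diploid genotypes (inbred-panel convention);
    missing calls become ``./.``.
    """
    if len(reference) != aln.length:
        raise FormatError("reference length does not match alignment length")
    ref = np.frombuffer(reference.upper().encode(), dtype=np.uint8)
    miss = aln.missing_mask()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chromosome}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(aln.sample_names) + "\n"
        )
        for j in range(aln.length):
            col = aln.matrix[:, j]
            called = col[~miss[:, j]]
            alts = sorted(set(int(c) for c in called) - {int(ref[j])})
            if not alts:
                continue
            allele_index = {int(ref[j]): 0}
            for k, a in enumerate(alts, start=1):
                allele_index[a] = k
            gts = []
            for i in range(aln.n):
                if miss[i, j]:
                    gts.append("./.")
                else:
                    k = allele_index[int(col[i])]
                    gts.append(f"{k}/{k}")
            fh.write(
                f"{chromosome}\t{offset + j + 1}\t.\t{chr(ref[j])}\t"
                + ",".join(chr(a) for a in alts)
                + "\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )
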