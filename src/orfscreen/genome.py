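"""Shared genomic data model: annotation I/O, interval queries, sequence identity.

Coordinates are 0-based half-open internally.  GTF input is read as 1-based
inclusive (the GENCODE dialect), BED as 0-based half-open.  Proximity queries
are strand-agnostic: Cas9 cuts double-stranded DNA, so distance to a feature
matters regardless of which strand a guide anneals to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "OrfRecord",
    "AnnotationIndex",
    "load_annotation",
    "query_features",
    "tss_window",
    "pairwise_identity",
    "read_bed",
    "write_bed",
    "read_orf_fasta",
]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """One gene: biotype, strand, TSS and feature intervals.

    CDS/UTR intervals are only populated for protein-coding genes; they are
    gene-level unions across transcripts (the isoform-collapsing rule).
    """

    gene_id: str
    chrom: str
    strand: str
    biotype: str  # protein_coding | lncRNA | other
    tss: int
    exon_intervals: list[GenomicInterval] = field(default_factory=list)
    cds_intervals: list[GenomicInterval] = field(default_factory=list)
    utr5_intervals: list[GenomicInterval] = field(default_factory=list)
    utr3_intervals: list[GenomicInterval] = field(default_factory=list)
    transcripts: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    essential: bool = False


@dataclass
class OrfRecord:
    """An ATG-initiated ORF on a transcript.

    ``transcript_start``/``transcript_stop`` are the 0-based transcript
    positions of the first base of the start and stop codons.  ``nt_sequence``
    includes the stop codon; ``aa_sequence`` excludes it.
    """

    orf_id: str
    host_gene: str
    transcript_id: str
    transcript_start: int
    transcript_stop: int
    genomic_blocks: list[GenomicInterval] = field(default_factory=list)
    start_codon: str = "ATG"
    nt_sequence: str = ""
    aa_sequence: str = ""
    ribo_p: float | None = None

    @property
    def n_codons(self) -> int:
        """Number of sense codons (stop excluded)."""
        return (self.transcript_stop - self.transcript_start) // 3


class AnnotationIndex:
    """Gene models plus a per-chromosome interval index over CDS/UTR features."""

    FEATURE_CLASSES = ("CDS", "UTR5", "UTR3")

    def __init__(self, genes: dict[str, GeneModel]):
        self.genes = genes
        self._trees: dict[str, IntervalTree] = {}
        for gene in genes.values():
            for feature_class, ivs in (
                ("CDS", gene.cds_intervals),
                ("UTR5", gene.utr5_intervals),
                ("UTR3", gene.utr3_intervals),
            ):
                for iv in ivs:
                    tree = self._trees.setdefault(iv.chrom, IntervalTree())
                    tree.addi(iv.start, iv.end, (gene.gene_id, feature_class))

    def query(self, interval: GenomicInterval) -> list[tuple[str, str]]:
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        hits = {iv.data for iv in tree.overlap(interval.start, interval.end)}
        return sorted(hits)

    def coding_genes(self) -> list[GeneModel]:
        return [g for g in self.genes.values() if g.biotype == "protein_coding"]

    def lncrna_genes(self) -> list[GeneModel]:
        return [g for g in self.genes.values() if g.biotype == "lncRNA"]


def query_features(
    index: AnnotationIndex, interval: GenomicInterval
) -> list[tuple[str, str]]:
    """Feature records whose interval overlaps ``interval`` (half-open overlap).

    Strand-agnostic; an absent chromosome yields an empty list, not an error.
    """
    return index.query(interval)


def tss_window(gene: GeneModel, flank: int) -> GenomicInterval:
    """Symmetric window of ``flank`` bp around the TSS, clipped at 0.

    The window always contains the TSS base itself, so its span is
    ``[tss - flank, tss + flank + 1)``.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    return GenomicInterval(gene.chrom, max(0, gene.tss - flank), gene.tss + flank + 1)


# -- GTF loading ------------------------------------------------------------


def _parse_gtf_attrs(attr_field: str) -> dict[str, str]:
    attrs = {}
    for chunk in attr_field.rstrip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def _subtract(intervals: list[tuple[int, int]], cut: list[tuple[int, int]]):
    """Set-subtract ``cut`` from ``intervals`` (lists of half-open pairs)."""
    out = []
    for s, e in intervals:
        pieces = [(s, e)]
        for cs, ce in cut:
            nxt = []
            for ps, pe in pieces:
                if ce <= ps or cs >= pe:
                    nxt.append((ps, pe))
                    continue
                if ps < cs:
                    nxt.append((ps, cs))
                if ce < pe:
                    nxt.append((ce, pe))
            pieces = nxt
        out.extend(pieces)
    return sorted(out)


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def load_annotation(
    gtf_path: str, essential_gene_list: str | None = None
) -> AnnotationIndex:
    """Read a GENCODE-dialect GTF into an :class:`AnnotationIndex`.

    1-based inclusive GTF coordinates become 0-based half-open.  UTRs are
    derived per transcript as exon minus CDS (split at the CDS into 5' and 3'
    parts by strand) when not explicit, then unioned across transcripts.
    Essentiality flags come from ``essential_gene_list`` (one gene_id per
    line; an optional ``gene_id`` header row is tolerated).
    """
    # per-gene accumulators keyed by gene_id
    meta: dict[str, tuple[str, str, str]] = {}  # gene_id -> (chrom, strand, biotype)
    exons: dict[str, dict[str, list[tuple[int, int]]]] = {}  # gene -> tx -> ivs
    cds: dict[str, dict[str, list[tuple[int, int]]]] = {}
    utrs: dict[str, dict[str, list[tuple[int, int]]]] = {"UTR5": {}, "UTR3": {}}
    explicit_utrs = False

    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GTF line {lineno}: expected 9 fields")
            chrom, _, feature, start_s, end_s, _, strand, _, attr_field = fields
            try:
                start = int(start_s) - 1  # to 0-based half-open
                end = int(end_s)
            except ValueError as exc:
                raise ValueError(f"malformed GTF line {lineno}: bad coordinates") from exc
            if feature not in ("gene", "transcript", "exon", "CDS", "UTR",
                               "five_prime_utr", "three_prime_utr"):
                continue
            attrs = _parse_gtf_attrs(attr_field)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise ValueError(f"malformed GTF line {lineno}: missing gene_id")
            if gene_id not in meta or feature == "gene":
                meta[gene_id] = (
                    chrom,
                    strand,
                    attrs.get("gene_type", attrs.get("gene_biotype", "other")),
                )
            tx_id = attrs.get("transcript_id", gene_id)
            if feature == "exon":
                exons.setdefault(gene_id, {}).setdefault(tx_id, []).append((start, end))
            elif feature == "CDS":
                cds.setdefault(gene_id, {}).setdefault(tx_id, []).append((start, end))
            elif feature in ("five_prime_utr", "three_prime_utr"):
                explicit_utrs = True
                key = "UTR5" if feature == "five_prime_utr" else "UTR3"
                utrs[key].setdefault(gene_id, []).append((start, end))

    genes: dict[str, GeneModel] = {}
    for gene_id, (chrom, strand, biotype) in meta.items():
        biotype = biotype if biotype in ("protein_coding", "lncRNA") else "other"
        gene_exons = exons.get(gene_id, {})
        all_exons = _merge([iv for tx in gene_exons.values() for iv in tx])
        if not all_exons:
            continue
        tss = all_exons[0][0] if strand == "+" else all_exons[-1][1] - 1
        gene = GeneModel(
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            biotype=biotype,
            tss=tss,
            exon_intervals=[GenomicInterval(chrom, s, e, strand) for s, e in all_exons],
            transcripts={
                tx: [GenomicInterval(chrom, s, e, strand) for s, e in sorted(ivs)]
                for tx, ivs in gene_exons.items()
            },
        )
        if biotype == "protein_coding":
            gene_cds = cds.get(gene_id, {})
            cds_union = _merge([iv for tx in gene_cds.values() for iv in tx])
            gene.cds_intervals = [
                GenomicInterval(chrom, s, e, strand) for s, e in cds_union
            ]
            if explicit_utrs and (
                gene_id in utrs["UTR5"] or gene_id in utrs["UTR3"]
            ):
                u5 = _merge(utrs["UTR5"].get(gene_id, []))
                u3 = _merge(utrs["UTR3"].get(gene_id, []))
            else:
                # derive per transcript: exon minus CDS, split by CDS position
                u5_parts, u3_parts = [], []
                for tx_id, tx_exons in gene_exons.items():
                    tx_cds = gene_cds.get(tx_id)
                    if not tx_cds:
                        continue
                    cds_lo = min(s for s, _ in tx_cds)
                    cds_hi = max(e for _, e in tx_cds)
                    non_cds = _subtract(tx_exons, tx_cds)
                    for s, e in non_cds:
                        upstream = e <= cds_lo
                        downstream = s >= cds_hi
                        if not (upstream or downstream):
                            continue  # internal exon gap, not UTR
                        is_five = upstream if strand == "+" else downstream
                        (u5_parts if is_five else u3_parts).append((s, e))
                u5, u3 = _merge(u5_parts), _merge(u3_parts)
            gene.utr5_intervals = [GenomicInterval(chrom, s, e, strand) for s, e in u5]
            gene.utr3_intervals = [GenomicInterval(chrom, s, e, strand) for s, e in u3]
        genes[gene_id] = gene

    if essential_gene_list is not None:
        with open(essential_gene_list) as fh:
            for raw in fh:
                name = raw.strip().split("\t")[0]
                if not name or name == "gene_id":
                    continue
                if name in genes:
                    genes[name].essential = True
                else:
                    warnings.warn(f"essential gene {name!r} not in annotation; ignored")

    return AnnotationIndex(genes)


# -- sequence identity ------------------------------------------------------

def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: matches / alignment columns.

    Needleman-Wunsch with unit match score, zero mismatch score and a linear
    gap penalty of 1 per gapped base; a gap column counts as non-identical.
    Among equal-scoring moves the traceback prefers diagonal, then a gap in
    the second sequence, then a gap in the first (a fixed rule, so the
    reported identity is deterministic).  Symmetric in its arguments up to
    that tie-break; identical sequences give 1.0.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    a, b = seq_a.upper(), seq_b.upper()
    if (len(b), b) < (len(a), a):
        a, b = b, a  # canonical order makes the tie-break exactly symmetric
    la, lb = len(a), len(b)
    score = np.zeros((la + 1, lb + 1), dtype=np.int64)
    score[:, 0] = -np.arange(la + 1)
    score[0, :] = -np.arange(lb + 1)
    bvec = np.frombuffer(b.encode(), dtype=np.uint8)
    avec = np.frombuffer(a.encode(), dtype=np.uint8)
    for i in range(1, la + 1):
        diag = score[i - 1, :-1] + (bvec == avec[i - 1])
        up = score[i - 1, 1:] - 1
        best = np.maximum(diag, up)
        row = score[i]
        for j in range(1, lb + 1):  # left-dependency forces the inner loop
            row[j] = max(best[j - 1], row[j - 1] - 1)
    # traceback with the fixed move preference
    i, j, matches, columns = la, lb, 0, 0
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            m = int(a[i - 1] == b[j - 1])
            if score[i, j] == score[i - 1, j - 1] + m:
                matches += m
                i, j = i - 1, j - 1
                columns += 1
                continue
        if i > 0 and score[i, j] == score[i - 1, j] - 1:
            i -= 1
        else:
            j -= 1
        columns += 1
    return matches / columns


# -- small format helpers ----------------------------------------------------


def read_bed(path: str) -> list[tuple[str, GenomicInterval, float]]:
    """Read BED (first 6 columns used; narrowPeak tolerated).

    Returns (name, interval, score) tuples; 0-based half-open as on disk.
    """
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 and f[3] != "." else f"peak_{i}"
            score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
            strand = f[5] if len(f) > 5 else "."
            out.append((name, GenomicInterval(chrom, start, end, strand), score))
    return out


def write_bed(path: str, records) -> None:
    with open(path, "w") as fh:
        for name, iv, score in records:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n")


def read_orf_fasta(path: str) -> dict[str, str]:
    """ORF sequences keyed by record id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
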