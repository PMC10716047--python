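"""Ribo-seq QC and translated-ORF calling.

Each ribosome-protected fragment (RPF) is represented by its 5' end.  A
metagene profile around annotated start codons gives a per-read-length P-site
offset; shifted reads yield the three-frame count distribution and the
dominant-frame fraction f_d.  ATG-initiated candidate ORFs on lncRNA
transcripts are then tested for active translation by comparing per-codon
in-frame P-site counts against the pooled off-frame counts with a one-sided
Wilcoxon rank-sum test; ORFs with p below the calling threshold are reported,
keeping only the longest ATG ORF per stop codon ("longest mode").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import rank_sum_test
from .genome import AnnotationIndex, GeneModel, GenomicInterval, OrfRecord

__all__ = [
    "RpfProfile",
    "MetageneProfile",
    "FrameQc",
    "OrfTranslationResult",
    "read_rpf_profiles",
    "write_rpf_profiles",
    "build_metagene",
    "estimate_psite_offset",
    "frame_distribution",
    "psite_codon_counts",
    "test_orf_translation",
    "enumerate_candidate_orfs",
    "call_orfs",
    "merge_orfs",
    "transcript_to_genomic_blocks",
    "qc_report",
]

# window around anchor codons for the metagene profile: -40..+20 inclusive
METAGENE_LO, METAGENE_HI = -40, 20
# P-site offsets are searched among 5'-end positions -18..-6 relative to the
# start codon (brackets the canonical ~12-13 nt distance)
OFFSET_LO, OFFSET_HI = -18, -6
# read-length band admitted to P-site analysis (gel excision is ~28-30 nt;
# a tolerant band is used)
MIN_READ_LEN, MAX_READ_LEN = 25, 35


@dataclass
class RpfProfile:
    """Per-transcript RPF 5'-end counts, one vector per read length."""

    transcript_id: str
    length: int  # transcript length in nt
    counts: dict[int, np.ndarray] = field(default_factory=dict)

    def add_read(self, read_length: int, position: int) -> None:
        if not 0 <= position < self.length:
            return
        vec = self.counts.get(read_length)
        if vec is None:
            vec = self.counts[read_length] = np.zeros(self.length, dtype=np.int64)
        vec[position] += 1

    def shifted_psites(self, offsets: dict[int, int]) -> np.ndarray:
        """Pooled P-site counts per transcript position after per-length shift."""
        pooled = np.zeros(self.length, dtype=np.int64)
        for read_length, vec in self.counts.items():
            off = offsets.get(read_length)
            if off is None:
                continue
            pooled[off:] += vec[: self.length - off]
        return pooled


@dataclass
class MetageneProfile:
    """Summed 5'-end counts over offsets -40..+20 from an anchor codon."""

    anchor: str  # "start" | "stop"
    profiles: dict[int, np.ndarray] = field(default_factory=dict)  # length -> len-61

    @staticmethod
    def index_of(rel_pos: int) -> int:
        return rel_pos - METAGENE_LO


@dataclass
class FrameQc:
    """Per-read-length three-frame counts and the dominant-frame fraction."""

    frame_counts: dict[int, tuple[int, int, int]]

    @property
    def totals(self) -> tuple[int, int, int]:
        agg = np.zeros(3, dtype=np.int64)
        for c in self.frame_counts.values():
            agg += np.asarray(c)
        return tuple(int(x) for x in agg)

    @property
    def f_d(self) -> float | None:
        n0, n1, n2 = self.totals
        total = n0 + n1 + n2
        if total == 0:
            return None
        return max(n0, n1, n2) / total


@dataclass
class OrfTranslationResult:
    orf_id: str
    in_frame: np.ndarray
    off_frame: tuple[np.ndarray, np.ndarray]
    statistic: float
    p: float


# -- profile I/O -------------------------------------------------------------


def read_rpf_profiles(
    path: str, transcript_lengths: dict[str, int]
) -> dict[str, RpfProfile]:
    """Read a TSV of (transcript_id, read_length, position, count) records."""
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "read_length", "position", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"RPF TSV must have columns {sorted(required)}")
    profiles: dict[str, RpfProfile] = {}
    for tx_id, grp in df.groupby("transcript_id", sort=True):
        tx_id = str(tx_id)
        if tx_id not in transcript_lengths:
            raise ValueError(f"unknown transcript {tx_id!r} in RPF profile")
        prof = RpfProfile(tx_id, transcript_lengths[tx_id])
        for rl, sub in grp.groupby("read_length"):
            vec = np.zeros(prof.length, dtype=np.int64)
            pos = sub["position"].to_numpy()
            if (pos < 0).any() or (pos >= prof.length).any():
                raise ValueError(f"position out of range for {tx_id}")
            np.add.at(vec, pos, sub["count"].to_numpy())
            prof.counts[int(rl)] = vec
        profiles[tx_id] = prof
    return profiles


def write_rpf_profiles(path: str, profiles: dict[str, RpfProfile]) -> None:
    rows = []
    for tx_id in sorted(profiles):
        prof = profiles[tx_id]
        for rl in sorted(prof.counts):
            vec = prof.counts[rl]
            for pos in np.nonzero(vec)[0]:
                rows.append((tx_id, rl, int(pos), int(vec[pos])))
    pd.DataFrame(
        rows, columns=["transcript_id", "read_length", "position", "count"]
    ).to_csv(path, sep="\t", index=False)


# -- metagene / offsets / frames ---------------------------------------------


def _coding_anchors(
    annotation: AnnotationIndex, anchor: str
) -> list[tuple[str, int]]:
    """(transcript_id, transcript position of the first base of the anchor codon).

    Assumes single-transcript coding genes whose transcript id equals the key
    in ``GeneModel.transcripts``; the anchor position is derived from the
    exon/CDS structure in transcript coordinates.
    """
    anchors = []
    for gene in annotation.coding_genes():
        if not gene.cds_intervals:
            continue
        for tx_id, tx_exons in gene.transcripts.items():
            pos = _genomic_to_transcript(
                gene, tx_exons,
                (gene.cds_intervals[0].start if gene.strand == "+"
                 else gene.cds_intervals[-1].end - 1)
                if anchor == "start"
                else (gene.cds_intervals[-1].end - 3 if gene.strand == "+"
                      else gene.cds_intervals[0].start + 2),
            )
            if pos is not None:
                anchors.append((tx_id, pos))
    return anchors


def _genomic_to_transcript(
    gene: GeneModel, tx_exons: list[GenomicInterval], gpos: int
) -> int | None:
    """Map a genomic base to its transcript coordinate (strand-aware)."""
    offset = 0
    if gene.strand == "+":
        for iv in tx_exons:
            if iv.start <= gpos < iv.end:
                return offset + (gpos - iv.start)
            offset += len(iv)
    else:
        for iv in reversed(tx_exons):
            if iv.start <= gpos < iv.end:
                return offset + (iv.end - 1 - gpos)
            offset += len(iv)
    return None


def build_metagene(
    profiles: dict[str, RpfProfile],
    annotation: AnnotationIndex,
    anchor: str = "start",
) -> MetageneProfile:
    """Sum 5'-end counts over -40..+20 around annotated start (or stop) codons."""
    if anchor not in ("start", "stop"):
        raise ValueError("anchor must be 'start' or 'stop'")
    anchors = _coding_anchors(annotation, anchor)
    if not anchors:
        raise ValueError("no anchors: annotation has no coding transcripts")
    meta = MetageneProfile(anchor=anchor)
    width = METAGENE_HI - METAGENE_LO + 1
    for tx_id, anchor_pos in anchors:
        prof = profiles.get(tx_id)
        if prof is None:
            continue
        lo = anchor_pos + METAGENE_LO
        hi = anchor_pos + METAGENE_HI + 1
        src_lo, src_hi = max(lo, 0), min(hi, prof.length)
        if src_lo >= src_hi:
            continue
        for rl, vec in prof.counts.items():
            dest = meta.profiles.get(rl)
            if dest is None:
                dest = meta.profiles[rl] = np.zeros(width, dtype=np.int64)
            dest[src_lo - lo : src_hi - lo] += vec[src_lo:src_hi]
    return meta


def estimate_psite_offset(metagene: MetageneProfile) -> dict[int, int]:
    """Per-read-length P-site offset from the start-codon metagene.

    The offset is the negated argmax 5'-end position within [-18, -6]; ties
    resolve to the smaller offset.  Read lengths with no counts in the window,
    or outside the admitted length band, are dropped.
    """
    if metagene.anchor != "start":
        raise ValueError("offsets are estimated from the start-anchored metagene")
    if not metagene.profiles:
        raise ValueError("empty metagene")
    offsets: dict[int, int] = {}
    lo_idx = MetageneProfile.index_of(OFFSET_LO)
    hi_idx = MetageneProfile.index_of(OFFSET_HI) + 1
    for rl in sorted(metagene.profiles):
        if not MIN_READ_LEN <= rl <= MAX_READ_LEN:
            continue
        window = metagene.profiles[rl][lo_idx:hi_idx]
        if window.sum() == 0:
            continue
        # argmax scanning from the -6 end keeps the smaller offset on ties
        best = int(np.argmax(window[::-1]))
        rel_pos = OFFSET_HI - best
        offsets[rl] = -rel_pos
    return offsets


def frame_distribution(
    profiles: dict[str, RpfProfile],
    annotation: AnnotationIndex,
    offsets: dict[int, int],
) -> FrameQc:
    """Three-frame RPF distribution over annotated coding regions.

    5'-end positions from 15 bp upstream of the start codon to 12 bp upstream
    of the stop codon contribute; each read's frame is computed from its
    P-site-shifted position relative to the start codon.
    """
    frame_counts: dict[int, np.ndarray] = {}
    stop_anchors = dict(_coding_anchors(annotation, "stop"))
    for tx_id, start_pos in _coding_anchors(annotation, "start"):
        prof = profiles.get(tx_id)
        if prof is None:
            continue
        stop_pos = stop_anchors.get(tx_id)
        if stop_pos is None:
            continue
        lo = max(0, start_pos - 15)
        hi = min(prof.length, stop_pos - 12)
        if hi <= lo:
            continue
        for rl, vec in prof.counts.items():
            off = offsets.get(rl)
            if off is None:
                continue
            acc = frame_counts.setdefault(rl, np.zeros(3, dtype=np.int64))
            positions = np.arange(lo, hi)
            frames = (positions + off - start_pos) % 3
            for f in range(3):
                acc[f] += vec[lo:hi][frames == f].sum()
    return FrameQc(
        frame_counts={
            rl: tuple(int(x) for x in acc) for rl, acc in frame_counts.items()
        }
    )


# -- ORF-level translation test ----------------------------------------------


def psite_codon_counts(
    profile: RpfProfile, orf: OrfRecord, offsets: dict[int, int]
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Per-codon P-site counts at codon bases 0 (in-frame) and 1/2 (off-frame).

    The stop codon is excluded.  ORFs extending beyond the transcript are an
    error.
    """
    n_codons = orf.n_codons
    if orf.transcript_start < 0 or orf.transcript_stop + 3 > profile.length:
        raise ValueError(f"ORF {orf.orf_id} outside transcript bounds")
    psites = profile.shifted_psites(offsets)
    block = psites[orf.transcript_start : orf.transcript_stop].reshape(n_codons, 3)
    return block[:, 0].copy(), (block[:, 1].copy(), block[:, 2].copy())


def test_orf_translation(
    in_frame: np.ndarray,
    off_frame: tuple[np.ndarray, np.ndarray],
    orf_id: str = "",
) -> OrfTranslationResult:
    """One-sided rank-sum test of in-frame vs pooled off-frame codon counts.

    Exact permutation enumeration when the pooled sample size is small
    (<= 12 values), tie-corrected normal approximation otherwise.  All-zero
    input yields p = 1.
    """
    in_frame = np.asarray(in_frame)
    off_a, off_b = (np.asarray(v) for v in off_frame)
    if not (len(in_frame) == len(off_a) == len(off_b)):
        raise ValueError("in-frame and off-frame vectors must have equal length")
    if len(in_frame) < 1:
        raise ValueError("need at least one codon")
    pooled_off = np.concatenate([off_a, off_b])
    w, p = rank_sum_test(in_frame, pooled_off, alternative="greater", exact_max_n=12)
    return OrfTranslationResult(orf_id, in_frame, (off_a, off_b), w, p)


# -- ORF enumeration and calling ---------------------------------------------

_STOPS = ("TAA", "TAG", "TGA")


def enumerate_candidate_orfs(sequence: str) -> list[tuple[int, int]]:
    """Longest ATG-initiated ORF per stop codon, in all three frames.

    Returns (start, stop) transcript positions of the first bases of the
    start and stop codons.
    """
    seq = sequence.upper()
    candidates = []
    for frame in range(3):
        first_atg: int | None = None
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in _STOPS:
                if first_atg is not None:
                    candidates.append((first_atg, pos))
                first_atg = None
            elif codon == "ATG" and first_atg is None:
                first_atg = pos
    return candidates


def transcript_to_genomic_blocks(
    gene: GeneModel,
    tx_exons: list[GenomicInterval],
    tx_start: int,
    tx_end: int,
) -> list[GenomicInterval]:
    """Project a transcript interval [tx_start, tx_end) onto the genome."""
    blocks: list[tuple[int, int]] = []
    offset = 0
    exons = tx_exons if gene.strand == "+" else list(reversed(tx_exons))
    for iv in exons:
        exon_len = len(iv)
        seg_lo = max(tx_start, offset)
        seg_hi = min(tx_end, offset + exon_len)
        if seg_lo < seg_hi:
            if gene.strand == "+":
                blocks.append((iv.start + (seg_lo - offset), iv.start + (seg_hi - offset)))
            else:
                blocks.append((iv.end - (seg_hi - offset), iv.end - (seg_lo - offset)))
        offset += exon_len
    return [
        GenomicInterval(gene.chrom, s, e, gene.strand) for s, e in sorted(blocks)
    ]


_CODON_TABLE = None


def _translate(nt: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(nt).translate(to_stop=False)).rstrip("*")


def call_orfs(
    transcripts: dict[str, tuple[str, str]],
    profiles: dict[str, RpfProfile],
    offsets: dict[int, int],
    annotation: AnnotationIndex | None = None,
    p_threshold: float = 0.05,
) -> list[OrfRecord]:
    """Call actively translated ATG ORFs on lncRNA transcripts.

    ``transcripts`` maps transcript_id -> (host_gene_id, nt sequence).  For
    each stop codon only the longest ATG ORF is tested; ORFs with translation
    p < ``p_threshold`` are returned with ``ribo_p`` set, ordered by
    transcript id and coordinate.
    """
    called: list[OrfRecord] = []
    for tx_id in sorted(transcripts):
        gene_id, seq = transcripts[tx_id]
        prof = profiles.get(tx_id)
        for tx_start, tx_stop in enumerate_candidate_orfs(seq):
            nt = seq[tx_start : tx_stop + 3]
            orf_id = f"{tx_id}:{tx_start}-{tx_stop}"
            orf = OrfRecord(
                orf_id=orf_id,
                host_gene=gene_id,
                transcript_id=tx_id,
                transcript_start=tx_start,
                transcript_stop=tx_stop,
                nt_sequence=nt,
                aa_sequence=_translate(nt),
            )
            if annotation is not None and gene_id in annotation.genes:
                gene = annotation.genes[gene_id]
                tx_exons = gene.transcripts.get(tx_id, gene.exon_intervals)
                orf.genomic_blocks = transcript_to_genomic_blocks(
                    gene, tx_exons, tx_start, tx_stop + 3
                )
            if prof is None:
                continue
            in_f, off_f = psite_codon_counts(prof, orf, offsets)
            result = test_orf_translation(in_f, off_f, orf_id)
            orf.ribo_p = result.p
            if result.p < p_threshold:
                called.append(orf)
    return called


def merge_orfs(orf_lists: list[list[OrfRecord]]) -> list[OrfRecord]:
    """Merge identical ORFs across libraries/isoforms, keeping the minimum p.

    Identity means the same genomic start-codon position and the same genomic
    stop position (chrom and strand included); output is sorted by coordinate.
    """
    merged: dict[tuple, OrfRecord] = {}
    for orfs in orf_lists:
        for orf in orfs:
            if orf.genomic_blocks:
                blocks = orf.genomic_blocks
                key = (blocks[0].chrom, blocks[0].strand, blocks[0].start, blocks[-1].end)
            else:
                key = (orf.transcript_id, ".", orf.transcript_start, orf.transcript_stop)
            prev = merged.get(key)
            if prev is None or _p_or_1(orf) < _p_or_1(prev):
                merged[key] = orf
    return [merged[k] for k in sorted(merged, key=lambda k: (k[0], k[2], k[3], k[1]))]


def _p_or_1(orf: OrfRecord) -> float:
    return 1.0 if orf.ribo_p is None else orf.ribo_p


def qc_report(
    profiles: dict[str, RpfProfile],
    metagene: MetageneProfile,
    offsets: dict[int, int],
    frame_qc: FrameQc,
) -> pd.DataFrame:
    """One row per read length: (length, n_reads, offset, f_d)."""
    n_reads = {}
    for prof in profiles.values():
        for rl, vec in prof.counts.items():
            n_reads[rl] = n_reads.get(rl, 0) + int(vec.sum())
    rows = []
    for rl in sorted(n_reads):
        counts = frame_qc.frame_counts.get(rl)
        if counts and sum(counts) > 0:
            fd = max(counts) / sum(counts)
        else:
            fd = np.nan
        rows.append((rl, n_reads[rl], offsets.get(rl, pd.NA), fd))
    return pd.DataFrame(rows, columns=["length", "n_reads", "offset", "f_d"])
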