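"""Seeded generators for every input the pipeline consumes.

The generators emulate the structure of the study's inputs at desk scale:
a compact annotation with protein-coding genes and lncRNAs (a subset of
which sit right next to coding-gene features, to exercise the 15-bp
neighbor filter), periodic ribosome-profiling profiles with planted P-site
offsets, negative-binomial screen counts with planted depleted ORFs and
deliberately cut-site-confounded guides, tumor/normal TPM cohorts with
planted effect sizes and subtype structure, TSS-proximal peak sets and an
AP-MS peptide table.  Every generator is a pure function of its parameters
and a seed; ground truth is recorded in a manifest sufficient to score every
recovery test.

Default study conditions mirror the screen design the pipeline targets:
three day-0 and six day-21 replicates, ~500x mean coverage per guide,
NB dispersion 0.05, depletion effect log2FC = -2, 5 guides per ORF, and a
lognormal (sigma = 1) abundance baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import AnnotationIndex, load_annotation
from .guides import GuideRecord, LibraryManifest, write_library
from .riboseq import RpfProfile, _coding_anchors, write_rpf_profiles

__all__ = [
    "SimBundle",
    "simulate_annotation",
    "simulate_rpf",
    "simulate_library",
    "simulate_screen",
    "simulate_expression",
    "simulate_peaks",
    "simulate_apms",
    "simulate",
    "simulate_riboseq_scenario",
]

_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA", "ATG")
]

DEFAULT_OFFSETS = {28: 12, 29: 12, 30: 13}


def _rng_of(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


# -- annotation ---------------------------------------------------------------


@dataclass
class AnnotationSim:
    gtf_text: str
    essentials: list[str]
    lnc_transcripts: dict[str, tuple[str, str]]  # tx -> (gene, sequence)
    orfs: list[dict]  # planted lncRNA ORFs with tx/genomic coordinates
    near_lnc: dict[str, tuple[int, int]]  # lnc gene -> adjacent CDS interval
    chrom: str = "chrS1"

    def load(self, tmp_dir: str | Path) -> AnnotationIndex:
        tmp_dir = Path(tmp_dir)
        gtf = tmp_dir / "annotation.gtf"
        ess = tmp_dir / "essentials.tsv"
        gtf.write_text(self.gtf_text)
        ess.write_text("\n".join(self.essentials) + ("\n" if self.essentials else ""))
        return load_annotation(str(gtf), str(ess) if self.essentials else None)


def _gtf_line(chrom, feature, start0, end0, strand, gene_id, gene_type, tx_id=None):
    attrs = f'gene_id "{gene_id}"; gene_type "{gene_type}";'
    if tx_id:
        attrs += f' transcript_id "{tx_id}";'
    return f"{chrom}\tsim\t{feature}\t{start0 + 1}\t{end0}\t.\t{strand}\t.\t{attrs}\n"


def simulate_annotation(
    seed=0,
    n_coding: int = 20,
    n_lncrna: int = 10,
    essential_fraction: float = 0.3,
    n_near: int = 0,
    min_codons: int = 20,
    max_codons: int = 80,
) -> AnnotationSim:
    """Simulate a GTF with coding genes and ORF-bearing lncRNAs.

    ``n_near`` lncRNAs are placed within 200 bp of a coding gene (their
    adjacent CDS interval is recorded for planting cut-site conflicts); the
    rest sit kilobases away from everything.  Every lncRNA transcript
    carries exactly one planted ATG ORF preceded by an in-frame stop, so the
    planted ORF is the longest for its stop codon.
    """
    if n_coding < 1 or n_lncrna < 1:
        raise ValueError("need at least one coding gene and one lncRNA")
    if n_near > min(n_coding, n_lncrna):
        raise ValueError("cannot place more near-lncRNAs than genes allow")
    rng = _rng_of(seed)
    chrom = "chrS1"
    gtf, essentials = [], []
    lnc_transcripts: dict[str, tuple[str, str]] = {}
    orfs: list[dict] = []
    near_lnc: dict[str, tuple[int, int]] = {}

    def add_lnc(idx: int, start: int) -> int:
        gene_id, tx_id = f"LNC{idx:04d}", f"LNC{idx:04d}-T1"
        tx_start_pos = int(rng.integers(60, 180)) * 3  # keep ORF frame 0
        n_codons = int(rng.integers(min_codons, max_codons + 1))
        tail = int(rng.integers(60, 240))
        length = tx_start_pos + 3 * (n_codons + 1) + tail
        seq = list(_random_seq(rng, length))
        # in-frame stop immediately before the planted ATG
        seq[tx_start_pos - 3 : tx_start_pos] = "TAA"
        seq[tx_start_pos : tx_start_pos + 3] = "ATG"
        body = rng.choice(_NON_STOP_CODONS, size=n_codons - 1)
        for k, codon in enumerate(body, start=1):
            seq[tx_start_pos + 3 * k : tx_start_pos + 3 * k + 3] = codon
        stop_tx = tx_start_pos + 3 * n_codons
        seq[stop_tx : stop_tx + 3] = "TAA"
        seq = "".join(seq)
        end = start + length
        gtf.append(_gtf_line(chrom, "gene", start, end, "+", gene_id, "lncRNA"))
        gtf.append(_gtf_line(chrom, "transcript", start, end, "+", gene_id, "lncRNA", tx_id))
        gtf.append(_gtf_line(chrom, "exon", start, end, "+", gene_id, "lncRNA", tx_id))
        lnc_transcripts[tx_id] = (gene_id, seq)
        orfs.append(
            {
                "orf_id": f"{tx_id}:{tx_start_pos}-{stop_tx}",
                "host_gene": gene_id,
                "transcript_id": tx_id,
                "transcript_start": tx_start_pos,
                "transcript_stop": stop_tx,
                "n_codons": n_codons,
                "chrom": chrom,
                "g_start": start + tx_start_pos,
                "g_end": start + stop_tx + 3,
                "strand": "+",
                "nt_sequence": seq[tx_start_pos : stop_tx + 3],
            }
        )
        return end

    cursor = 1_000
    lnc_idx = 0
    for i in range(n_coding):
        gene_id, tx_id = f"PC{i:04d}", f"PC{i:04d}-T1"
        strand = "+" if rng.random() < 0.5 else "-"
        u5 = int(rng.integers(100, 200))
        cds_len = 3 * int(rng.integers(100, 300))
        u3 = int(rng.integers(100, 300))
        start, end = cursor, cursor + u5 + cds_len + u3
        cds_lo = start + (u5 if strand == "+" else u3)
        cds_hi = cds_lo + cds_len
        gtf.append(_gtf_line(chrom, "gene", start, end, strand, gene_id, "protein_coding"))
        gtf.append(_gtf_line(chrom, "transcript", start, end, strand, gene_id, "protein_coding", tx_id))
        gtf.append(_gtf_line(chrom, "exon", start, end, strand, gene_id, "protein_coding", tx_id))
        gtf.append(_gtf_line(chrom, "CDS", cds_lo, cds_hi, strand, gene_id, "protein_coding", tx_id))
        if rng.random() < essential_fraction:
            essentials.append(gene_id)
        cursor = end
        if lnc_idx < n_near:
            gap = int(rng.integers(20, 180))
            lnc_start = cursor + gap
            lnc_end = add_lnc(lnc_idx, lnc_start)
            near_lnc[f"LNC{lnc_idx:04d}"] = (cds_lo, cds_hi)
            lnc_idx += 1
            cursor = lnc_end
        cursor += 3_000
    while lnc_idx < n_lncrna:
        cursor = add_lnc(lnc_idx, cursor) + 3_000
        lnc_idx += 1

    return AnnotationSim(
        gtf_text="".join(gtf),
        essentials=essentials,
        lnc_transcripts=lnc_transcripts,
        orfs=orfs,
        near_lnc=near_lnc,
        chrom=chrom,
    )


# -- ribo-seq -----------------------------------------------------------------


def _length_weights(lengths: list[int]) -> np.ndarray:
    # peaked distribution centered on the middle read length
    n = len(lengths)
    center = (n - 1) / 2.0
    w = np.array([1.0 / (1.0 + abs(i - center)) for i in range(n)])
    return w / w.sum()


def simulate_rpf(
    annotation: AnnotationIndex,
    orf_catalog: list[dict],
    translated_orf_ids: set[str],
    offsets: dict[int, int] | None = None,
    periodicity: float = 0.9,
    reads_per_codon: float = 50.0,
    background_per_nt: float = 0.2,
    initiation_boost: float = 3.0,
    seed=0,
) -> dict[str, RpfProfile]:
    """Simulate RPF 5'-end profiles with a planted per-length P-site offset.

    Annotated coding CDSs and the translated lncRNA ORFs receive periodic
    reads (``periodicity`` = probability a read's P-site falls on codon base
    0); the initiation codon is overrepresented by ``initiation_boost`` (the
    ribosome pause at starts that produces the metagene peak); every
    transcript also receives uniform background.  5' ends are placed at
    P-site minus the planted offset for the read's length.
    """
    if not 1 / 3 <= periodicity <= 1:
        raise ValueError("periodicity must lie in [1/3, 1]")
    offsets = dict(DEFAULT_OFFSETS) if offsets is None else offsets
    rng = _rng_of(seed)
    lengths = sorted(offsets)
    weights = _length_weights(lengths)

    tx_length: dict[str, int] = {}
    for gene in annotation.genes.values():
        for tx_id, exons in gene.transcripts.items():
            tx_length[tx_id] = sum(len(iv) for iv in exons)
    profiles = {
        tx_id: RpfProfile(tx_id, L) for tx_id, L in sorted(tx_length.items())
    }

    regions: list[tuple[str, int, int]] = []  # (tx, start, n_codons)
    starts = dict(_coding_anchors(annotation, "start"))
    stops = dict(_coding_anchors(annotation, "stop"))
    for tx_id in sorted(starts):
        if tx_id in stops and stops[tx_id] > starts[tx_id]:
            regions.append((tx_id, starts[tx_id], (stops[tx_id] - starts[tx_id]) // 3))
    for orf in orf_catalog:
        if orf["orf_id"] in translated_orf_ids:
            regions.append(
                (orf["transcript_id"], orf["transcript_start"], orf["n_codons"])
            )

    p_base = np.array([periodicity, (1 - periodicity) / 2, (1 - periodicity) / 2])
    off_arr = np.array([offsets[rl] for rl in lengths])
    for tx_id, start, n_codons in regions:
        prof = profiles[tx_id]
        n_reads = rng.poisson(reads_per_codon * (n_codons - 1 + initiation_boost))
        if n_reads == 0:
            continue
        codon_w = np.ones(n_codons)
        codon_w[0] = initiation_boost
        codon = rng.choice(n_codons, size=n_reads, p=codon_w / codon_w.sum())
        base = rng.choice(3, size=n_reads, p=p_base)
        li = rng.choice(len(lengths), size=n_reads, p=weights)
        five = start + 3 * codon + base - off_arr[li]
        ok = (five >= 0) & (five < prof.length)
        for rl_idx in range(len(lengths)):
            sel = ok & (li == rl_idx)
            if not sel.any():
                continue
            vec = prof.counts.setdefault(
                lengths[rl_idx], np.zeros(prof.length, dtype=np.int64)
            )
            np.add.at(vec, five[sel], 1)
    # uniform background on every transcript
    for tx_id in sorted(profiles):
        prof = profiles[tx_id]
        n_bg = rng.poisson(background_per_nt * prof.length)
        if n_bg == 0:
            continue
        pos = rng.integers(0, prof.length, size=n_bg)
        li = rng.choice(len(lengths), size=n_bg, p=weights)
        for rl_idx in range(len(lengths)):
            sel = li == rl_idx
            if not sel.any():
                continue
            vec = prof.counts.setdefault(
                lengths[rl_idx], np.zeros(prof.length, dtype=np.int64)
            )
            np.add.at(vec, pos[sel], 1)
    return {tx: p for tx, p in profiles.items() if p.counts}


# -- sgRNA library ------------------------------------------------------------


def _random_protospacer(rng: np.random.Generator) -> str:
    # rejection-sample a spacer that passes the library filters
    while True:
        s = _random_seq(rng, 20)
        gc = (s.count("G") + s.count("C")) / 20
        if "TTTT" not in s and gc <= 0.60:
            return s


def _guide_at(rng, guide_id, chrom, cut_site, guide_class, target_orf) -> GuideRecord:
    from .genome import GenomicInterval

    # plus-strand geometry: protospacer [cut-16, cut+4), PAM [cut+4, cut+7)
    return GuideRecord(
        guide_id=guide_id,
        protospacer=_random_protospacer(rng),
        chrom=chrom,
        strand="+",
        protospacer_interval=GenomicInterval(chrom, cut_site - 16, cut_site + 4, "+"),
        pam_interval=GenomicInterval(chrom, cut_site + 4, cut_site + 7, "+"),
        guide_class=guide_class,
        target_orf=target_orf,
        efficiency=float(np.round(rng.uniform(0.2, 1.0), 4)),
        genome_hits=1,
    )


def simulate_library(
    sim: AnnotationSim,
    orf_ids: list[str] | None = None,
    n_guides_per_orf: int = 5,
    confounded_orfs: set[str] | None = None,
    n_positive: int = 30,
    n_negative: int = 100,
    seed=0,
) -> LibraryManifest:
    """Build a synthetic guide library over the planted ORFs.

    Guides for ``confounded_orfs`` have their cut sites planted within 15 bp
    of the CDS of the lncRNA's adjacent coding gene (such ORFs must belong
    to near-lncRNA hosts); all other targeting guides cut inside the ORF
    body, far from any coding feature.  Controls live on a chromosome absent
    from the annotation.
    """
    rng = _rng_of(seed)
    confounded_orfs = confounded_orfs or set()
    orf_by_id = {o["orf_id"]: o for o in sim.orfs}
    orf_ids = sorted(orf_by_id) if orf_ids is None else list(orf_ids)
    guides: list[GuideRecord] = []
    for orf_id in orf_ids:
        orf = orf_by_id[orf_id]
        for j in range(n_guides_per_orf):
            gid = f"sg_{orf_id}_{j}"
            if orf_id in confounded_orfs:
                if orf["host_gene"] not in sim.near_lnc:
                    raise ValueError(
                        f"confounded ORF {orf_id} host is not a near-lncRNA"
                    )
                cds_lo, cds_hi = sim.near_lnc[orf["host_gene"]]
                cut = cds_hi + int(rng.integers(0, 11))  # within 15 bp of CDS
            else:
                lo = orf["g_start"] + 17
                hi = max(lo + 1, orf["g_end"] - 5)
                cut = int(rng.integers(lo, hi))
            guides.append(_guide_at(rng, gid, sim.chrom, cut, "targeting", orf_id))
    for i in range(n_positive):
        guides.append(
            _guide_at(rng, f"sg_pos_{i:04d}", "chrCTRL", 1_000 + 100 * i,
                      "positive_control", "")
        )
    for i in range(n_negative):
        guides.append(
            _guide_at(rng, f"sg_neg_{i:04d}", "chrCTRL", 200_000 + 100 * i,
                      "negative_control", "")
        )
    return LibraryManifest(guides=guides)


# -- screen counts ------------------------------------------------------------


def _nb_draw(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_screen(
    library: LibraryManifest,
    effects: dict[str, float],
    dispersion: float = 0.05,
    depth: float = 500.0,
    n_day0: int = 3,
    n_day21: int = 6,
    positive_control_log2fc: float = -3.0,
    sample_depth_sigma: float = 0.15,
    seed=0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate guide x sample NB counts for a day-0 / day-21 dropout screen.

    ``effects`` maps orf_id -> log2 fold change (<= 0 for depleted ORFs);
    guides of unlisted ORFs and negative controls have effect 0, positive
    controls ``positive_control_log2fc``.  Baseline guide abundances are
    lognormal (sigma = 1) scaled to a mean of ``depth`` counts per guide.
    Returns (counts, conditions).
    """
    if any(e > 0 for e in effects.values()):
        raise ValueError("depletion effects must be <= 0")
    rng = _rng_of(seed)
    guides = library.guides
    n = len(guides)
    abundance = rng.lognormal(0.0, 1.0, size=n)
    base_mean = depth * abundance / abundance.mean()
    effect = np.zeros(n)
    for i, g in enumerate(guides):
        if g.guide_class == "positive_control":
            effect[i] = positive_control_log2fc
        elif g.guide_class == "targeting":
            effect[i] = effects.get(g.target_orf, 0.0)
    samples = [f"D0_{r + 1}" for r in range(n_day0)] + [
        f"D21_{r + 1}" for r in range(n_day21)
    ]
    conditions = pd.Series(
        ["day0"] * n_day0 + ["day21"] * n_day21, index=samples, name="condition"
    )
    cols = {}
    for s in samples:
        sf = rng.lognormal(0.0, sample_depth_sigma)
        mean = base_mean * sf * (2.0 ** effect if conditions[s] == "day21" else 1.0)
        cols[s] = _nb_draw(rng, mean, dispersion)
    counts = pd.DataFrame(cols, index=[g.guide_id for g in guides])
    return counts, conditions


# -- expression ---------------------------------------------------------------


def simulate_expression(
    gene_ids: list[str],
    tumor_up: dict[str, float] | None = None,
    subtype_high: dict[str, tuple[str, float]] | None = None,
    n_tumor: int = 100,
    n_normal: int = 100,
    subtype_proportions: dict[str, float] | None = None,
    noise_sigma: float = 0.5,
    seed=0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Simulate a lognormal TPM cohort with planted tumor/subtype effects.

    ``tumor_up`` maps gene -> log2 effect applied to tumor samples (negative
    values plant tumor-downregulation); ``subtype_high`` maps gene ->
    (subtype, log2 effect) applied only to tumor samples of that subtype.
    Returns (tpm, cohort, subtype) with samples T0001.../N0001....
    """
    tumor_up = tumor_up or {}
    subtype_high = subtype_high or {}
    props = subtype_proportions or {
        "CMS1": 0.20, "CMS2": 0.30, "CMS3": 0.20, "CMS4": 0.20, "NA": 0.10,
    }
    if abs(sum(props.values()) - 1.0) > 1e-9:
        raise ValueError("subtype proportions must sum to 1")
    rng = _rng_of(seed)
    genes = list(gene_ids)
    tumors = [f"T{i + 1:04d}" for i in range(n_tumor)]
    normals = [f"N{i + 1:04d}" for i in range(n_normal)]
    subtype_labels = list(props)
    tumor_subtype = rng.choice(
        subtype_labels, size=n_tumor, p=[props[s] for s in subtype_labels]
    )
    base = rng.lognormal(np.log(10.0), 1.0, size=len(genes))
    tpm = pd.DataFrame(
        rng.lognormal(0.0, noise_sigma, size=(len(genes), n_tumor + n_normal)),
        index=genes,
        columns=tumors + normals,
    ).mul(base, axis=0)
    for gene, lfc in tumor_up.items():
        tpm.loc[gene, tumors] *= 2.0 ** lfc
    for gene, (subtype, lfc) in subtype_high.items():
        cols = [t for t, s in zip(tumors, tumor_subtype) if s == subtype]
        tpm.loc[gene, cols] *= 2.0 ** lfc
    cohort = pd.Series(
        ["tumor"] * n_tumor + ["normal"] * n_normal,
        index=tumors + normals, name="cohort",
    )
    subtype = pd.Series(
        list(tumor_subtype) + ["NA"] * n_normal,
        index=tumors + normals, name="subtype",
    )
    return tpm.round(4), cohort, subtype


# -- peaks & AP-MS ------------------------------------------------------------


def simulate_peaks(
    annotation: AnnotationIndex,
    bound_genes: list[str],
    flank: int = 10_000,
    decoy_count: int = 10,
    seed=0,
) -> list[tuple[str, "object", float]]:
    """One peak inside each bound gene's TSS window; decoys far from all TSSs."""
    from .genome import GenomicInterval

    rng = _rng_of(seed)
    unknown = set(bound_genes) - set(annotation.genes)
    if unknown:
        raise ValueError(f"bound genes absent from annotation: {sorted(unknown)[:5]}")
    peaks = []
    for i, gene_id in enumerate(sorted(bound_genes)):
        gene = annotation.genes[gene_id]
        width = int(rng.integers(200, 800))
        center = gene.tss + int(rng.integers(-(flank - width), flank - width))
        start = max(0, center - width // 2)
        peaks.append(
            (f"peak_{i:04d}", GenomicInterval(gene.chrom, start, start + width),
             float(np.round(rng.uniform(5, 100), 2)))
        )
    max_coord = max(
        (iv.end for g in annotation.genes.values() for iv in g.exon_intervals),
        default=0,
    )
    cursor = max_coord + 2 * flank + 10_000
    chrom = next(iter(annotation.genes.values())).chrom if annotation.genes else "chrS1"
    for i in range(decoy_count):
        width = int(rng.integers(200, 800))
        peaks.append(
            (f"decoy_{i:04d}", GenomicInterval(chrom, cursor, cursor + width),
             float(np.round(rng.uniform(5, 100), 2)))
        )
        cursor += width + 5_000
    return peaks


def simulate_apms(
    candidate_proteins: list[str],
    n_background: int = 30,
    seed=0,
) -> pd.DataFrame:
    """Unique-peptide table with planted candidates passing the AP-MS filter."""
    rng = _rng_of(seed)
    rows = []
    for prot in sorted(candidate_proteins):
        rows.append((prot, int(rng.integers(3, 12)), 0, 0))
    for i in range(n_background):
        kind = rng.random()
        if kind < 0.4:  # detected in a control
            rows.append((f"BG{i:03d}", int(rng.integers(1, 8)),
                         int(rng.integers(1, 4)), 0))
        else:  # too few bait peptides
            rows.append((f"BG{i:03d}", int(rng.integers(0, 3)), 0, 0))
    return pd.DataFrame(
        rows, columns=["protein", "pep_bait", "pep_ctrl1", "pep_ctrl2"]
    )


# -- full scenario ------------------------------------------------------------


@dataclass
class SimBundle:
    """In-memory synthetic scenario plus its ground-truth manifest."""

    seed: int
    annotation_sim: AnnotationSim
    annotation: AnnotationIndex
    library: LibraryManifest
    counts: pd.DataFrame
    conditions: pd.Series
    tpm: pd.DataFrame
    cohort: pd.Series
    subtype: pd.Series
    manifest: dict
    profiles: dict[str, RpfProfile] | None = None
    peaks: list = field(default_factory=list)
    apms: pd.DataFrame | None = None


def simulate(
    seed: int = 1,
    out_dir: str | Path | None = None,
    n_coding: int = 40,
    n_lncrna: int = 500,
    n_guides_per_orf: int = 5,
    n_depleted: int = 50,
    n_confounded: int = 10,
    n_tumor_up: int = 20,
    depletion_log2fc: float = -2.0,
    dispersion: float = 0.05,
    depth: float = 500.0,
    n_day0: int = 3,
    n_day21: int = 6,
    n_tumor: int = 100,
    n_normal: int = 100,
    essential_fraction: float = 0.3,
    with_riboseq: bool = False,
) -> SimBundle:
    """Generate the full screen-discovery scenario.

    Of ``n_depleted`` planted dependency ORFs (log2FC ``depletion_log2fc``),
    ``n_confounded`` have every guide cut-site-conflicted with a neighboring
    CDS (their depletion is pure off-target) and ``n_tumor_up`` of the clean
    remainder have tumor-upregulated host genes -- those are the true,
    recoverable dependencies.  The manifest records every planted set.
    """
    if n_confounded + n_tumor_up > n_depleted:
        raise ValueError("confounded + tumor-up cannot exceed depleted ORFs")
    if n_depleted > n_lncrna:
        raise ValueError("more depleted ORFs than lncRNAs")
    rng = np.random.default_rng(seed)
    sim = simulate_annotation(
        seed=rng,
        n_coding=n_coding,
        n_lncrna=n_lncrna,
        essential_fraction=essential_fraction,
        n_near=n_confounded,
    )
    orf_ids = [o["orf_id"] for o in sim.orfs]
    # near-lnc hosts come first in construction order -> confounded ORFs
    confounded = [
        o["orf_id"] for o in sim.orfs if o["host_gene"] in sim.near_lnc
    ][:n_confounded]
    clean_pool = [oid for oid in orf_ids if oid not in set(confounded)]
    n_clean_depleted = n_depleted - n_confounded
    clean_depleted = rng.choice(
        clean_pool, size=n_clean_depleted, replace=False
    ).tolist()
    tumor_up_orfs = clean_depleted[:n_tumor_up]
    depleted = sorted(confounded + clean_depleted)
    effects = {oid: depletion_log2fc for oid in depleted}

    library = simulate_library(
        sim,
        orf_ids=orf_ids,
        n_guides_per_orf=n_guides_per_orf,
        confounded_orfs=set(confounded),
        seed=rng,
    )
    counts, conditions = simulate_screen(
        library,
        effects,
        dispersion=dispersion,
        depth=depth,
        n_day0=n_day0,
        n_day21=n_day21,
        seed=rng,
    )

    orf_host = {o["orf_id"]: o["host_gene"] for o in sim.orfs}
    gene_ids = sorted(
        {o["host_gene"] for o in sim.orfs} | {f"PC{i:04d}" for i in range(n_coding)}
    )
    tumor_up_genes = {orf_host[oid]: 1.0 for oid in tumor_up_orfs}
    # some non-dependency hosts are tumor-up too, to exercise the filter
    extra_pool = sorted(
        set(orf_host.values())
        - {orf_host[o] for o in depleted}
    )
    for g in rng.choice(extra_pool, size=min(30, len(extra_pool)), replace=False):
        tumor_up_genes[g] = 1.0
    tpm, cohort, subtype = simulate_expression(
        gene_ids,
        tumor_up=tumor_up_genes,
        n_tumor=n_tumor,
        n_normal=n_normal,
        seed=rng,
    )

    # pseudo translation p-values for the planted (already-called) ORFs
    ribo_p = {
        o["orf_id"]: float(np.round(rng.uniform(1e-4, 0.04), 6)) for o in sim.orfs
    }

    manifest = {
        "seed": seed,
        "planted_depleted_orfs": sorted(depleted),
        "depletion_log2fc": depletion_log2fc,
        "confounded_orfs": sorted(confounded),
        "clean_depleted_orfs": sorted(clean_depleted),
        "tumor_up_dependency_orfs": sorted(tumor_up_orfs),
        "tumor_up_genes": sorted(tumor_up_genes),
        "essential_genes": sorted(sim.essentials),
        "orf_hosts": orf_host,
        "ribo_p": ribo_p,
        "n_guides_per_orf": n_guides_per_orf,
        "conditions": {"n_day0": n_day0, "n_day21": n_day21, "depth": depth,
                       "dispersion": dispersion},
    }

    import tempfile

    with tempfile.TemporaryDirectory() as td:
        annotation = sim.load(td)

    # regulatory peaks over half the coding genes, plus decoys; a compact
    # AP-MS table with planted candidate interactors
    bound_genes = [f"PC{i:04d}" for i in range(0, n_coding, 2)]
    peaks = simulate_peaks(annotation, bound_genes, decoy_count=10, seed=rng)
    apms_candidates = [f"CAND{i:02d}" for i in range(5)]
    apms = simulate_apms(apms_candidates, n_background=20, seed=rng)
    manifest["peak_bound_genes"] = sorted(bound_genes)
    manifest["apms_candidates"] = apms_candidates

    profiles = None
    if with_riboseq:
        profiles = simulate_rpf(
            annotation,
            sim.orfs,
            translated_orf_ids=set(orf_ids),
            seed=rng,
        )

    # materialize on disk
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "annotation.gtf").write_text(sim.gtf_text)
        (out_dir / "essentials.tsv").write_text(
            "\n".join(sim.essentials) + ("\n" if sim.essentials else "")
        )
        write_library(str(out_dir / "library.tsv"), library)
        (out_dir / "negctrl.txt").write_text(
            "".join(
                g.guide_id + "\n"
                for g in library.by_class("negative_control")
            )
        )
        counts.rename_axis("guide_id").to_csv(out_dir / "screen_counts.tsv", sep="\t")
        pd.DataFrame(
            {"sample": conditions.index, "condition": conditions.to_numpy()}
        ).to_csv(out_dir / "samples.tsv", sep="\t", index=False)
        tpm.rename_axis("gene_id").to_csv(out_dir / "expression.tsv", sep="\t")
        pd.DataFrame(
            {"sample": cohort.index, "cohort": cohort.to_numpy(),
             "subtype": subtype.to_numpy()}
        ).to_csv(out_dir / "labels.tsv", sep="\t", index=False)
        with open(out_dir / "orfs.fa", "w") as fh:
            for o in sim.orfs:
                fh.write(f">{o['orf_id']}\n{o['nt_sequence']}\n")
        pd.DataFrame(
            [
                (o["orf_id"], o["host_gene"], o["transcript_id"],
                 o["transcript_start"], o["transcript_stop"],
                 ribo_p[o["orf_id"]])
                for o in sim.orfs
            ],
            columns=["orf_id", "host_gene", "transcript_id",
                     "transcript_start", "transcript_stop", "ribo_p"],
        ).to_csv(out_dir / "orf_table.tsv", sep="\t", index=False)
        from .genome import write_bed

        write_bed(str(out_dir / "peaks.bed"), peaks)
        apms.to_csv(out_dir / "apms.tsv", sep="\t", index=False)
        with open(out_dir / "truth.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        if profiles is not None:
            write_rpf_profiles(str(out_dir / "rpf.tsv"), profiles)

    return SimBundle(
        seed=seed,
        annotation_sim=sim,
        annotation=annotation,
        library=library,
        counts=counts,
        conditions=conditions,
        tpm=tpm,
        cohort=cohort,
        subtype=subtype,
        manifest=manifest,
        profiles=profiles,
        peaks=peaks,
        apms=apms,
    )


def simulate_riboseq_scenario(
    seed: int = 1,
    n_coding: int = 100,
    n_translated: int = 20,
    n_untranslated: int = 80,
    offsets: dict[int, int] | None = None,
    periodicity: float = 0.9,
    reads_per_codon: float = 50.0,
    background_per_nt: float = 0.2,
):
    """Compact ribo-seq scenario: coding anchors plus planted lncRNA ORFs.

    Returns (annotation, lnc_transcripts, profiles, manifest); the manifest
    records which planted ORFs are translated and the true offsets.
    """
    import tempfile

    offsets = dict(DEFAULT_OFFSETS) if offsets is None else offsets
    rng = np.random.default_rng(seed)
    sim = simulate_annotation(
        seed=rng,
        n_coding=n_coding,
        n_lncrna=n_translated + n_untranslated,
        essential_fraction=0.0,
    )
    with tempfile.TemporaryDirectory() as td:
        annotation = sim.load(td)
    orf_ids = [o["orf_id"] for o in sim.orfs]
    translated = set(
        rng.choice(orf_ids, size=n_translated, replace=False).tolist()
    )
    profiles = simulate_rpf(
        annotation,
        sim.orfs,
        translated,
        offsets=offsets,
        periodicity=periodicity,
        reads_per_codon=reads_per_codon,
        background_per_nt=background_per_nt,
        seed=rng,
    )
    manifest = {
        "seed": seed,
        "offsets": offsets,
        "periodicity": periodicity,
        "translated_orfs": sorted(translated),
        "untranslated_orfs": sorted(set(orf_ids) - translated),
        "orfs": sim.orfs,
    }
    return annotation, sim.lnc_transcripts, profiles, manifest
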