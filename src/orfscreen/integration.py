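"""Downstream target triage: DE overlap, peak-to-TSS association, AP-MS filter.

Combines perturbation DE call sets (microprotein knockout vs partner
knockdown) through a one-sided Fisher exact test, associates regulatory
peaks with genes whose TSS lies within a symmetric window, classifies shared
targets by their tumor expression direction, and filters AP-MS interactor
candidates on unique-peptide evidence plus tumor upregulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import AnnotationIndex, GenomicInterval, tss_window

__all__ = [
    "PeakSet",
    "GeneSetOverlap",
    "InteractorRecord",
    "de_overlap",
    "associate_peaks_tss",
    "triage_targets",
    "filter_interactors",
]

TSS_FLANK = 10_000
APMS_MIN_PEPTIDES = 3
APMS_STRONG_PEPTIDES = 4
APMS_LFC_MIN = 0.4
APMS_FDR_MAX = 0.01


@dataclass
class PeakSet:
    peaks: list[tuple[str, GenomicInterval, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [name for name, _, _ in self.peaks]
        if len(ids) != len(set(ids)):
            raise ValueError("peak ids must be unique")


@dataclass
class GeneSetOverlap:
    direction: str
    set_a: set[str]
    set_b: set[str]
    shared: set[str]
    universe_size: int
    fisher_p: float


@dataclass
class InteractorRecord:
    protein: str
    unique_peptides_bait: int
    unique_peptides_ctrl1: int
    unique_peptides_ctrl2: int
    tumor_log2fc: float
    tumor_fdr: float
    candidate: bool = False
    strong: bool = False

    def __post_init__(self) -> None:
        for n in (
            self.unique_peptides_bait,
            self.unique_peptides_ctrl1,
            self.unique_peptides_ctrl2,
        ):
            if n < 0:
                raise ValueError("peptide counts must be non-negative")


def de_overlap(
    calls_a: set[str],
    calls_b: set[str],
    universe: set[str],
    direction: str = "up",
) -> GeneSetOverlap:
    """Overlap of two DE call sets with a one-sided Fisher exact p.

    The p-value is the hypergeometric upper tail P(X >= |A intersect B|) for
    drawing |B| genes from a universe containing |A| successes -- the
    enrichment (over-sharing) alternative.  Symmetric in A and B.
    """
    if not universe:
        raise ValueError("empty universe")
    if not (calls_a <= universe and calls_b <= universe):
        raise ValueError("call sets must be subsets of the universe")
    shared = calls_a & calls_b
    N, K, n, k = len(universe), len(calls_a), len(calls_b), len(shared)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return GeneSetOverlap(
        direction=direction,
        set_a=set(calls_a),
        set_b=set(calls_b),
        shared=shared,
        universe_size=N,
        fisher_p=min(p, 1.0),
    )


def associate_peaks_tss(
    peaks: PeakSet,
    annotation: AnnotationIndex,
    flank: int = TSS_FLANK,
    genes=None,
) -> dict[str, list[str]]:
    """Genes with >= 1 peak overlapping their TSS +/- ``flank`` window.

    Many-to-many: a peak may hit several genes and vice versa.  Only genes
    with at least one association appear in the result.
    """
    gene_iter = (
        annotation.genes.values()
        if genes is None
        else [annotation.genes[g] for g in genes]
    )
    assoc: dict[str, list[str]] = {}
    for gene in gene_iter:
        window = tss_window(gene, flank)
        matched = [
            name
            for name, iv, _ in peaks.peaks
            if iv.overlaps(window)
        ]
        if matched:
            assoc[gene.gene_id] = sorted(matched)
    return assoc


def triage_targets(
    overlap_up: GeneSetOverlap,
    overlap_down: GeneSetOverlap,
    peak_assoc: dict[str, list[str]],
    tumor_de: pd.DataFrame,
    universe: set[str],
    lfc_min: float = float(np.log2(1.5)),
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Classify every universe gene by the co-regulation triage rule.

    ``co-repressed_tumor_down``: shared-upregulated on perturbation, has a
    TSS peak, and significantly *down* in tumors -- the tumor-suppressive
    targets a repressive axis silences.  ``co-activated_tumor_up`` is the
    mirror class.  All other genes are ``none``.  Tumor direction uses
    |log2fc| >= ``lfc_min`` with fdr <= ``fdr_max``; genes missing from
    ``tumor_de`` get direction ``ns``.
    """
    rows = []
    for gene in sorted(universe):
        in_up = gene in overlap_up.shared
        in_down = gene in overlap_down.shared
        has_peak = gene in peak_assoc
        if gene in tumor_de.index:
            lfc = float(tumor_de.loc[gene, "log2fc"])
            fdr = float(tumor_de.loc[gene, "fdr"])
            if np.isnan(lfc) or np.isnan(fdr) or fdr > fdr_max:
                direction = "ns"
            elif lfc >= lfc_min:
                direction = "up"
            elif lfc <= -lfc_min:
                direction = "down"
            else:
                direction = "ns"
        else:
            direction = "ns"
        if in_up and has_peak and direction == "down":
            klass = "co-repressed_tumor_down"
        elif in_down and has_peak and direction == "up":
            klass = "co-activated_tumor_up"
        else:
            klass = "none"
        rows.append(
            {
                "gene": gene,
                "in_shared_up": in_up,
                "in_shared_down": in_down,
                "has_tss_peak": has_peak,
                "tumor_direction": direction,
                "class": klass,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def filter_interactors(
    records: list[InteractorRecord],
    lfc_min: float = APMS_LFC_MIN,
    fdr_max: float = APMS_FDR_MAX,
) -> list[InteractorRecord]:
    """AP-MS interactor filter.

    Candidate: >= 3 unique peptides in the bait pulldown, zero in both
    controls, and tumor upregulation (log2fc >= ``lfc_min``, fdr <
    ``fdr_max``).  Candidates with >= 4 bait peptides get the ``strong``
    evidence flag.  Flags are set on the records; candidates are returned.
    """
    candidates = []
    for rec in records:
        rec.candidate = (
            rec.unique_peptides_bait >= APMS_MIN_PEPTIDES
            and rec.unique_peptides_ctrl1 == 0
            and rec.unique_peptides_ctrl2 == 0
            and rec.tumor_log2fc >= lfc_min
            and rec.tumor_fdr < fdr_max
        )
        rec.strong = rec.candidate and rec.unique_peptides_bait >= APMS_STRONG_PEPTIDES
        if rec.candidate:
            candidates.append(rec)
    return candidates
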