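"""The dependency-ORF hit funnel.

Candidate: an ORF with at least two significantly depleted guides
(log2FC <= -log2(1.5) and p < 0.05 at the guide level).  Valid: still at
least two depleted guides after removing guides whose cut site lies within
15 bp of any protein-coding CDS (essential or not) or within 15 bp of a UTR
of an essential gene.  Final: the host lncRNA gene is upregulated in tumors
(log2FC >= log2(1.2), FDR < 0.01) and the ORF survives the within-gene
redundancy collapse (kept set pairwise <= 85% nucleotide identity, most
significant translation p first).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import AnnotationIndex, GenomicInterval, pairwise_identity
from .guides import GuideRecord

__all__ = [
    "HitTable",
    "OrfHit",
    "call_candidates",
    "flag_neighbor_conflicts",
    "validate_hits",
    "cancer_expression_filter",
    "deduplicate_orfs",
]

STAGES = ("none", "candidate", "valid", "post_expression", "final")

DEPLETION_LFC_MAX = -float(np.log2(1.5))
DEPLETION_P_MAX = 0.05
NEIGHBOR_WINDOW = 15
TUMOR_LFC_MIN = float(np.log2(1.2))
TUMOR_FDR_MAX = 0.01
IDENTITY_MAX = 0.85


@dataclass
class OrfHit:
    orf_id: str
    host_gene: str = ""
    stage: str = "none"
    supporting_guides: list[tuple[str, float, float]] = field(default_factory=list)
    removed_guides: list[tuple[str, str]] = field(default_factory=list)
    tcga_log2fc: float | None = None
    tcga_fdr: float | None = None
    expression_fail_reason: str | None = None
    dedup_survivor: bool = False

    @property
    def n_depleted_pre(self) -> int:
        return len(self.supporting_guides) + len(self.removed_guides)

    @property
    def n_depleted_post(self) -> int:
        return len(self.supporting_guides)


@dataclass
class HitTable:
    hits: dict[str, OrfHit] = field(default_factory=dict)

    def at_stage(self, stage: str) -> list[str]:
        """ORFs that reached at least ``stage`` (the funnel is nested)."""
        want = STAGES.index(stage)
        return sorted(
            orf_id
            for orf_id, h in self.hits.items()
            if STAGES.index(h.stage) >= want
        )

    def funnel_counts(self) -> dict[str, int]:
        return {
            "n_candidate": len(self.at_stage("candidate")),
            "n_valid": len(self.at_stage("valid")),
            "n_post_expression": len(self.at_stage("post_expression")),
            "n_final": len(self.at_stage("final")),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for orf_id in sorted(self.hits):
            h = self.hits[orf_id]
            rows.append(
                {
                    "orf_id": orf_id,
                    "host_gene": h.host_gene,
                    "stage": h.stage,
                    "n_depleted_pre": h.n_depleted_pre,
                    "n_depleted_post": h.n_depleted_post,
                    "removal_reasons": ";".join(
                        f"{g}:{r}" for g, r in sorted(h.removed_guides)
                    ),
                    "tcga_log2fc": h.tcga_log2fc,
                    "tcga_fdr": h.tcga_fdr,
                    "final": h.stage == "final",
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "orf_id", "host_gene", "stage", "n_depleted_pre",
                "n_depleted_post", "removal_reasons", "tcga_log2fc",
                "tcga_fdr", "final",
            ],
        )


def call_candidates(
    stats: pd.DataFrame,
    guide_to_orf: dict[str, str],
    orf_hosts: dict[str, str] | None = None,
    lfc_max: float = DEPLETION_LFC_MAX,
    p_max: float = DEPLETION_P_MAX,
    min_guides: int = 2,
) -> HitTable:
    """Call candidate ORFs from per-guide depletion statistics.

    ``stats`` is indexed by guide_id with columns log2fc and p.  A guide is
    significantly depleted iff log2fc <= ``lfc_max`` (boundary equality
    counts) and p < ``p_max``; an ORF is a candidate iff at least
    ``min_guides`` of its guides are depleted.
    """
    orf_hosts = orf_hosts or {}
    table = HitTable()
    for guide_id, orf_id in guide_to_orf.items():
        if orf_id not in table.hits:
            table.hits[orf_id] = OrfHit(
                orf_id=orf_id, host_gene=orf_hosts.get(orf_id, "")
            )
    known = set(stats.index)
    for guide_id, orf_id in sorted(guide_to_orf.items()):
        if guide_id not in known:
            raise ValueError(f"guide {guide_id!r} has no screen statistics")
        row = stats.loc[guide_id]
        log2fc, p = float(row["log2fc"]), float(row["p"])
        if np.isnan(log2fc) or np.isnan(p):
            continue
        if log2fc <= lfc_max and p < p_max:
            table.hits[orf_id].supporting_guides.append((guide_id, log2fc, p))
    for hit in table.hits.values():
        if len(hit.supporting_guides) >= min_guides:
            hit.stage = "candidate"
    return table


def flag_neighbor_conflicts(
    guides: list[GuideRecord],
    annotation: AnnotationIndex,
    window: int = NEIGHBOR_WINDOW,
) -> dict[str, list[str]]:
    """Flag guides whose cut site is within ``window`` bp of neighbor features.

    CDS of any protein-coding gene -> ``CDS_conflict``; UTR of an essential
    gene -> ``essential_UTR_conflict``.  Distance is symmetric and
    strand-ignored; a guide can carry both flags.  Guides on chromosomes
    absent from the annotation get no flags.
    """
    flags: dict[str, list[str]] = {}
    for guide in guides:
        cut = guide.cut_site
        query = GenomicInterval(guide.chrom, max(0, cut - window), cut + window + 1)
        guide_flags = set()
        for gene_id, feature_class in annotation.query(query):
            gene = annotation.genes[gene_id]
            if feature_class == "CDS":
                guide_flags.add("CDS_conflict")
            elif feature_class in ("UTR5", "UTR3") and gene.essential:
                guide_flags.add("essential_UTR_conflict")
        flags[guide.guide_id] = sorted(guide_flags)
    return flags


def validate_hits(
    table: HitTable,
    flags: dict[str, list[str]],
    min_guides: int = 2,
) -> HitTable:
    """Promote candidates with >= ``min_guides`` depleted guides post-filter."""
    for hit in table.hits.values():
        if hit.stage != "candidate":
            continue
        remaining = []
        for guide_id, log2fc, p in hit.supporting_guides:
            guide_flags = flags.get(guide_id, [])
            if guide_flags:
                hit.removed_guides.append((guide_id, "+".join(guide_flags)))
            else:
                remaining.append((guide_id, log2fc, p))
        hit.supporting_guides = remaining
        if len(remaining) >= min_guides:
            hit.stage = "valid"
    return table


def cancer_expression_filter(
    table: HitTable,
    tumor_de: pd.DataFrame,
    lfc_min: float = TUMOR_LFC_MIN,
    fdr_max: float = TUMOR_FDR_MAX,
) -> HitTable:
    """Advance valid ORFs whose host gene is tumor-upregulated.

    ``tumor_de`` is indexed by gene with columns log2fc and fdr; passing
    requires log2fc >= ``lfc_min`` and fdr < ``fdr_max``.  A host gene absent
    from the table fails the filter (conservative), with the reason logged.
    """
    for hit in table.hits.values():
        if hit.stage != "valid":
            continue
        if hit.host_gene not in tumor_de.index:
            hit.expression_fail_reason = "host_gene_missing_from_DE"
            continue
        row = tumor_de.loc[hit.host_gene]
        hit.tcga_log2fc = float(row["log2fc"])
        hit.tcga_fdr = float(row["fdr"])
        if hit.tcga_log2fc >= lfc_min and hit.tcga_fdr < fdr_max:
            hit.stage = "post_expression"
        else:
            hit.expression_fail_reason = "not_tumor_upregulated"
    return table


def deduplicate_orfs(
    table: HitTable,
    sequences: dict[str, str],
    ribo_p: dict[str, float],
    orf_lengths: dict[str, int] | None = None,
    identity_max: float = IDENTITY_MAX,
) -> HitTable:
    """Collapse redundant same-gene ORFs to a pairwise <=85%-identity set.

    Within each host gene, surviving ORFs are sorted by ascending translation
    p (ties: longer ORF, then lexicographic id) and kept greedily iff their
    identity to every already-kept ORF of the gene is <= ``identity_max``.
    """
    by_gene: dict[str, list[str]] = {}
    for orf_id in table.at_stage("post_expression"):
        hit = table.hits[orf_id]
        if orf_id not in sequences:
            raise ValueError(f"missing nucleotide sequence for ORF {orf_id!r}")
        by_gene.setdefault(hit.host_gene, []).append(orf_id)

    def sort_key(orf_id: str):
        length = (
            orf_lengths[orf_id] if orf_lengths is not None
            else len(sequences[orf_id])
        )
        return (ribo_p.get(orf_id, 1.0), -length, orf_id)

    for gene, orf_ids in by_gene.items():
        kept: list[str] = []
        for orf_id in sorted(orf_ids, key=sort_key):
            if all(
                pairwise_identity(sequences[orf_id], sequences[k]) <= identity_max
                for k in kept
            ):
                kept.append(orf_id)
                table.hits[orf_id].stage = "final"
                table.hits[orf_id].dedup_survivor = True
    return table
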