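"""End-to-end orchestration: config, stage sequencing, funnel report.

``RunConfig`` carries every threshold used across the stages, defaulting to
the discovery values (guide depletion log2FC <= -log2(1.5) with p < 0.05 and
>= 2 guides; 15-bp neighbor window; tumor filter log2FC >= log2(1.2) with
FDR < 0.01; <= 85% identity redundancy collapse).  ``run_pipeline`` executes
screen statistics -> candidate calling -> neighbor-gene validation -> tumor
expression filter -> redundancy collapse, writing stage TSVs and a JSON
funnel report; the optional ribo-seq stage runs first when RPF profiles are
supplied.  All stages are deterministic given the config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import expression, hits, riboseq
from .genome import load_annotation, read_orf_fasta
from .guides import load_library
from .screen import ScreenDepletionModel

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    # inputs
    annotation_gtf: str = ""
    essential_genes: str | None = None
    library_tsv: str = ""
    screen_counts: str = ""
    samples_tsv: str = ""
    expression_tsv: str = ""
    labels_tsv: str = ""
    orf_table: str = ""  # orf_id, host_gene, transcript coords, ribo_p
    orf_fasta: str = ""
    rpf_tsv: str | None = None
    transcript_fasta: str | None = None
    out_dir: str = "results"
    # thresholds (discovery defaults)
    depletion_lfc_max: float = -float(np.log2(1.5))
    depletion_p_max: float = 0.05
    min_guides: int = 2
    neighbor_window: int = 15
    tumor_lfc_min: float = float(np.log2(1.2))
    tumor_fdr_max: float = 0.01
    identity_max: float = 0.85
    de_basemean_min: float = 1.0
    de_lfc_min: float = float(np.log2(1.5))
    de_fdr_max: float = 0.05
    subtype_lfc_min: float = 0.4
    subtype_fdr_max: float = 0.05
    tss_flank: int = 10_000
    apms_min_peptides: int = 3
    apms_lfc_min: float = 0.4
    apms_fdr_max: float = 0.01
    ribo_p_threshold: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - abort names the stage
                raise PipelineError(name, str(exc)) from exc

        return inner

    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Run the stages end-to-end and return the funnel report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    annotation = _stage("load_annotation")(load_annotation)(
        config.annotation_gtf, config.essential_genes
    )
    library = _stage("load_library")(load_library)(config.library_tsv)

    # ORF catalog: either called from ribo-seq here, or supplied as a table
    orf_table = _stage("load_orfs")(pd.read_csv)(config.orf_table, sep="\t")
    sequences = _stage("load_orfs")(read_orf_fasta)(config.orf_fasta)
    ribo_p = dict(zip(orf_table["orf_id"], orf_table["ribo_p"]))
    orf_hosts = dict(zip(orf_table["orf_id"], orf_table["host_gene"]))

    riboqc = None
    if config.rpf_tsv:
        riboqc = _run_riboseq_qc(config, annotation, out)

    model = _stage("screen_stats")(ScreenDepletionModel.from_tsv)(
        config.screen_counts, config.samples_tsv
    )
    neg_controls = [
        g.guide_id for g in library.by_class("negative_control")
    ]
    model.control_rows = neg_controls or None
    results = _stage("screen_stats")(model.fit)()
    results.stats.rename_axis("guide_id").to_csv(
        out / "guide_stats.tsv", sep="\t"
    )

    targeting = [
        g for g in library.by_class("targeting") if g.target_orf in orf_hosts
    ]
    guide_to_orf = {g.guide_id: g.target_orf for g in targeting}
    table = _stage("call_candidates")(hits.call_candidates)(
        results.stats,
        guide_to_orf,
        orf_hosts=orf_hosts,
        lfc_max=config.depletion_lfc_max,
        p_max=config.depletion_p_max,
        min_guides=config.min_guides,
    )
    flags = _stage("neighbor_filter")(hits.flag_neighbor_conflicts)(
        targeting, annotation, window=config.neighbor_window
    )
    table = _stage("neighbor_filter")(hits.validate_hits)(
        table, flags, min_guides=config.min_guides
    )

    expr = _stage("expression")(expression.ExpressionMatrix.from_tsv)(
        config.expression_tsv, config.labels_tsv
    )
    tumor_de = _stage("expression")(expression.wilcoxon_de)(
        expr, expr.samples("tumor"), expr.samples("normal")
    )
    tumor_de.rename_axis("gene_id").to_csv(out / "tumor_de.tsv", sep="\t")
    table = _stage("expression_filter")(hits.cancer_expression_filter)(
        table, tumor_de, lfc_min=config.tumor_lfc_min, fdr_max=config.tumor_fdr_max
    )

    orf_lengths = {oid: len(seq) for oid, seq in sequences.items()}
    table = _stage("deduplicate")(hits.deduplicate_orfs)(
        table, sequences, ribo_p, orf_lengths, identity_max=config.identity_max
    )

    table.to_frame().to_csv(out / "hit_funnel.tsv", sep="\t", index=False)
    audit = pd.DataFrame(
        [
            (g.guide_id, g.target_orf, ";".join(flags.get(g.guide_id, [])))
            for g in targeting
        ],
        columns=["guide_id", "target_orf", "flags"],
    )
    audit.to_csv(out / "guide_audit.tsv", sep="\t", index=False)

    report = {
        "n_orfs": len(orf_table),
        **table.funnel_counts(),
        "final_orfs": table.at_stage("final"),
    }
    if riboqc is not None:
        report["riboseq_qc"] = riboqc
    counts = table.funnel_counts()
    assert (
        counts["n_final"] <= counts["n_post_expression"]
        <= counts["n_valid"] <= counts["n_candidate"] <= report["n_orfs"]
    ), "funnel monotonicity violated"
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def _run_riboseq_qc(config: RunConfig, annotation, out: Path) -> dict:
    """Optional ribo-seq QC stage: metagene, offsets, frame distribution."""
    tx_lengths = {}
    for gene in annotation.genes.values():
        for tx_id, exons in gene.transcripts.items():
            tx_lengths[tx_id] = sum(len(iv) for iv in exons)
    profiles = _stage("riboseq_qc")(riboseq.read_rpf_profiles)(
        config.rpf_tsv, tx_lengths
    )
    metagene = _stage("riboseq_qc")(riboseq.build_metagene)(
        profiles, annotation, "start"
    )
    offsets = _stage("riboseq_qc")(riboseq.estimate_psite_offset)(metagene)
    frame_qc = _stage("riboseq_qc")(riboseq.frame_distribution)(
        profiles, annotation, offsets
    )
    riboseq.qc_report(profiles, metagene, offsets, frame_qc).to_csv(
        out / "ribo_qc.tsv", sep="\t", index=False
    )
    return {
        "offsets": {str(k): int(v) for k, v in offsets.items()},
        "f_d": frame_qc.f_d,
    }
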