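"""Tumor/normal and subtype expression statistics on TPM matrices.

Differential expression between sample groups uses the Wilcoxon rank-sum
test (exact permutation enumeration for group sizes up to 5+5, tie-corrected
normal approximation beyond) with a mean-ratio log2 fold change; multiple
testing is controlled with Benjamini-Hochberg.  Gene-level count contrasts
(perturbation RNA-seq) reuse the NB Wald machinery from :mod:`.screen`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import bh_adjust, rank_sum_test
from .screen import (
    control_size_factors,
    estimate_dispersion,
    moderate_dispersion,
    nb_wald_test,
)

__all__ = [
    "ExpressionMatrix",
    "wilcoxon_de",
    "bh_adjust",
    "subtype_enrichment",
    "gene_level_de",
]

SUBTYPE_LFC_MIN = 0.4
SUBTYPE_FDR_MAX = 0.05
DE_BASEMEAN_MIN = 1.0
DE_LFC_MIN = float(np.log2(1.5))
DE_FDR_MAX = 0.05


@dataclass
class ExpressionMatrix:
    """TPM matrix (genes x samples) with per-sample cohort/subtype labels."""

    tpm: pd.DataFrame
    cohort: pd.Series  # sample -> {tumor, normal}
    subtype: pd.Series = field(default=None)  # sample -> CMS1..4/other/NA

    def __post_init__(self) -> None:
        if (self.tpm.to_numpy() < 0).any():
            raise ValueError("TPM values must be >= 0")
        missing = set(self.tpm.columns) - set(self.cohort.index)
        if missing:
            raise ValueError(f"samples without cohort label: {sorted(missing)[:5]}")
        if self.subtype is None:
            self.subtype = pd.Series("NA", index=self.tpm.columns)

    @classmethod
    def from_tsv(cls, tpm_path: str, labels_path: str) -> "ExpressionMatrix":
        tpm = pd.read_csv(tpm_path, sep="\t", index_col=0)
        labels = pd.read_csv(labels_path, sep="\t", dtype=str).set_index("sample")
        subtype = (
            labels["subtype"] if "subtype" in labels.columns
            else pd.Series("NA", index=labels.index)
        )
        return cls(tpm=tpm, cohort=labels["cohort"], subtype=subtype.fillna("NA"))

    def samples(self, cohort: str) -> list[str]:
        return [s for s in self.tpm.columns if self.cohort[s] == cohort]


def wilcoxon_de(
    expr: ExpressionMatrix | pd.DataFrame,
    group_a,
    group_b,
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Per-gene rank-sum DE of samples ``group_a`` vs ``group_b``.

    Two-sided p-values; log2fc = log2((mean_a + pc)/(mean_b + pc)).  Genes
    with all-zero TPM in both groups are excluded from testing and from BH.
    Returns a DataFrame indexed by gene with columns (log2fc, p, fdr).
    """
    tpm = expr.tpm if isinstance(expr, ExpressionMatrix) else expr
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("sample groups overlap")
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("both groups need >= 3 samples")
    A = tpm[group_a].to_numpy(dtype=float)
    B = tpm[group_b].to_numpy(dtype=float)
    expressed = (A.sum(axis=1) + B.sum(axis=1)) > 0
    log2fc = np.log2((A.mean(axis=1) + pseudocount) / (B.mean(axis=1) + pseudocount))
    pvals = np.full(tpm.shape[0], np.nan)
    for i in np.flatnonzero(expressed):
        _, pvals[i] = rank_sum_test(
            A[i], B[i], alternative="two-sided", exact_max_n=10
        )
    fdr = np.full_like(pvals, np.nan)
    fdr[expressed] = bh_adjust(pvals[expressed])
    out = pd.DataFrame(
        {"log2fc": np.where(expressed, log2fc, np.nan), "p": pvals, "fdr": fdr},
        index=tpm.index,
    )
    return out


def subtype_enrichment(
    expr: ExpressionMatrix,
    lfc_min: float = SUBTYPE_LFC_MIN,
    fdr_max: float = SUBTYPE_FDR_MAX,
) -> dict[str, pd.DataFrame]:
    """One-vs-rest DE per subtype over tumor samples only.

    Samples with subtype "NA" are excluded; subtypes with fewer than 3
    samples are skipped with a warning.  Each returned DataFrame carries an
    ``enriched`` flag (log2fc >= ``lfc_min`` and fdr < ``fdr_max``); a gene
    may be enriched in several subtypes.
    """
    tumor = [s for s in expr.tpm.columns if expr.cohort[s] == "tumor"]
    labeled = [s for s in tumor if expr.subtype.get(s, "NA") != "NA"]
    subtypes = sorted({expr.subtype[s] for s in labeled})
    if len(subtypes) < 2:
        raise ValueError("need >= 2 subtypes among tumor samples")
    results: dict[str, pd.DataFrame] = {}
    for subtype in subtypes:
        in_group = [s for s in labeled if expr.subtype[s] == subtype]
        rest = [s for s in labeled if expr.subtype[s] != subtype]
        if len(in_group) < 3:
            warnings.warn(f"subtype {subtype} has < 3 samples; skipped")
            continue
        de = wilcoxon_de(expr, in_group, rest)
        de["enriched"] = (de["log2fc"] >= lfc_min) & (de["fdr"] < fdr_max)
        de["enriched"] = de["enriched"].fillna(False)
        results[subtype] = de
    return results


def gene_level_de(
    counts: pd.DataFrame,
    conditions: pd.Series,
    contrast: tuple[str, str],
    basemean_min: float = DE_BASEMEAN_MIN,
    lfc_min: float = DE_LFC_MIN,
    fdr_max: float = DE_FDR_MAX,
) -> pd.DataFrame:
    """NB Wald DE on gene counts with the standard up/down call filters.

    Size factors use the all-rows median-of-ratios variant.  A gene is called
    ``up`` iff log2fc >= ``lfc_min``, ``down`` iff log2fc <= -``lfc_min``,
    both additionally requiring base_mean >= ``basemean_min`` and FDR <=
    ``fdr_max`` (inclusive); everything else is ``ns``.
    """
    size_factors = control_size_factors(counts, None)
    raw = estimate_dispersion(counts, size_factors, conditions)
    dispersions = moderate_dispersion(raw, counts, size_factors, conditions)
    resid_df = sum(
        max((conditions == c).sum() - 1, 0) for c in conditions.unique()
    )
    stats = nb_wald_test(
        counts, size_factors, dispersions, conditions, contrast,
        t_df=resid_df + 50.0,
    )
    call = np.full(len(stats), "ns", dtype=object)
    eligible = (stats["base_mean"] >= basemean_min) & (stats["fdr"] <= fdr_max)
    eligible = eligible.fillna(False).to_numpy()
    call[eligible & (stats["log2fc"] >= lfc_min).to_numpy()] = "up"
    call[eligible & (stats["log2fc"] <= -lfc_min).to_numpy()] = "down"
    stats = stats.copy()
    stats["call"] = call
    return stats
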