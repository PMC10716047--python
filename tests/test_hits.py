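"""The candidate -> valid -> final hit funnel and the neighbor filter."""

import numpy as np
import pandas as pd
import pytest

from orfscreen.genome import AnnotationIndex, GeneModel, GenomicInterval
from orfscreen.guides import GuideRecord
from orfscreen.hits import (
    HitTable,
    OrfHit,
    call_candidates,
    cancer_expression_filter,
    deduplicate_orfs,
    flag_neighbor_conflicts,
    validate_hits,
)

LFC = -float(np.log2(1.5))


def _stats(rows):
    return pd.DataFrame(rows, columns=["log2fc", "p"]).set_index(
        pd.Index([f"g{i}" for i in range(len(rows))])
    )


def _guide_at(cut, guide_id="g0", chrom="c"):
    return GuideRecord(
        guide_id=guide_id,
        protospacer="ACGT" * 5,
        chrom=chrom,
        strand="+",
        protospacer_interval=GenomicInterval(chrom, cut - 16, cut + 4, "+"),
        pam_interval=GenomicInterval(chrom, cut + 4, cut + 7, "+"),
    )


def _annotation(essential=False):
    gene = GeneModel(
        gene_id="PC", chrom="c", strand="+", biotype="protein_coding",
        tss=1000,
        cds_intervals=[GenomicInterval("c", 1000, 1300)],
        utr3_intervals=[GenomicInterval("c", 1300, 1400)],
        essential=essential,
    )
    return AnnotationIndex({"PC": gene})


def test_candidate_rule_and_boundaries():
    stats = _stats([(-1.0, 0.01), (-0.8, 0.02),     # orfA: two depleted
                    (-1.0, 0.01), (-0.3, 0.001),    # orfB: one (lfc too mild)
                    (LFC, 0.049), (LFC, 0.049)])    # orfC: boundary equality
    mapping = {"g0": "A", "g1": "A", "g2": "B", "g3": "B", "g4": "C", "g5": "C"}
    table = call_candidates(stats, mapping)
    assert table.hits["A"].stage == "candidate"
    assert table.hits["B"].stage == "none"
    assert table.hits["C"].stage == "candidate"  # lfc == -log2(1.5) counts


def test_candidate_unknown_guide_errors():
    with pytest.raises(ValueError, match="no screen statistics"):
        call_candidates(_stats([(-1, 0.01)]), {"nope": "A"})


def test_neighbor_flags_window_and_essentiality():
    # CDS spans [1000,1300); cut at 990 is 10 bp away -> conflict
    flags = flag_neighbor_conflicts([_guide_at(990)], _annotation())
    assert flags["g0"] == ["CDS_conflict"]
    # 16 bp away -> outside the strict 15-bp window
    flags = flag_neighbor_conflicts([_guide_at(984)], _annotation())
    assert flags["g0"] == []
    # inside the UTR of a non-essential gene -> no flag
    flags = flag_neighbor_conflicts([_guide_at(1350)], _annotation(False))
    assert flags["g0"] == []
    # same cut, essential host -> essential_UTR_conflict
    flags = flag_neighbor_conflicts([_guide_at(1350)], _annotation(True))
    assert flags["g0"] == ["essential_UTR_conflict"]
    # unknown chromosome -> no flags, no error
    flags = flag_neighbor_conflicts([_guide_at(990, chrom="chrZ")], _annotation())
    assert flags["g0"] == []


def test_neighbor_flags_match_bruteforce_distance_scan(rng):
    genes = {}
    features = []
    for i in range(120):
        s = int(rng.integers(100, 40_000))
        e = s + int(rng.integers(30, 400))
        essential = bool(rng.random() < 0.4)
        cls = "cds" if i % 2 == 0 else ("utr5" if i % 4 == 1 else "utr3")
        g = GeneModel(gene_id=f"G{i}", chrom="c", strand="+",
                      biotype="protein_coding", tss=s, essential=essential)
        getattr(g, f"{cls}_intervals").append(GenomicInterval("c", s, e))
        genes[f"G{i}"] = g
        features.append((cls, s, e, essential))
    index = AnnotationIndex(genes)
    guides = [
        _guide_at(int(rng.integers(100, 41_000)), guide_id=f"sg{j}")
        for j in range(300)
    ]
    flags = flag_neighbor_conflicts(guides, index, window=15)
    for g in guides:
        cut = g.cut_site
        expect = set()
        for cls, s, e, essential in features:
            dist = 0 if s <= cut < e else min(abs(cut - (e - 1)), abs(s - cut))
            if dist <= 15:
                if cls == "cds":
                    expect.add("CDS_conflict")
                elif essential:
                    expect.add("essential_UTR_conflict")
        assert set(flags[g.guide_id]) == expect


def _table_with(stage, guides, orf="A", host="L1"):
    t = HitTable()
    t.hits[orf] = OrfHit(orf_id=orf, host_gene=host, stage=stage,
                         supporting_guides=list(guides))
    return t


def test_validate_hits_removal_rules():
    t = _table_with("candidate", [("g0", -1, 0.01), ("g1", -1, 0.01),
                                  ("g2", -1, 0.01)])
    out = validate_hits(t, {"g0": ["CDS_conflict"]})
    assert out.hits["A"].stage == "valid"
    assert out.hits["A"].removed_guides == [("g0", "CDS_conflict")]
    t2 = _table_with("candidate", [("g0", -1, 0.01), ("g1", -1, 0.01)])
    out2 = validate_hits(t2, {"g1": ["essential_UTR_conflict"]})
    assert out2.hits["A"].stage == "candidate"  # only one guide left
    t3 = _table_with("candidate", [("g0", -1, 0.01), ("g1", -1, 0.01)])
    assert validate_hits(t3, {}).hits["A"].stage == "valid"  # identity case


def test_expression_filter_thresholds_and_missing_host():
    de = pd.DataFrame(
        {"log2fc": [0.5, 0.3], "fdr": [0.001, 0.10]}, index=["L1", "L2"]
    )
    t = _table_with("valid", [("g0", -1, 0.01), ("g1", -1, 0.01)])
    assert cancer_expression_filter(t, de).hits["A"].stage == "post_expression"
    t2 = _table_with("valid", [("g0", -1, 0.01)], host="L2")
    assert cancer_expression_filter(t2, de).hits["A"].stage == "valid"
    t3 = _table_with("valid", [("g0", -1, 0.01)], host="MISSING")
    out = cancer_expression_filter(t3, de)
    assert out.hits["A"].stage == "valid"
    assert out.hits["A"].expression_fail_reason == "host_gene_missing_from_DE"


def test_dedup_identity_rules():
    seqs = {"A1": "ATG" + "AAA" * 20, "A2": "ATG" + "AAA" * 19 + "CCC",
            "A3": "ATG" + "CCC" * 20}
    ribo_p = {"A1": 0.001, "A2": 0.01, "A3": 0.02}
    t = HitTable()
    for orf in seqs:
        t.hits[orf] = OrfHit(orf_id=orf, host_gene="L1", stage="post_expression")
    out = deduplicate_orfs(t, seqs, ribo_p)
    final = set(out.at_stage("final"))
    # A2 is ~95% identical to the more significant A1 -> dropped;
    # A3 is dissimilar -> kept
    assert final == {"A1", "A3"}
    # single ORF is vacuously final
    t2 = HitTable()
    t2.hits["B1"] = OrfHit(orf_id="B1", host_gene="L2", stage="post_expression")
    assert deduplicate_orfs(t2, {"B1": "ATGAAA"}, {"B1": 0.01}).at_stage(
        "final"
    ) == ["B1"]


def test_dedup_missing_sequence_errors():
    t = HitTable()
    t.hits["X"] = OrfHit(orf_id="X", host_gene="L", stage="post_expression")
    with pytest.raises(ValueError, match="missing nucleotide sequence"):
        deduplicate_orfs(t, {}, {})


def test_funnel_monotonic_and_deterministic(screen_bundle):
    from orfscreen.expression import ExpressionMatrix, wilcoxon_de
    from orfscreen.screen import ScreenDepletionModel

    b = screen_bundle
    res = ScreenDepletionModel(
        b.counts, b.conditions,
        control_rows=[g.guide_id for g in b.library.by_class("negative_control")],
    ).fit()
    targeting = b.library.by_class("targeting")
    mapping = {g.guide_id: g.target_orf for g in targeting}

    def funnel(stats):
        t = call_candidates(stats, mapping, b.manifest["orf_hosts"])
        t = validate_hits(t, flag_neighbor_conflicts(targeting, b.annotation))
        expr = ExpressionMatrix(tpm=b.tpm, cohort=b.cohort, subtype=b.subtype)
        de = wilcoxon_de(expr, expr.samples("tumor"), expr.samples("normal"))
        t = cancer_expression_filter(t, de)
        seqs = {o["orf_id"]: o["nt_sequence"] for o in b.annotation_sim.orfs}
        return deduplicate_orfs(t, seqs, b.manifest["ribo_p"])

    t1 = funnel(res.stats)
    # nesting of the funnel stages
    final = set(t1.at_stage("final"))
    post = set(t1.at_stage("post_expression"))
    valid = set(t1.at_stage("valid"))
    cand = set(t1.at_stage("candidate"))
    assert final <= post <= valid <= cand
    # identical result from a permuted stats table
    shuffled = res.stats.sample(frac=1.0, random_state=0)
    t2 = funnel(shuffled)
    assert t1.to_frame().equals(t2.to_frame())


def test_adding_unflagged_depleted_guide_never_demotes():
    stats = _stats([(-1.0, 0.01), (-0.9, 0.02)])
    mapping = {"g0": "A", "g1": "A"}
    base = validate_hits(call_candidates(stats, mapping), {})
    assert base.hits["A"].stage == "valid"
    stats2 = _stats([(-1.0, 0.01), (-0.9, 0.02), (-2.0, 0.001)])
    mapping2 = dict(mapping, g2="A")
    more = validate_hits(call_candidates(stats2, mapping2), {})
    assert more.hits["A"].stage == "valid"
    assert more.hits["A"].n_depleted_post == 3
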