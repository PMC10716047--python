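"""Metagene construction, P-site offsets, frame QC and ORF calling."""

import numpy as np
import pytest

from orfscreen.genome import (
    AnnotationIndex,
    GeneModel,
    GenomicInterval,
    OrfRecord,
)
from orfscreen.riboseq import test_orf_translation as translation_test
from orfscreen.riboseq import (
    MetageneProfile,
    RpfProfile,
    build_metagene,
    call_orfs,
    enumerate_candidate_orfs,
    estimate_psite_offset,
    frame_distribution,
    merge_orfs,
    psite_codon_counts,
    read_rpf_profiles,
    write_rpf_profiles,
)


def _coding_annotation(n=1, tx_len=400, cds_start=100, cds_len=150):
    """Single-exon plus-strand coding genes; CDS at a known transcript offset."""
    genes = {}
    cursor = 0
    for i in range(n):
        gid, tx = f"G{i}", f"G{i}-T1"
        exon = GenomicInterval("c", cursor, cursor + tx_len, "+")
        genes[gid] = GeneModel(
            gene_id=gid, chrom="c", strand="+", biotype="protein_coding",
            tss=cursor,
            exon_intervals=[exon],
            cds_intervals=[GenomicInterval("c", cursor + cds_start,
                                           cursor + cds_start + cds_len, "+")],
            transcripts={tx: [exon]},
        )
        cursor += tx_len + 1000
    return AnnotationIndex(genes)


def test_metagene_single_read_at_start_codon():
    ann = _coding_annotation()
    prof = RpfProfile("G0-T1", 400)
    prof.add_read(29, 100)  # 5' end exactly at the start codon
    mg = build_metagene({"G0-T1": prof}, ann, "start")
    assert mg.profiles[29][MetageneProfile.index_of(0)] == 1
    assert mg.profiles[29].sum() == 1


def test_metagene_additivity_across_transcripts():
    ann = _coding_annotation(n=2)
    profiles = {}
    for tx in ("G0-T1", "G1-T1"):
        p = RpfProfile(tx, 400)
        p.add_read(29, 100 - 12)
        profiles[tx] = p
    mg = build_metagene(profiles, ann, "start")
    assert mg.profiles[29][MetageneProfile.index_of(-12)] == 2


def test_metagene_requires_anchors():
    empty = AnnotationIndex({})
    with pytest.raises(ValueError, match="no anchors"):
        build_metagene({}, empty, "start")


def test_offset_estimation_and_tie_break():
    mg = MetageneProfile(anchor="start")
    vec = np.zeros(61, dtype=np.int64)
    vec[MetageneProfile.index_of(-12)] = 10
    mg.profiles[29] = vec
    assert estimate_psite_offset(mg) == {29: 12}
    # tie between -12 and -13 resolves to the smaller offset
    vec2 = vec.copy()
    vec2[MetageneProfile.index_of(-13)] = 10
    mg.profiles[29] = vec2
    assert estimate_psite_offset(mg) == {29: 12}
    # a read length with no counts in the window is dropped
    mg.profiles[33] = np.zeros(61, dtype=np.int64)
    assert 33 not in estimate_psite_offset(mg)


def test_offset_shift_equivariance(ribo_scenario):
    """Shifting all 5' ends 1 nt upstream increases every offset by 1."""
    ann, _, profiles, manifest = ribo_scenario
    shifted = {}
    for tx, prof in profiles.items():
        sp = RpfProfile(tx, prof.length)
        for rl, vec in prof.counts.items():
            nv = np.zeros_like(vec)
            nv[:-1] = vec[1:]
            sp.counts[rl] = nv
        shifted[tx] = sp
    base = estimate_psite_offset(build_metagene(profiles, ann, "start"))
    moved = estimate_psite_offset(build_metagene(shifted, ann, "start"))
    for rl, off in base.items():
        assert moved[rl] == off + 1


def test_planted_offsets_recovered_across_seeds():
    from orfscreen.simulate import simulate_riboseq_scenario

    for seed in range(1, 11):
        ann, _, profiles, manifest = simulate_riboseq_scenario(
            seed=seed, n_coding=20, n_translated=3, n_untranslated=3
        )
        mg = build_metagene(profiles, ann, "start")
        assert estimate_psite_offset(mg) == manifest["offsets"]


@pytest.mark.parametrize(
    "counts,expected",
    [(((10, 0, 0),), 1.0), (((5, 5, 5),), 1 / 3), (((10, 5, 5),), 0.5)],
)
def test_frame_fraction_arithmetic(counts, expected):
    from orfscreen.riboseq import FrameQc

    qc = FrameQc(frame_counts={29: counts[0]})
    assert qc.f_d == pytest.approx(expected)


def test_frame_fraction_undefined_without_reads():
    from orfscreen.riboseq import FrameQc

    assert FrameQc(frame_counts={}).f_d is None


def test_frame_distribution_recovers_dominant_frame(ribo_scenario):
    ann, _, profiles, manifest = ribo_scenario
    offsets = estimate_psite_offset(build_metagene(profiles, ann, "start"))
    qc = frame_distribution(profiles, ann, offsets)
    assert qc.f_d is not None and qc.f_d >= 0.8
    n0, n1, n2 = qc.totals
    assert n0 == max(n0, n1, n2)  # planted periodicity puts frame 0 on top


def test_psite_codon_counts_against_bruteforce(rng):
    orf = OrfRecord("o", "g", "t", 30, 90)
    prof = RpfProfile("t", 200)
    for _ in range(300):
        prof.add_read(int(rng.choice([28, 29, 30])), int(rng.integers(0, 200)))
    offsets = {28: 12, 29: 12, 30: 13}
    in_f, (off1, off2) = psite_codon_counts(prof, orf, offsets)
    # naive per-position oracle
    for k in range(20):
        for base, vec in ((0, in_f), (1, off1), (2, off2)):
            pos = 30 + 3 * k + base
            expect = sum(
                prof.counts[rl][pos - off]
                for rl, off in offsets.items()
                if 0 <= pos - off < 200 and rl in prof.counts
            )
            assert vec[k] == expect


def test_psite_codon_counts_bounds_and_zero():
    prof = RpfProfile("t", 50)
    with pytest.raises(ValueError, match="outside transcript"):
        psite_codon_counts(prof, OrfRecord("o", "g", "t", 30, 60), {29: 12})
    in_f, (o1, o2) = psite_codon_counts(
        prof, OrfRecord("o", "g", "t", 0, 30), {29: 12}
    )
    assert in_f.sum() == o1.sum() == o2.sum() == 0


def test_translation_test_all_zero_is_one():
    z = np.zeros(6)
    assert translation_test(z, (z, z)).p == 1.0


def test_translation_test_exact_tail():
    """Fully separated 4 vs 8 gives the exact 1/C(12,4) enumeration tail."""
    res = translation_test(
        np.array([5, 6, 7, 8]),
        (np.zeros(4), np.zeros(4)),
    )
    assert res.p == pytest.approx(1 / 495)


def test_translation_test_length_mismatch():
    with pytest.raises(ValueError, match="equal length"):
        translation_test(np.ones(3), (np.ones(2), np.ones(3)))


def test_translation_null_p_uniform(rng):
    """iid counts (no periodicity) give approximately uniform p-values."""
    pvals = []
    for _ in range(400):
        vals = rng.poisson(15, size=90)
        pvals.append(translation_test(vals[:30], (vals[30:60], vals[60:])).p)
    from scipy import stats as sps

    assert sps.kstest(pvals, "uniform").pvalue > 1e-3
    frac = np.mean(np.array(pvals) < 0.05)
    assert abs(frac - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / 400)


def test_longest_mode_one_candidate_per_stop():
    # nested ATGs sharing a stop: only the longest is emitted
    seq = "ATGATGAAATAA"
    assert enumerate_candidate_orfs(seq) == [(0, 9)]
    assert enumerate_candidate_orfs("CCCCCC") == []


def test_call_orfs_recovers_planted(ribo_scenario):
    ann, transcripts, profiles, manifest = ribo_scenario
    offsets = estimate_psite_offset(build_metagene(profiles, ann, "start"))
    called = {o.orf_id for o in call_orfs(transcripts, profiles, offsets, ann)}
    translated = set(manifest["translated_orfs"])
    untranslated = set(manifest["untranslated_orfs"])
    assert len(called & translated) >= 0.9 * len(translated)
    # false calls bounded by a generous binomial tail at alpha = 0.05
    assert len(called & untranslated) <= max(5, 0.15 * len(untranslated))


def test_merge_orfs_keeps_min_p_and_groups_by_coordinates():
    blocks = [GenomicInterval("c", 100, 160, "+")]
    a = OrfRecord("a", "g", "t1", 0, 57, genomic_blocks=blocks, ribo_p=0.03)
    b = OrfRecord("b", "g", "t2", 10, 67, genomic_blocks=blocks, ribo_p=0.01)
    merged = merge_orfs([[a], [b]])
    assert len(merged) == 1 and merged[0].ribo_p == 0.01
    # same stop, different start -> kept apart
    c = OrfRecord("c", "g", "t3", 0, 57,
                  genomic_blocks=[GenomicInterval("c", 110, 160, "+")],
                  ribo_p=0.02)
    assert len(merge_orfs([[a], [c]])) == 2


def test_merge_orfs_matches_grouping_oracle(rng):
    records, key_of = [], {}
    for i in range(200):
        start = int(rng.integers(0, 50)) * 10
        end = start + 30 + int(rng.integers(0, 5)) * 30
        orf = OrfRecord(
            f"o{i}", "g", f"t{i}", 0, end - start - 3,
            genomic_blocks=[GenomicInterval("c", start, end, "+")],
            ribo_p=float(rng.uniform()),
        )
        records.append(orf)
        key_of[orf.orf_id] = ("c", start, end)
    merged = merge_orfs([records])
    brute = {}
    for orf in records:
        k = key_of[orf.orf_id]
        if k not in brute or orf.ribo_p < brute[k].ribo_p:
            brute[k] = orf
    assert {o.orf_id for o in merged} == {o.orf_id for o in brute.values()}


def test_rpf_profile_roundtrip(tmp_path, ribo_scenario):
    _, _, profiles, _ = ribo_scenario
    path = tmp_path / "rpf.tsv"
    write_rpf_profiles(str(path), profiles)
    lengths = {tx: p.length for tx, p in profiles.items()}
    back = read_rpf_profiles(str(path), lengths)
    assert set(back) == set(profiles)
    for tx in profiles:
        for rl, vec in profiles[tx].counts.items():
            assert np.array_equal(back[tx].counts[rl], vec)
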