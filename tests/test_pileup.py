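"""Featurization oracles: candidate scanning, tensor counting, labels."""

import numpy as np
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from depthcall import pileup
from depthcall.pileup import (
    CandidateSite,
    GenomeRegion,
    TruthVariant,
    build_pileup_tensor,
    flatten_tensor,
    label_site,
    make_training_pairs,
    scan_candidates,
    unflatten_image,
)

from conftest import write_bam, write_fasta, write_vcf


# ---------------------------------------------------------------------------
# scan_candidates


def test_scan_emits_site_at_af_threshold(tmp_path, toy_ref):
    seq = toy_ref["seq"]
    pos = 20
    reads = []
    for i in range(10):
        base = seq[pos]
        if i < 2:  # two reads carry a mismatch
            base = "T" if seq[pos] != "T" else "A"
        read_seq = seq[10:pos] + base + seq[pos + 1 : 30]
        reads.append((f"r{i}", 10, "20M", read_seq, False))
    bam = write_bam(tmp_path / "t.bam", "toy", 60, reads)
    sites = scan_candidates(bam, GenomeRegion("toy", 0, 60), toy_ref["fasta"], min_af=0.2)
    assert [s.pos for s in sites] == [pos]
    assert sites[0].depth == 10
    assert sites[0].alt_support == 2
    assert sites[0].alt_fraction == pytest.approx(0.2)


def test_scan_all_reference_reads_empty(tmp_path, toy_ref):
    seq = toy_ref["seq"]
    reads = [(f"r{i}", 5, "30M", seq[5:35], i % 2 == 1) for i in range(8)]
    bam = write_bam(tmp_path / "t.bam", "toy", 60, reads)
    assert scan_candidates(bam, GenomeRegion("toy", 0, 60), toy_ref["fasta"]) == []


def test_scan_planted_het_snp_clean_sim(clean_sim_run):
    """0% error: every candidate is a real variant site; a het SNP shows
    alt fraction near 0.5 (binomial over covering reads)."""
    out = clean_sim_run
    sites = scan_candidates(out["bam"], out["region"], out["fasta"])
    het_snps = [
        v
        for v in out["genome"].variants
        if len(v.ref) == 1 and len(v.alts[0]) == 1 and sorted(v.genotype) == [0, 1]
    ]
    assert het_snps, "fixture must contain a het SNP"
    by_pos = {s.pos: s for s in sites}
    v = het_snps[0]
    assert v.pos in by_pos
    site = by_pos[v.pos]
    sigma = 0.5 / np.sqrt(site.depth)
    assert abs(site.alt_fraction - 0.5) < 3 * sigma
    # conversely every candidate coincides with a truth site
    truth_pos = {v.pos for v in out["genome"].variants}
    for s in sites:
        assert s.pos in truth_pos


def test_scan_monotone_in_min_af(sim_run):
    out = sim_run
    region = GenomeRegion(out["cfg"].contig_name, 200, 5_000)
    lo = {s.pos for s in scan_candidates(out["bam"], region, out["fasta"], min_af=0.2)}
    hi = {s.pos for s in scan_candidates(out["bam"], region, out["fasta"], min_af=0.35)}
    assert hi <= lo


def test_scan_unknown_contig_raises(sim_run):
    with pytest.raises(ValueError):
        scan_candidates(sim_run["bam"], GenomeRegion("nope", 0, 10), sim_run["fasta"])


# ---------------------------------------------------------------------------
# build_pileup_tensor


def _brute_force_nondeleted(bam_path, contig, w0, w1):
    """Independent per-position counter of aligned, non-deleted read bases
    (excluding N), via pysam's aligned-pairs machinery."""
    counts = np.zeros(w1 - w0)
    with pysam.AlignmentFile(bam_path) as bam:
        for read in bam.fetch(contig, max(w0, 0), w1):
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                if w0 <= rpos < w1 and read.query_sequence[qpos].upper() != "N":
                    counts[rpos - w0] += 1
    return counts


def test_tensor_empty_stack_is_zero(tmp_path, toy_ref):
    bam = write_bam(tmp_path / "t.bam", "toy", 60, [])
    site = CandidateSite("toy", 30, toy_ref["seq"][30], 1, 0)
    t = build_pileup_tensor(bam, site, toy_ref["fasta"])
    assert t.data.shape == (33, 8, 4)
    assert not t.data.any()


def test_tensor_hand_enumerated_counts(tmp_path):
    # ref ACGT at positions 0-3; 3 forward reads, one with C->T at offset 1
    fasta = write_fasta(tmp_path / "r.fa", "mini", "ACGTACGT")
    reads = [
        ("r0", 0, "4M", "ACGT", False),
        ("r1", 0, "4M", "ATGT", False),  # mismatch T at pos 1
        ("r2", 0, "4M", "ACGT", False),
    ]
    bam = write_bam(tmp_path / "m.bam", "mini", 8, reads)
    site = CandidateSite("mini", 1, "C", 3, 1)
    t = build_pileup_tensor(bam, site, fasta, flank=16)
    b = pileup.BASE_INDEX
    col = lambda p: p - (site.pos - 16)
    ch0 = t.data[:, :, 0]
    assert ch0[col(0), b["A"]] == 3
    assert ch0[col(1), b["C"]] == 2
    assert ch0[col(2), b["G"]] == 3
    assert ch0[col(3), b["T"]] == 3
    ch3 = t.data[:, :, 3]
    assert ch3[col(1), b["T"]] == 1
    assert ch3.sum() == 1
    assert t.data[:, :, 1].sum() == 0 and t.data[:, :, 2].sum() == 0
    # nothing on reverse rows
    assert not t.data[:, 4:, :].any()


def test_tensor_shape_is_33_8_4(sim_run):
    sites = scan_candidates(sim_run["bam"], sim_run["region"], sim_run["fasta"])
    t = build_pileup_tensor(sim_run["bam"], sites[0], sim_run["fasta"], flank=16)
    assert t.data.shape == (33, 8, 4)


def test_tensor_insertion_and_deletion_channels(tmp_path):
    fasta = write_fasta(tmp_path / "r.fa", "mini", "AACCGGTTAACC")
    reads = [
        ("ins", 0, "4M3I4M", "AACC" + "AAT" + "GGTT", False),  # AAT inserted after pos 3
        ("del", 0, "4M2D4M", "AACC" + "TTAA", True),  # positions 4,5 (G,G) deleted
    ]
    bam = write_bam(tmp_path / "m.bam", "mini", 12, reads)
    site = CandidateSite("mini", 3, "C", 2, 2)
    t = build_pileup_tensor(bam, site, fasta)
    b = pileup.BASE_INDEX
    col = lambda p: p - (site.pos - 16)
    # insertion bases all at the anchor column, per-base counts, forward rows
    assert t.data[col(3), b["A"], 1] == 2
    assert t.data[col(3), b["T"], 1] == 1
    # deletions on the reverse strand rows of the deleted reference bases
    assert t.data[col(4), b["G"] + 4, 2] == 1
    assert t.data[col(5), b["G"] + 4, 2] == 1


def test_tensor_contig_edge_padding(tmp_path, toy_ref):
    reads = [("r0", 0, "10M", toy_ref["seq"][:10], False)]
    bam = write_bam(tmp_path / "t.bam", "toy", 60, reads)
    site = CandidateSite("toy", 2, toy_ref["seq"][2], 1, 0)
    t = build_pileup_tensor(bam, site, toy_ref["fasta"])  # window starts at -14
    assert not t.data[:14].any()  # out-of-range columns all-zero
    assert t.data[14:].sum() > 0


def test_count_conservation_on_simulated_windows(sim_run):
    """Sum of channels 0+3 equals an independent brute-force counter."""
    sites = scan_candidates(sim_run["low_bam"], sim_run["region"], sim_run["fasta"])
    rng = np.random.default_rng(0)
    for s in (sites[i] for i in rng.choice(len(sites), size=25, replace=False)):
        t = build_pileup_tensor(sim_run["low_bam"], s, sim_run["fasta"])
        observed = t.data[:, :, 0].sum(axis=1) + t.data[:, :, 3].sum(axis=1)
        expected = _brute_force_nondeleted(sim_run["low_bam"], s.contig, s.pos - 16, s.pos + 17)
        np.testing.assert_array_equal(observed, expected)


def test_strand_split(sim_run, tmp_path):
    """Forward-only input puts nothing on reverse rows and vice versa."""
    with pysam.AlignmentFile(sim_run["low_bam"]) as src:
        fwd = [r for r in src.fetch() if not r.is_reverse]
        header = src.header
    fwd_bam = str(tmp_path / "fwd.bam")
    with pysam.AlignmentFile(fwd_bam, "wb", header=header) as out:
        for r in fwd:
            out.write(r)
    pysam.index(fwd_bam)
    sites = scan_candidates(fwd_bam, sim_run["region"], sim_run["fasta"])
    t = build_pileup_tensor(fwd_bam, sites[0], sim_run["fasta"])
    assert t.data[:, 4:, :].sum() == 0
    assert t.data[:, :4, :].sum() > 0


# ---------------------------------------------------------------------------
# flatten / unflatten


def test_flatten_zero():
    site = CandidateSite("x", 100, "A", 1, 0)
    t = pileup.PileupTensor(site, 16, np.zeros((33, 8, 4), dtype=np.float32))
    img = flatten_tensor(t)
    assert img.data.shape == (33, 32)
    assert not img.data.any()


def test_flatten_index_map_enumeration():
    site = CandidateSite("x", 100, "A", 1, 0)
    for b in range(8):
        for s in range(4):
            data = np.zeros((33, 8, 4), dtype=np.float32)
            data[0, b, s] = 7
            img = flatten_tensor(pileup.PileupTensor(site, 16, data))
            assert img.data[0, 4 * b + s] == 7
            assert img.data.sum() == 7


@settings(max_examples=100, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_flatten_roundtrip(seed):
    rng = np.random.default_rng(seed)
    data = rng.integers(0, 40, size=(33, 8, 4)).astype(np.float32)
    site = CandidateSite("x", 100, "A", 1, 0)
    t = pileup.PileupTensor(site, 16, data)
    back = unflatten_image(flatten_tensor(t), site)
    np.testing.assert_array_equal(back.data, t.data)


# ---------------------------------------------------------------------------
# labels


def _site(ref_base="G"):
    return CandidateSite("c", 500, ref_base, 10, 5)


def test_label_absent_record_is_hom_ref():
    lab = label_site(_site("G"), None)
    table = pileup.genotype_class_table()
    assert lab.zygosity == 0
    assert table[lab.gt21] == ("G", "G")
    assert lab.len1 == lab.len2 == 16


def test_label_het_snp():
    tv = TruthVariant("c", 500, "A", ("C",), (0, 1))
    lab = label_site(_site("A"), tv)
    assert lab.zygosity == 1
    assert pileup.genotype_class_table()[lab.gt21] == ("A", "C")
    assert lab.len1 == lab.len2 == 16


def test_label_het_insertion_t_to_taat():
    tv = TruthVariant("c", 500, "T", ("TAAT",), (0, 1))
    lab = label_site(_site("T"), tv)
    assert lab.zygosity == 1
    pair = pileup.genotype_class_table()[lab.gt21]
    assert "Ins" in pair and "T" in pair
    assert sorted((lab.len1, lab.len2)) == [16, 19]


def test_label_hom_deletion_agt_to_a():
    tv = TruthVariant("c", 500, "AGT", ("A",), (1, 1))
    lab = label_site(_site("A"), tv)
    assert lab.zygosity == 2
    pair = pileup.genotype_class_table()[lab.gt21]
    assert pair == ("Del", "Del")
    assert lab.len1 == lab.len2 == 14


def test_label_multiallelic_het():
    tv = TruthVariant("c", 500, "A", ("C", "T"), (1, 2))
    lab = label_site(_site("A"), tv)
    assert lab.zygosity == 1
    assert pileup.genotype_class_table()[lab.gt21] == ("C", "T")


def test_label_non_acgt_allele_rejected_with_warning():
    tv = TruthVariant("c", 500, "A", ("<DEL>",), (0, 1))
    with pytest.warns(UserWarning):
        lab = label_site(_site("A"), tv)
    assert lab.zygosity == 0


def test_label_length_clipped_to_flank():
    tv = TruthVariant("c", 500, "T", ("T" + "A" * 25,), (1, 1))
    lab = label_site(_site("T"), tv, flank=16)
    assert lab.len1 == lab.len2 == 32


# ---------------------------------------------------------------------------
# make_training_pairs


def test_pairs_identical_alignments_give_identical_images(sim_run):
    region = GenomeRegion(sim_run["cfg"].contig_name, 200, 2_000)
    ex = make_training_pairs(
        sim_run["bam"], sim_run["bam"], sim_run["vcf"], region, sim_run["fasta"]
    )
    assert ex
    for e in ex:
        np.testing.assert_array_equal(e.low_image.data, e.high_image.data)


def test_pairs_empty_truth_all_hom_ref(tmp_path, clean_sim_run):
    out = clean_sim_run
    empty_vcf = write_vcf(tmp_path / "empty.vcf", out["cfg"].contig_name, 8_000, [])
    # restrict to a variant-free window so all reads match the reference
    bounds = [210] + sorted(v.pos for v in out["genome"].variants) + [7800]
    start, end = max(
        ((bounds[i] + 40, bounds[i + 1] - 40) for i in range(len(bounds) - 1)),
        key=lambda w: w[1] - w[0],
    )
    region = GenomeRegion(out["cfg"].contig_name, start, end)
    ex = make_training_pairs(out["bam"], out["bam"], empty_vcf, region, out["fasta"])
    for e in ex:
        assert e.label.zygosity == 0


def test_pairs_planted_variants_carry_matching_labels(clean_sim_run):
    out = clean_sim_run
    ex = make_training_pairs(
        out["low_bam"] if "low_bam" in out else out["bam"],
        out["bam"],
        out["vcf"],
        out["region"],
        out["fasta"],
    )
    by_pos = {e.site.pos: e for e in ex}
    for v in out["genome"].variants:
        assert v.pos in by_pos, "every truth site must be emitted"
        lab = by_pos[v.pos].label
        expected = pileup.label_site(by_pos[v.pos].site, v)
        assert lab == expected
        assert lab.zygosity in (1, 2)
    # order is position-sorted and deterministic
    assert [e.site.pos for e in ex] == sorted(e.site.pos for e in ex)
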