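"""Shared fixtures: hand-built toy alignments and a small simulated run.

All fixtures are generated at test time; nothing binary ships with the
repository.
"""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from depthcall import simulate
from depthcall.pileup import GenomeRegion


def write_fasta(path, contig, seq):
    with open(path, "w") as fh:
        fh.write(f">{contig}\n{seq}\n")
    pysam.faidx(str(path))
    return str(path)


def write_bam(path, contig, contig_len, reads):
    """reads: iterable of (name, start, cigar_string, seq, is_reverse)."""
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": contig, "LN": contig_len}]}
    )
    records = []
    for name, start, cigar, seq, reverse in reads:
        a = pysam.AlignedSegment(header)
        a.query_name = name
        a.flag = 16 if reverse else 0
        a.reference_id = 0
        a.reference_start = start
        a.mapping_quality = 60
        a.cigarstring = cigar
        a.query_sequence = seq
        records.append(a)
    records.sort(key=lambda a: (a.reference_start, a.query_name))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for a in records:
            bam.write(a)
    pysam.index(str(path))
    return str(path)


def write_vcf(path, contig, contig_len, records, sample="truth"):
    """records: iterable of (pos0, ref, alts_tuple, genotype_tuple)."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.contigs.add(contig, length=contig_len)
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for pos0, ref, alts, gt in sorted(records):
            rec = vcf.new_record(
                contig=contig, start=pos0, stop=pos0 + len(ref), alleles=(ref,) + tuple(alts)
            )
            rec.samples[sample]["GT"] = gt
            rec.samples[sample].phased = False
            vcf.write(rec)
    return str(path)


@pytest.fixture(scope="session")
def toy_ref(tmp_path_factory):
    """60 bp contig with a known sequence."""
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=60))
    d = tmp_path_factory.mktemp("toyref")
    return {"contig": "toy", "seq": seq, "fasta": write_fasta(d / "toy.fa", "toy", seq)}


@pytest.fixture(scope="session")
def sim_run(tmp_path_factory):
    """20 kb simulated diploid sample at 30x with a 1/3 down-sampled twin."""
    d = tmp_path_factory.mktemp("sim")
    cfg = simulate.SimConfig(genome_length=20_000, depth=30.0, seed=11)
    out = simulate.simulate_run(cfg, d)
    out["low_bam"] = simulate.downsample(out["bam"], 1.0 / 3.0, 77, d / "low.bam")
    out["cfg"] = cfg
    out["region"] = GenomeRegion(cfg.contig_name, 200, 19_800)
    out["dir"] = d
    return out


@pytest.fixture(scope="session")
def clean_sim_run(tmp_path_factory):
    """Error-free 30x simulation: only true variant sites show alt support."""
    d = tmp_path_factory.mktemp("cleansim")
    cfg = simulate.SimConfig(
        genome_length=8_000,
        depth=30.0,
        seed=5,
        snp_rate=1e-3,
        indel_rate=3e-4,
        error_mismatch=0.0,
        error_insertion=0.0,
        error_deletion=0.0,
        read_length_mean=1200,
    )
    out = simulate.simulate_run(cfg, d)
    out["cfg"] = cfg
    out["region"] = GenomeRegion(cfg.contig_name, 200, 7_800)
    out["dir"] = d
    return out
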