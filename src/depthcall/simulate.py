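"""Diploid read simulator.

Plants SNPs and short indels into a random reference, emits noisy
long reads with their true alignments (no mapping step: the CIGAR is
derived from the known haplotype edits and injected errors), and
supports seeded read-level down-sampling. Everything is reproducible
from (config, seed): the same inputs yield byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as onp
import pysam

from .pileup import BASES, TruthVariant

_EDGE_BP = 200  # confident-region trim at contig ends


@dataclass
class SimConfig:
    genome_length: int = 100_000
    contig_name: str = "sim1"
    snp_rate: float = 1e-3
    indel_rate: float = 2e-4
    max_indel: int = 8
    het_fraction: float = 0.6
    error_mismatch: float = 0.05
    error_insertion: float = 0.03
    error_deletion: float = 0.03
    read_length_mean: int = 2000
    depth: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (
            self.snp_rate,
            self.indel_rate,
            self.het_fraction,
            self.error_mismatch,
            self.error_insertion,
            self.error_deletion,
        )
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("rates must lie in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.max_indel < 1:
            raise ValueError("max_indel must be >= 1")

    @property
    def error_profile(self) -> dict:
        return {
            "mismatch": self.error_mismatch,
            "insertion": self.error_insertion,
            "deletion": self.error_deletion,
        }


@dataclass
class DiploidGenome:
    contig: str
    reference: str
    haplotypes: tuple[str, str]
    variants: list[TruthVariant] = field(default_factory=list)


def _other_base(rng, base: str) -> str:
    choices = [b for b in BASES if b != base]
    return choices[rng.integers(len(choices))]


def apply_variants(reference: str, variants: list[TruthVariant], hap: int) -> str:
    """Apply the hap-th allele of each variant to the reference."""
    parts = []
    cursor = 0
    for v in sorted(variants, key=lambda v: v.pos):
        allele = v.allele_seq(v.genotype[hap])
        parts.append(reference[cursor : v.pos])
        parts.append(allele)
        cursor = v.pos + len(v.ref)
    parts.append(reference[cursor:])
    return "".join(parts)


def simulate_genome(cfg: SimConfig) -> DiploidGenome:
    """Random reference with planted variants; variants are spaced at
    least 2*max_indel apart and kept away from the contig edges."""
    rng = onp.random.default_rng(cfg.seed)
    ref = "".join(rng.choice(list(BASES), size=cfg.genome_length))

    total_rate = cfg.snp_rate + cfg.indel_rate
    variants: list[TruthVariant] = []
    if total_rate > 0:
        hits = onp.flatnonzero(rng.random(cfg.genome_length) < total_rate)
        spacing = 2 * cfg.max_indel
        edge = max(_EDGE_BP, 2 * cfg.max_indel)
        last = -(10 * spacing)
        for pos in hits:
            pos = int(pos)
            if pos < edge or pos >= cfg.genome_length - edge:
                continue
            if pos - last < spacing:
                continue
            last = pos
            is_indel = rng.random() < (cfg.indel_rate / total_rate)
            het = rng.random() < cfg.het_fraction
            genotype = (0, 1) if het and rng.random() < 0.5 else ((1, 0) if het else (1, 1))
            if not is_indel:
                ref_allele = ref[pos]
                alt = _other_base(rng, ref_allele)
            else:
                length = int(min(rng.geometric(0.5), cfg.max_indel))
                if rng.random() < 0.5:  # insertion after pos
                    ref_allele = ref[pos]
                    alt = ref_allele + "".join(rng.choice(list(BASES), size=length))
                else:  # deletion of bases pos+1 .. pos+length
                    ref_allele = ref[pos : pos + length + 1]
                    alt = ref[pos]
            variants.append(
                TruthVariant(
                    contig=cfg.contig_name,
                    pos=pos,
                    ref=ref_allele,
                    alts=(alt,),
                    genotype=genotype,
                )
            )
    haps = (apply_variants(ref, variants, 0), apply_variants(ref, variants, 1))
    return DiploidGenome(cfg.contig_name, ref, haps, variants)


# ---------------------------------------------------------------------------
# read generation


def _haplotype_edits(variants: list[TruthVariant], hap: int):
    subs: dict[int, str] = {}
    ins: dict[int, str] = {}
    dels: set[int] = set()
    for v in variants:
        allele = v.allele_seq(v.genotype[hap])
        if allele == v.ref:
            continue
        if len(allele) == len(v.ref):
            subs[v.pos] = allele
        elif len(allele) > len(v.ref):
            ins[v.pos] = allele[len(v.ref) :]
        else:
            for p in range(v.pos + 1, v.pos + len(v.ref)):
                dels.add(p)
    return subs, ins, dels


class _CigarBuilder:
    def __init__(self) -> None:
        self.ops: list[list[int]] = []  # [op, length]

    def add(self, op: int, length: int = 1) -> None:
        if length <= 0:
            return
        if self.ops and self.ops[-1][0] == op:
            self.ops[-1][1] += length
        else:
            self.ops.append([op, length])

    def finish(self) -> tuple[list[tuple[int, int]], int]:
        while self.ops and self.ops[-1][0] == 2:  # no trailing deletion
            self.ops.pop()
        lead_del = 0
        while self.ops and self.ops[0][0] == 2:  # no leading deletion
            lead_del += self.ops.pop(0)[1]
        return [tuple(o) for o in self.ops], lead_del


def _make_read(rng, genome, edits, cfg, start: int, target_len: int):
    """Walk the reference from ``start`` applying haplotype edits and
    sequencing errors; returns (seq, cigar, ref_start) or None."""
    subs, ins, dels = edits
    L = len(genome.reference)
    p = start
    while p < L and p in dels:  # never start inside a deleted stretch
        p += 1
    if p >= L:
        return None
    ref_start = p
    seq: list[str] = []
    cig = _CigarBuilder()
    while p < L and len(seq) < target_len:
        if p in dels:
            cig.add(2)
            p += 1
            continue
        base = subs.get(p, genome.reference[p])
        r = rng.random()
        if r < cfg.error_deletion:
            cig.add(2)
        else:
            if r < cfg.error_deletion + cfg.error_mismatch:
                base = _other_base(rng, base)
            seq.append(base)
            cig.add(0)
        if p in ins:
            inserted = ins[p]
            seq.append(inserted)
            cig.add(1, len(inserted))
        if rng.random() < cfg.error_insertion:
            seq.append(BASES[rng.integers(4)])
            cig.add(1)
        p += 1
    cigar, lead_del = cig.finish()
    if not any(op == 0 for op, _ in cigar):
        return None
    return "".join(seq), cigar, ref_start + lead_del


def _bam_header(genome: DiploidGenome) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": genome.contig, "LN": len(genome.reference)}],
        }
    )


def simulate_reads(genome: DiploidGenome, cfg: SimConfig, out_bam) -> str:
    """Emit noisy reads alternating between haplotypes and strands into a
    sorted, indexed BAM. Returns the BAM path."""
    rng = onp.random.default_rng(cfg.seed + 1)
    L = len(genome.reference)
    m = cfg.read_length_mean
    # starts are drawn over [-len+1, L) and clipped, so coverage is flat
    # across the whole contig; n is scaled to keep the mean at cfg.depth
    n_reads = max(1, int(round(cfg.depth * (L + m) / m)))
    edits = (_haplotype_edits(genome.variants, 0), _haplotype_edits(genome.variants, 1))

    records = []
    for i in range(n_reads):
        hap = i % 2
        reverse = (i // 2) % 2 == 1
        target_len = max(100, int(rng.exponential(m)))
        start = int(rng.integers(1 - target_len, max(2 - target_len, L - 50)))
        if start < 0:
            target_len += start
            start = 0
        if target_len < 50:
            continue
        made = _make_read(rng, genome, edits[hap], cfg, start, min(target_len, L - start))
        if made is None:
            continue
        seq, cigar, ref_start = made
        if not seq:
            continue
        records.append((ref_start, f"read{i}", seq, cigar, reverse))

    records.sort(key=lambda r: (r[0], r[1]))
    header = _bam_header(genome)
    out_bam = str(out_bam)
    with pysam.AlignmentFile(out_bam, "wb", header=header) as bam:
        for ref_start, name, seq, cigar, reverse in records:
            a = pysam.AlignedSegment(header)
            a.query_name = name
            a.flag = 16 if reverse else 0
            a.reference_id = 0
            a.reference_start = ref_start
            a.mapping_quality = 60
            a.cigartuples = cigar
            a.query_sequence = seq
            bam.write(a)
    pysam.index(out_bam)
    return out_bam


def downsample(in_bam, rate: float, seed: int, out_bam) -> str:
    """Keep each read independently with probability ``rate`` (seeded)."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    rng = onp.random.default_rng(seed)
    in_bam, out_bam = str(in_bam), str(out_bam)
    with pysam.AlignmentFile(in_bam, "rb") as src:
        with pysam.AlignmentFile(out_bam, "wb", header=src.header) as dst:
            for read in src.fetch(until_eof=True):
                if rng.random() < rate:
                    dst.write(read)
    pysam.index(out_bam)
    return out_bam


# ---------------------------------------------------------------------------
# on-disk artifacts


def write_fasta(genome: DiploidGenome, path) -> str:
    path = str(path)
    with open(path, "w") as fh:
        fh.write(f">{genome.contig}\n")
        for i in range(0, len(genome.reference), 70):
            fh.write(genome.reference[i : i + 70] + "\n")
    pysam.faidx(path)
    return path


def write_truth_vcf(genome: DiploidGenome, path) -> str:
    path = str(path)
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.contigs.add(genome.contig, length=len(genome.reference))
    header.add_sample("sim")
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for v in sorted(genome.variants, key=lambda v: v.pos):
            rec = vcf.new_record(
                contig=v.contig,
                start=v.pos,
                stop=v.pos + len(v.ref),
                alleles=(v.ref,) + v.alts,
            )
            rec.samples["sim"]["GT"] = v.genotype
            rec.samples["sim"].phased = False
            vcf.write(rec)
    return path


def write_confident_bed(genome: DiploidGenome, path) -> str:
    path = str(path)
    with open(path, "w") as fh:
        end = max(_EDGE_BP + 1, len(genome.reference) - _EDGE_BP)
        fh.write(f"{genome.contig}\t{_EDGE_BP}\t{end}\n")
    return path


def simulate_run(cfg: SimConfig, outdir) -> dict:
    """Full simulation: reference FASTA, truth VCF, confident BED, and a
    sorted indexed BAM at the configured depth."""
    os.makedirs(str(outdir), exist_ok=True)
    genome = simulate_genome(cfg)
    paths = {
        "fasta": write_fasta(genome, os.path.join(str(outdir), "ref.fa")),
        "vcf": write_truth_vcf(genome, os.path.join(str(outdir), "truth.vcf")),
        "bed": write_confident_bed(genome, os.path.join(str(outdir), "confident.bed")),
        "bam": simulate_reads(genome, cfg, os.path.join(str(outdir), "reads.bam")),
    }
    return {"genome": genome, **paths}
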