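"""Decode caller attribute probabilities into concrete variant calls.

The zygosity head gates the decision: a homozygous-reference argmax
yields no call; otherwise the most probable genotype-pair class that is
consistent with the zygosity is selected (heterozygous classes either
contain the reference symbol or pair two distinct non-reference symbols
for a 1/2 call; homozygous-alternate classes pair a non-reference
symbol with itself). Indel allele sequences are reconstructed from the
supporting reads, with the decoded length classes as a guide.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as onp
import pysam

from . import models
from .pileup import (
    BASES,
    DEFAULT_FLANK,
    DEFAULT_MIN_AF,
    DEFAULT_MIN_DEPTH,
    CandidateSite,
    GenomeRegion,
    _open_bam,
    _open_fasta,
    build_pileup_tensor,
    flatten_tensor,
    genotype_class_table,
    scan_candidates,
)

QUAL_CAP = 60.0

GT_TABLE = genotype_class_table()


@dataclass
class AttributeProbabilities:
    p_gt21: onp.ndarray
    p_zyg: onp.ndarray
    p_len1: onp.ndarray
    p_len2: onp.ndarray

    def __post_init__(self) -> None:
        for name, vec, k in (
            ("p_gt21", self.p_gt21, 21),
            ("p_zyg", self.p_zyg, 3),
            ("p_len1", self.p_len1, 33),
            ("p_len2", self.p_len2, 33),
        ):
            vec = onp.asarray(vec, dtype=onp.float64)
            if vec.shape != (k,):
                raise ValueError(f"{name} must have shape ({k},)")
            if abs(float(vec.sum()) - 1.0) > 1e-4 or (vec < 0).any():
                raise ValueError(f"{name} is not a probability simplex")
            setattr(self, name, vec)

    @classmethod
    def from_heads(cls, heads: dict, index: int | None = None):
        pick = (lambda a: a[index]) if index is not None else (lambda a: a)
        return cls(
            p_gt21=pick(heads["gt21"]),
            p_zyg=pick(heads["zygosity"]),
            p_len1=pick(heads["len1"]),
            p_len2=pick(heads["len2"]),
        )


@dataclass
class VariantCall:
    contig: str
    pos: int  # 1-based
    ref_allele: str
    alt_alleles: list[str]
    genotype: str  # 0/1, 1/1 or 1/2
    qual: float
    filter: str = "PASS"

    def __post_init__(self) -> None:
        if any(a == self.ref_allele for a in self.alt_alleles):
            raise ValueError("alt allele equals ref allele")


@dataclass
class SiteEvidence:
    """Read-level indel evidence at a site: inserted sequences anchored at
    the site and lengths of deletions starting immediately after it."""

    insertions: Counter = field(default_factory=Counter)
    deletion_lengths: Counter = field(default_factory=Counter)


def collect_indel_evidence(alignment, site: CandidateSite) -> SiteEvidence:
    aln = _open_bam(alignment)
    ev = SiteEvidence()
    for read in aln.fetch(site.contig, site.pos, site.pos + 1):
        if read.is_unmapped or read.cigartuples is None:
            continue
        rpos = read.reference_start
        qpos = 0
        seq = (read.query_sequence or "").upper()
        for op, length in read.cigartuples:
            if op in (0, 7, 8):
                rpos += length
                qpos += length
            elif op == 1:
                if rpos - 1 == site.pos:
                    ev.insertions[seq[qpos : qpos + length]] += 1
                qpos += length
            elif op == 2 or op == 3:
                if op == 2 and rpos == site.pos + 1:
                    ev.deletion_lengths[length] += 1
                rpos += length
            elif op == 4:
                qpos += length
    return ev


def _consensus_insertion(ev: SiteEvidence, want_len: int) -> str:
    if ev.insertions:
        of_len = {s: c for s, c in ev.insertions.items() if len(s) == want_len}
        pool = of_len or dict(ev.insertions)
        return max(sorted(pool), key=pool.__getitem__)
    return "A" * max(want_len, 1)


def _consensus_deletion_length(ev: SiteEvidence, want_len: int) -> int:
    if want_len > 0:
        return want_len
    if ev.deletion_lengths:
        return max(sorted(ev.deletion_lengths), key=ev.deletion_lengths.__getitem__)
    return 1


def _admissible_classes(zygosity: int, ref_symbol: str | None) -> list[int]:
    out = []
    for k, (a, b) in enumerate(GT_TABLE):
        if zygosity == 1:
            if ref_symbol is None:
                ok = a != b
            else:
                ok = (a != b) and (ref_symbol in (a, b) or (a != ref_symbol and b != ref_symbol))
        else:  # hom-alt
            ok = a == b and a != ref_symbol
        if ok:
            out.append(k)
    return out


def _phred(p_conf: float) -> float:
    err = max(1.0 - p_conf, 1e-6)
    return min(QUAL_CAP, -10.0 * math.log10(err))


def decode_site(
    probs: AttributeProbabilities,
    site: CandidateSite,
    alignment,
    reference,
    flank: int = DEFAULT_FLANK,
) -> VariantCall | None:
    """Total decoding rule: every (zygosity, gt21) argmax combination maps
    to either ``None`` or a well-formed call."""
    zyg = int(onp.argmax(probs.p_zyg))
    if zyg == 0:
        return None
    ref = _open_fasta(reference)
    ref_base = site.ref_base.upper()
    ref_symbol = ref_base if ref_base in BASES else None

    admissible = _admissible_classes(zyg, ref_symbol)
    k = max(admissible, key=lambda i: probs.p_gt21[i])
    sym_a, sym_b = GT_TABLE[k]

    deltas = sorted((int(onp.argmax(probs.p_len1)) - flank, int(onp.argmax(probs.p_len2)) - flank))
    ins_len = max((d for d in deltas if d > 0), default=0)
    del_len = max((-d for d in deltas if d < 0), default=0)

    ev = None
    filt = "PASS"
    contig_len = ref.get_reference_length(site.contig)

    # deletion extent shared by all alleles at the site
    alt_symbols = [s for s in (sym_a, sym_b) if s != ref_symbol] if zyg == 1 else [sym_a]
    if zyg == 1 and ref_symbol is not None and ref_symbol not in (sym_a, sym_b):
        alt_symbols = [sym_a, sym_b]  # multi-allelic het (1/2)

    del_extent = 0
    if "Del" in alt_symbols:
        if ev is None:
            ev = collect_indel_evidence(alignment, site)
        del_extent = _consensus_deletion_length(ev, del_len)
        if del_extent > flank:
            del_extent = flank
            filt = "lowqual"
        del_extent = min(del_extent, contig_len - site.pos - 1)
        if del_extent < 1:
            return None  # deletion decoded at the contig edge: nothing to delete

    suffix = ref.fetch(site.contig, site.pos + 1, site.pos + 1 + del_extent).upper()
    ref_allele = ref_base + suffix

    alts: list[str] = []
    for sym in alt_symbols:
        if sym == "Del":
            alts.append(ref_base)
        elif sym == "Ins":
            if ev is None:
                ev = collect_indel_evidence(alignment, site)
            want = ins_len
            if want > flank:
                want = flank
                filt = "lowqual"
            alts.append(ref_base + _consensus_insertion(ev, want) + suffix)
        else:  # SNP symbol
            alts.append(sym + suffix)

    # degenerate collisions (e.g. no usable distinction) -> drop duplicates
    seen: list[str] = []
    for a in alts:
        if a != ref_allele and a not in seen:
            seen.append(a)
    if not seen:
        return None
    genotype = {1: "0/1", 2: "1/1"}[zyg] if len(seen) == 1 else "1/2"
    p_conf = min(float(probs.p_zyg.max()), float(probs.p_gt21.max()))
    return VariantCall(
        contig=site.contig,
        pos=site.pos + 1,
        ref_allele=ref_allele,
        alt_alleles=seen,
        genotype=genotype,
        qual=_phred(p_conf),
        filter=filt,
    )


def call_region(
    g_params: dict | None,
    c_params: dict,
    alignment,
    reference,
    region: GenomeRegion,
    min_af: float = DEFAULT_MIN_AF,
    min_depth: int = DEFAULT_MIN_DEPTH,
    flank: int = DEFAULT_FLANK,
    use_generator: bool = True,
    batch_size: int = 128,
) -> list[VariantCall]:
    """Scan, featurize, project, classify and decode a region.

    With ``use_generator=False`` (or ``g_params=None``) the caller sees
    the low-depth image twice — the generator-free baseline.
    """
    aln = _open_bam(alignment)
    ref = _open_fasta(reference)
    sites = scan_candidates(aln, region, ref, min_af=min_af, min_depth=min_depth)
    if not sites:
        return []
    images = onp.stack(
        [
            flatten_tensor(build_pileup_tensor(aln, s, ref, flank)).data
            for s in sites
        ]
    ).astype(onp.float32)

    calls: list[VariantCall] = []
    for i in range(0, len(sites), batch_size):
        chunk = images[i : i + batch_size]
        if use_generator and g_params is not None:
            gen = onp.asarray(models.generator_forward(g_params, chunk), dtype=onp.float32)
        else:
            gen = chunk
        heads = models.caller_forward(c_params, gen, chunk)
        for j, site in enumerate(sites[i : i + batch_size]):
            probs = AttributeProbabilities.from_heads(heads, j)
            call = decode_site(probs, site, aln, ref, flank)
            if call is not None:
                calls.append(call)
    calls.sort(key=lambda c: c.pos)
    return calls


# ---------------------------------------------------------------------------
# VCF output


def write_vcf(
    calls: list[VariantCall],
    contigs: list[tuple[str, int]],
    path,
    sample: str = "SAMPLE",
) -> str:
    """Write calls as VCF v4.2 with GT and GQ; calls are sorted first."""
    path = str(path)
    header = pysam.VariantHeader()
    header.add_line('##FILTER=<ID=lowqual,Description="Clipped or low-confidence decode">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    for name, length in contigs:
        header.contigs.add(name, length=length)
    header.add_sample(sample)
    order = {name: i for i, (name, _) in enumerate(contigs)}
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for call in sorted(calls, key=lambda c: (order.get(c.contig, 0), c.pos)):
            rec = vcf.new_record(
                contig=call.contig,
                start=call.pos - 1,
                stop=call.pos - 1 + len(call.ref_allele),
                alleles=(call.ref_allele, *call.alt_alleles),
                qual=round(call.qual, 2),
            )
            rec.filter.add(call.filter)
            gt = tuple(int(x) for x in call.genotype.split("/"))
            rec.samples[sample]["GT"] = gt
            rec.samples[sample].phased = False
            rec.samples[sample]["GQ"] = int(round(call.qual))
            vcf.write(rec)
    return path


def read_calls(path) -> list[VariantCall]:
    """Inverse of :func:`write_vcf` for round-trip checks."""
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch():
            gt = rec.samples[0]["GT"]
            out.append(
                VariantCall(
                    contig=rec.contig,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_alleles=list(rec.alts or ()),
                    genotype="/".join(str(g) for g in gt),
                    qual=float(rec.qual) if rec.qual is not None else 0.0,
                    filter=next(iter(rec.filter), "PASS"),
                )
            )
    return out
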