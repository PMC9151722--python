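"""Genotype-aware VCF comparison and precision/recall/F1 arithmetic.

Matching is exact after trimming-based left alignment: a call is a true
positive iff a truth record agrees on contig, position, reference
allele and the unordered pair of genotype allele sequences. This is
deliberately stricter than haplotype-aware matchers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pysam


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class MetricsResult:
    precision: float
    recall: float
    f1: float
    degenerate: bool = False


def round_half_up(x: float, places: int = 4) -> float:
    q = Decimal(10) ** -places
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def compute_metrics(c: ConfusionCounts) -> MetricsResult:
    """precision = tp/(tp+fp), recall = tp/(tp+fn), f1 = harmonic mean;
    zero denominators yield 0 with the degenerate flag set."""
    degenerate = False
    if c.tp + c.fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = c.tp / (c.tp + c.fn)
    if precision + recall == 0:
        return MetricsResult(precision, recall, 0.0, True)
    f1 = 2 * precision * recall / (precision + recall)
    return MetricsResult(precision, recall, f1, degenerate)


def f1_from_precision_recall(precision: float, recall: float) -> float:
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


# ---------------------------------------------------------------------------
# record normalization and matching


@dataclass(frozen=True)
class _Record:
    contig: str
    pos: int  # 0-based, post-normalization
    ref: str
    gt_alleles: tuple[str, ...]  # sorted pair of genotype allele sequences


def normalize_alleles(pos: int, ref: str, alleles: list[str]) -> tuple[int, str, list[str]]:
    """Trim shared trailing then leading bases across ref + all alleles."""
    seqs = [ref] + list(alleles)
    while all(len(s) > 1 for s in seqs) and len({s[-1] for s in seqs}) == 1:
        seqs = [s[:-1] for s in seqs]
    while all(len(s) > 1 for s in seqs) and len({s[0] for s in seqs}) == 1:
        seqs = [s[1:] for s in seqs]
        pos += 1
    return pos, seqs[0], seqs[1:]


def _record_is_snp(ref: str, gt_alleles: tuple[str, ...]) -> bool:
    return len(ref) == 1 and all(len(a) == 1 for a in gt_alleles)


def _load_records(vcf_path, regions=None, variant_type=None) -> list[_Record]:
    out = []
    seen = set()
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf.fetch():
            if regions is not None and not _in_regions(rec.contig, rec.start, regions):
                continue
            if not rec.samples or rec.samples[0].get("GT") is None:
                continue
            gt = rec.samples[0]["GT"]
            if len(gt) != 2 or any(g is None for g in gt):
                continue
            alleles = (rec.ref,) + tuple(rec.alts or ())
            gt_seqs = [alleles[g].upper() for g in gt]
            if all(s == rec.ref.upper() for s in gt_seqs):
                continue  # hom-ref records carry no variant
            pos, ref, norm = normalize_alleles(rec.start, rec.ref.upper(), gt_seqs)
            if variant_type == "snp" and not _record_is_snp(ref, tuple(norm)):
                continue
            if variant_type == "indel" and _record_is_snp(ref, tuple(norm)):
                continue
            key = (rec.contig, pos, ref, tuple(sorted(norm)))
            if key in seen:
                warnings.warn(f"duplicate record at {rec.contig}:{pos + 1}; keeping first")
                continue
            seen.add(key)
            out.append(_Record(rec.contig, pos, ref, tuple(sorted(norm))))
    return out


def read_bed(path) -> list[tuple[str, int, int]]:
    regions = []
    with open(str(path)) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            regions.append((fields[0], int(fields[1]), int(fields[2])))
    return regions


def _in_regions(contig, pos, regions) -> bool:
    return any(c == contig and s <= pos < e for c, s, e in regions)


def match_calls(called_vcf, truth_vcf, regions_bed=None, variant_type=None) -> ConfusionCounts:
    """Genotype-aware exact matching of called against truth records,
    optionally restricted to BED regions and/or one variant type
    ('snp' or 'indel')."""
    regions = read_bed(regions_bed) if regions_bed is not None else None
    called = _load_records(called_vcf, regions, variant_type)
    truth = _load_records(truth_vcf, regions, variant_type)
    truth_keys = {(r.contig, r.pos, r.ref, r.gt_alleles) for r in truth}
    called_keys = {(r.contig, r.pos, r.ref, r.gt_alleles) for r in called}
    tp = len(called_keys & truth_keys)
    return ConfusionCounts(tp=tp, fp=len(called_keys) - tp, fn=len(truth_keys) - tp)
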