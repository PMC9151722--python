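"""Candidate scanning and counting-pileup featurization.

A candidate site is any reference position whose fraction of
alternative read observations (mismatch, insertion anchor or deletion)
reaches ``min_af``. Around each candidate, the local read stack is
summarised into a (2*flank+1, 8, 4) tensor of non-negative counts:

* axis 0 — reference positions ``[pos - flank, pos + flank]``;
* axis 1 — stranded read base, fixed order A, C, G, T (forward) then
  A-, C-, G-, T- (reverse);
* axis 2 — counting channel: 0 reference-matching bases, 1 inserted
  bases (all attributed to the anchor column), 2 deletions (attributed
  to the deleted reference base row), 3 mismatching bases.

Flattening along the last axis (column = 4*base_row + channel) yields
the 33x32 image exchanged between the networks; the reshape is a
bijection and ``unflatten_image`` inverts it exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pysam

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: allele symbols used by the 21-class genotype encoding, in canonical order
GT_SYMBOLS = ("A", "C", "G", "T", "Ins", "Del")

DEFAULT_FLANK = 16
DEFAULT_MIN_AF = 0.2
DEFAULT_MIN_DEPTH = 4

# counting channels
CH_REF, CH_INS, CH_DEL, CH_ALT = 0, 1, 2, 3

_MATCH_OPS = frozenset((0, 7, 8))  # M, =, X


@dataclass(frozen=True)
class GenomeRegion:
    """Half-open 0-based interval on a contig."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid region {self.contig}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CandidateSite:
    """A position with enough alternative-allele support to be decoded."""

    contig: str
    pos: int  # 0-based
    ref_base: str
    depth: int
    alt_support: int

    @property
    def alt_fraction(self) -> float:
        return self.alt_support / self.depth if self.depth else 0.0


@dataclass
class PileupTensor:
    site: CandidateSite
    flank: int
    data: np.ndarray  # (2*flank+1, 8, 4) float32 counts

    def __post_init__(self) -> None:
        expected = (2 * self.flank + 1, 8, 4)
        if self.data.shape != expected:
            raise ValueError(f"tensor shape {self.data.shape} != {expected}")
        if (self.data < 0).any():
            raise ValueError("pileup counts must be non-negative")


@dataclass
class PileupImage:
    data: np.ndarray  # (2*flank+1, 32)
    provenance: str = "observed_low"  # observed_low | observed_high | generated


@dataclass(frozen=True)
class VariantLabel:
    """Four classification targets: genotype pair, zygosity, allele length changes."""

    gt21: int
    zygosity: int  # 0 hom-ref, 1 het, 2 hom-alt
    len1: int  # index into [-flank, +flank] mapped by +flank
    len2: int

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.gt21, self.zygosity, self.len1, self.len2)


@dataclass
class TrainingExample:
    low_image: PileupImage
    high_image: PileupImage
    label: VariantLabel
    site: CandidateSite


@dataclass(frozen=True)
class TruthVariant:
    """Normalized truth record: 0-based pos, ref/alt strings, diploid genotype.

    ``genotype`` holds two allele indices into ``[ref] + alts`` (0 = ref).
    """

    contig: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotype: tuple[int, int]

    def allele_seq(self, index: int) -> str:
        return self.ref if index == 0 else self.alts[index - 1]


# ---------------------------------------------------------------------------
# file handling helpers


def _open_bam(alignment) -> pysam.AlignmentFile:
    if isinstance(alignment, pysam.AlignmentFile):
        return alignment
    return pysam.AlignmentFile(str(alignment), "rb")


def _open_fasta(reference) -> pysam.FastaFile:
    if isinstance(reference, pysam.FastaFile):
        return reference
    return pysam.FastaFile(str(reference))


def _check_region(region: GenomeRegion, ref: pysam.FastaFile) -> None:
    if region.contig not in ref.references:
        raise ValueError(f"unknown contig {region.contig!r}")
    if region.end > ref.get_reference_length(region.contig):
        raise ValueError(f"region {region} exceeds contig bounds")


# ---------------------------------------------------------------------------
# candidate scanning


def _scan_arrays(
    aln: pysam.AlignmentFile, region: GenomeRegion, refseq: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position read depth and alternative-observation counts.

    Depth counts every read aligned over a position (match or deletion);
    alternative support counts mismatching bases, deleted positions and
    insertion events (one per event, at the anchor position).
    """
    n = len(region)
    depth = np.zeros(n, dtype=np.int64)
    alt = np.zeros(n, dtype=np.int64)
    ref_arr = np.frombuffer(refseq.upper().encode(), dtype=np.uint8)

    for read in aln.fetch(region.contig, region.start, region.end):
        if read.is_unmapped or read.cigartuples is None:
            continue
        rpos = read.reference_start
        qpos = 0
        seq = read.query_sequence or ""
        for op, length in read.cigartuples:
            if op in _MATCH_OPS:
                lo = max(rpos, region.start)
                hi = min(rpos + length, region.end)
                if lo < hi:
                    depth[lo - region.start : hi - region.start] += 1
                    qseg = np.frombuffer(
                        seq[qpos + (lo - rpos) : qpos + (hi - rpos)].upper().encode(),
                        dtype=np.uint8,
                    )
                    rseg = ref_arr[lo - region.start : hi - region.start]
                    mism = (qseg != rseg) & (qseg != ord("N"))
                    alt[lo - region.start : hi - region.start] += mism
                rpos += length
                qpos += length
            elif op == 1:  # insertion anchored at the preceding reference base
                anchor = rpos - 1
                if region.start <= anchor < region.end:
                    alt[anchor - region.start] += 1
                qpos += length
            elif op == 2 or op == 3:  # deletion / ref skip
                lo = max(rpos, region.start)
                hi = min(rpos + length, region.end)
                if lo < hi and op == 2:
                    depth[lo - region.start : hi - region.start] += 1
                    alt[lo - region.start : hi - region.start] += 1
                rpos += length
            elif op == 4:  # soft clip
                qpos += length
            # hard clip / pad consume nothing
    return depth, alt


def scan_candidates(
    alignment,
    region: GenomeRegion,
    reference,
    min_af: float = DEFAULT_MIN_AF,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> list[CandidateSite]:
    """Return every position in ``region`` whose alternative-allele
    fraction reaches ``min_af`` at depth >= ``min_depth``, sorted by position."""
    aln = _open_bam(alignment)
    ref = _open_fasta(reference)
    _check_region(region, ref)
    refseq = ref.fetch(region.contig, region.start, region.end).upper()
    depth, alt = _scan_arrays(aln, region, refseq)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    keep = (depth >= min_depth) & (frac >= min_af)
    sites = []
    for i in np.flatnonzero(keep):
        sites.append(
            CandidateSite(
                contig=region.contig,
                pos=region.start + int(i),
                ref_base=refseq[i],
                depth=int(depth[i]),
                alt_support=int(alt[i]),
            )
        )
    return sites


# ---------------------------------------------------------------------------
# tensor construction


def build_pileup_tensor(
    alignment,
    site: CandidateSite,
    reference,
    flank: int = DEFAULT_FLANK,
) -> PileupTensor:
    """Count the read stack around ``site`` into the stranded pileup tensor.

    Window columns that extend past the contig edge stay all-zero.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    aln = _open_bam(alignment)
    ref = _open_fasta(reference)
    contig_len = ref.get_reference_length(site.contig)
    if not (0 <= site.pos < contig_len):
        raise ValueError(f"site position {site.pos} outside contig {site.contig}")

    w0 = site.pos - flank
    w1 = site.pos + flank + 1  # exclusive
    width = 2 * flank + 1
    data = np.zeros((width, 8, 4), dtype=np.float32)

    lo_fetch = max(w0, 0)
    hi_fetch = min(w1, contig_len)
    refwin = ref.fetch(site.contig, lo_fetch, hi_fetch).upper()

    def ref_base_at(p: int) -> str:
        if lo_fetch <= p < hi_fetch:
            return refwin[p - lo_fetch]
        return "N"

    for read in aln.fetch(site.contig, lo_fetch, hi_fetch):
        if read.is_unmapped or read.cigartuples is None:
            continue
        srow = 4 if read.is_reverse else 0
        rpos = read.reference_start
        qpos = 0
        seq = (read.query_sequence or "").upper()
        for op, length in read.cigartuples:
            if op in _MATCH_OPS:
                lo = max(rpos, w0)
                hi = min(rpos + length, w1)
                for p in range(lo, hi):
                    b = seq[qpos + (p - rpos)]
                    if b not in BASE_INDEX:
                        continue
                    ch = CH_REF if b == ref_base_at(p) else CH_ALT
                    data[p - w0, BASE_INDEX[b] + srow, ch] += 1
                rpos += length
                qpos += length
            elif op == 1:
                anchor = rpos - 1
                if w0 <= anchor < w1:
                    for b in seq[qpos : qpos + length]:
                        if b in BASE_INDEX:
                            data[anchor - w0, BASE_INDEX[b] + srow, CH_INS] += 1
                qpos += length
            elif op == 2 or op == 3:
                if op == 2:
                    lo = max(rpos, w0)
                    hi = min(rpos + length, w1)
                    for p in range(lo, hi):
                        rb = ref_base_at(p)
                        if rb in BASE_INDEX:
                            data[p - w0, BASE_INDEX[rb] + srow, CH_DEL] += 1
                rpos += length
            elif op == 4:
                qpos += length
    return PileupTensor(site=site, flank=flank, data=data)


def flatten_tensor(t: PileupTensor, provenance: str = "observed_low") -> PileupImage:
    """Flatten (width, 8, 4) -> (width, 32) with column = 4*base_row + channel."""
    width = t.data.shape[0]
    return PileupImage(data=t.data.reshape(width, 32).copy(), provenance=provenance)


def unflatten_image(img: PileupImage, site: CandidateSite | None = None) -> PileupTensor:
    """Exact inverse of :func:`flatten_tensor`."""
    width = img.data.shape[0]
    flank = (width - 1) // 2
    if site is None:
        site = CandidateSite("unknown", flank, "N", 1, 0)
    return PileupTensor(site=site, flank=flank, data=img.data.reshape(width, 8, 4).copy())


# ---------------------------------------------------------------------------
# labels


def genotype_class_table() -> list[tuple[str, str]]:
    """All 21 unordered symbol pairs (with repetition) over the six
    allele symbols, in lexicographic order of (index_i, index_j), i <= j."""
    pairs = []
    for i in range(len(GT_SYMBOLS)):
        for j in range(i, len(GT_SYMBOLS)):
            pairs.append((GT_SYMBOLS[i], GT_SYMBOLS[j]))
    return pairs


_GT_TABLE = genotype_class_table()
_GT_PAIR_INDEX = {pair: k for k, pair in enumerate(_GT_TABLE)}


def gt21_index(sym_a: str, sym_b: str) -> int:
    order = {s: i for i, s in enumerate(GT_SYMBOLS)}
    pair = tuple(sorted((sym_a, sym_b), key=order.__getitem__))
    return _GT_PAIR_INDEX[pair]


def _allele_symbol(allele: str, ref: str) -> str:
    if len(allele) > len(ref):
        return "Ins"
    if len(allele) < len(ref):
        return "Del"
    return allele[0]


def _length_index(delta: int, flank: int) -> int:
    return int(np.clip(delta, -flank, flank)) + flank


def hom_ref_label(ref_base: str, flank: int = DEFAULT_FLANK) -> VariantLabel:
    base = ref_base if ref_base in BASE_INDEX else "A"
    return VariantLabel(
        gt21=gt21_index(base, base),
        zygosity=0,
        len1=_length_index(0, flank),
        len2=_length_index(0, flank),
    )


def label_site(
    site: CandidateSite,
    truth_record: TruthVariant | None,
    flank: int = DEFAULT_FLANK,
) -> VariantLabel:
    """Encode the truth record at ``site`` into the four classification targets.

    No record (or an unusable one) yields the homozygous-reference label.
    """
    if truth_record is None:
        return hom_ref_label(site.ref_base, flank)
    alleles = [truth_record.allele_seq(i) for i in truth_record.genotype]
    for a in alleles + [truth_record.ref]:
        if not a or any(c not in BASE_INDEX for c in a):
            warnings.warn(
                f"truth record at {truth_record.contig}:{truth_record.pos + 1} has "
                f"non-ACGT allele {a!r}; labelling as hom-ref"
            )
            return hom_ref_label(site.ref_base, flank)
    ref = truth_record.ref
    if any(len(a) == len(ref) and len(a) > 1 and a != ref for a in alleles):
        warnings.warn(
            f"multi-nucleotide allele at {truth_record.contig}:{truth_record.pos + 1} "
            "not supported; labelling as hom-ref"
        )
        return hom_ref_label(site.ref_base, flank)

    symbols = [_allele_symbol(a, ref) for a in alleles]
    non_ref = [a != ref for a in alleles]
    if not any(non_ref):
        zyg = 0
    elif all(non_ref) and alleles[0] == alleles[1]:
        zyg = 2
    else:
        zyg = 1
    deltas = sorted(len(a) - len(ref) for a in alleles)
    return VariantLabel(
        gt21=gt21_index(symbols[0], symbols[1]),
        zygosity=zyg,
        len1=_length_index(deltas[0], flank),
        len2=_length_index(deltas[1], flank),
    )


def read_truth_variants(truth_vcf, region: GenomeRegion | None = None) -> list[TruthVariant]:
    """Load truth records (optionally restricted to ``region``) as
    :class:`TruthVariant`, skipping records without a diploid genotype."""
    vf = truth_vcf if isinstance(truth_vcf, pysam.VariantFile) else pysam.VariantFile(str(truth_vcf))
    if region is not None:
        try:
            records = vf.fetch(region.contig, region.start, region.end)
        except ValueError:
            records = (r for r in vf.fetch() if r.contig == region.contig
                       and region.start <= r.start < region.end)
    else:
        records = vf.fetch()
    out = []
    for rec in records:
        if not rec.samples:
            continue
        gt = rec.samples[0].get("GT")
        if gt is None or len(gt) != 2 or any(g is None for g in gt):
            continue
        out.append(
            TruthVariant(
                contig=rec.contig,
                pos=rec.start,
                ref=rec.ref.upper(),
                alts=tuple((a or "").upper() for a in (rec.alts or ())),
                genotype=(int(gt[0]), int(gt[1])),
            )
        )
    return out


# ---------------------------------------------------------------------------
# training pairs


def make_training_pairs(
    low_alignment,
    high_alignment,
    truth_vcf,
    region: GenomeRegion,
    reference,
    min_af: float = DEFAULT_MIN_AF,
    min_depth: int = DEFAULT_MIN_DEPTH,
    flank: int = DEFAULT_FLANK,
) -> list[TrainingExample]:
    """Paired (low image, high image, label) examples for the union of
    low-depth candidate sites and truth variant sites in ``region``."""
    low = _open_bam(low_alignment)
    high = _open_bam(high_alignment)
    ref = _open_fasta(reference)
    _check_region(region, ref)
    refseq = ref.fetch(region.contig, region.start, region.end).upper()

    candidates = {
        s.pos: s for s in scan_candidates(low, region, ref, min_af=min_af, min_depth=min_depth)
    }
    truth = {t.pos: t for t in read_truth_variants(truth_vcf, region)}

    depth_arr, alt_arr = None, None
    examples: list[TrainingExample] = []
    for pos in sorted(set(candidates) | set(truth)):
        site = candidates.get(pos)
        if site is None:
            if depth_arr is None:
                depth_arr, alt_arr = _scan_arrays(low, region, refseq)
            i = pos - region.start
            site = CandidateSite(
                contig=region.contig,
                pos=pos,
                ref_base=refseq[i],
                depth=int(depth_arr[i]),
                alt_support=int(alt_arr[i]),
            )
        low_img = flatten_tensor(build_pileup_tensor(low, site, ref, flank), "observed_low")
        high_img = flatten_tensor(build_pileup_tensor(high, site, ref, flank), "observed_high")
        if not high_img.data.any():
            logger.warning(
                "truth site %s:%d has zero coverage in the high-depth alignment",
                region.contig,
                pos + 1,
            )
        label = label_site(site, truth.get(pos), flank)
        examples.append(TrainingExample(low_img, high_img, label, site))
    return examples
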