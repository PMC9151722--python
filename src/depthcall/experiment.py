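"""Desk-scale low-depth recovery experiment.

Simulates a diploid sample, thins the alignment to low depth, trains
the full projection pipeline and a caller-only baseline under identical
budgets, and compares their SNP F1 on a held-out region of the
low-depth alignment. This is the package's qualitative reproduction of
the claim that depth projection plus adversarial training helps at low
depth — scaled to a single CPU.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as onp

from . import dataset as dataset_io
from . import decode, metrics, simulate, train
from .pileup import (
    GenomeRegion,
    TrainingExample,
    build_pileup_tensor,
    flatten_tensor,
    label_site,
    read_truth_variants,
    scan_candidates,
)

logger = logging.getLogger(__name__)


@dataclass
class RecoveryConfig:
    genome_length: int = 100_000
    snp_rate: float = 1e-3
    indel_rate: float = 2e-4
    error_mismatch: float = 0.05
    error_insertion: float = 0.03
    error_deletion: float = 0.03
    high_depth: float = 30.0
    downsample_rate: float = 1.0 / 3.0
    holdout_length: int = 20_000
    edge: int = 300
    # training budget (desk scale, single CPU). The hom-ref candidate cap
    # and variant oversampling keep one full-pipeline training run inside
    # a few minutes; both arms always share the exact same budget.
    max_hom_ref_examples: int = 700
    variant_oversample: int = 4
    learning_rate: float = 5e-3
    batch_size: int = 32
    epochs: int = 8
    augment: bool = True
    seed: int = 0


@dataclass
class RecoveryResult:
    full_snp_f1: float
    baseline_snp_f1: float
    full_counts: metrics.ConfusionCounts = None
    baseline_counts: metrics.ConfusionCounts = None
    n_train_examples: int = 0

    @property
    def generator_helps(self) -> bool:
        return self.full_snp_f1 > self.baseline_snp_f1


def _capped_training_pairs(low_bam, high_bam, truth_vcf, region, fasta, cap, seed, flank=16):
    """Training pairs with the hom-ref candidates subsampled to ``cap``
    before featurization (error-driven candidates dominate at low depth)."""
    candidates = scan_candidates(low_bam, region, fasta)
    truth = {t.pos: t for t in read_truth_variants(truth_vcf, region)}
    hom_ref_sites = [s for s in candidates if s.pos not in truth]
    rng = onp.random.default_rng(seed)
    if len(hom_ref_sites) > cap:
        idx = sorted(rng.choice(len(hom_ref_sites), size=cap, replace=False))
        hom_ref_sites = [hom_ref_sites[i] for i in idx]
    by_pos = {s.pos: s for s in candidates}
    keep = {s.pos for s in hom_ref_sites} | set(truth)
    examples = []
    for pos in sorted(keep):
        site = by_pos.get(pos)
        if site is None:  # truth site below the candidate thresholds
            from .pileup import CandidateSite

            site = CandidateSite(region.contig, pos, truth[pos].ref[0], 1, 0)
        low_img = flatten_tensor(build_pileup_tensor(low_bam, site, fasta, flank), "observed_low")
        high_img = flatten_tensor(build_pileup_tensor(high_bam, site, fasta, flank), "observed_high")
        examples.append(TrainingExample(low_img, high_img, label_site(site, truth.get(pos), flank), site))
    return examples


def _snp_f1(calls, truth_vcf, region, fasta, workdir, tag):
    import pysam

    with pysam.FastaFile(str(fasta)) as ref:
        contigs = [(n, ref.get_reference_length(n)) for n in ref.references]
    called_vcf = os.path.join(workdir, f"calls_{tag}.vcf")
    decode.write_vcf(calls, contigs, called_vcf)
    bed = os.path.join(workdir, f"holdout_{tag}.bed")
    with open(bed, "w") as fh:
        fh.write(f"{region.contig}\t{region.start}\t{region.end}\n")
    counts = metrics.match_calls(called_vcf, truth_vcf, bed, variant_type="snp")
    return metrics.compute_metrics(counts).f1, counts


def run_recovery(cfg: RecoveryConfig, workdir) -> RecoveryResult:
    """One seed of the full-vs-baseline comparison."""
    workdir = str(workdir)
    os.makedirs(workdir, exist_ok=True)
    sim_cfg = simulate.SimConfig(
        genome_length=cfg.genome_length,
        snp_rate=cfg.snp_rate,
        indel_rate=cfg.indel_rate,
        error_mismatch=cfg.error_mismatch,
        error_insertion=cfg.error_insertion,
        error_deletion=cfg.error_deletion,
        depth=cfg.high_depth,
        seed=cfg.seed,
    )
    sim = simulate.simulate_run(sim_cfg, workdir)
    low_bam = simulate.downsample(
        sim["bam"], cfg.downsample_rate, cfg.seed + 1, os.path.join(workdir, "low.bam")
    )

    holdout_start = cfg.genome_length - cfg.holdout_length
    train_region = GenomeRegion(sim_cfg.contig_name, cfg.edge, holdout_start)
    holdout_region = GenomeRegion(
        sim_cfg.contig_name, holdout_start, cfg.genome_length - cfg.edge
    )

    examples = _capped_training_pairs(
        low_bam, sim["bam"], sim["vcf"], train_region, sim["fasta"],
        cap=cfg.max_hom_ref_examples, seed=cfg.seed + 2,
    )
    variant = [e for e in examples if e.label.zygosity > 0]
    hom_ref = [e for e in examples if e.label.zygosity == 0]
    arrays = dataset_io.examples_to_arrays(hom_ref + variant * cfg.variant_oversample)
    logger.info(
        "seed %d: %d training examples (%d variant, oversampled x%d)",
        cfg.seed, len(examples), len(variant), cfg.variant_oversample,
    )

    results = {}
    for tag, caller_only in (("full", False), ("baseline", True)):
        tc = train.TrainConfig(
            learning_rate=cfg.learning_rate,
            batch_size=cfg.batch_size,
            epochs=cfg.epochs,
            seed=cfg.seed,
            adversarial=not caller_only,
            caller_only=caller_only,
            augment=cfg.augment,
        )
        fitted = train.fit(arrays, config=tc, init_seed=cfg.seed)
        calls = decode.call_region(
            None if caller_only else fitted.g_params,
            fitted.c_params,
            low_bam,
            sim["fasta"],
            holdout_region,
            use_generator=not caller_only,
        )
        f1, counts = _snp_f1(calls, sim["vcf"], holdout_region, sim["fasta"], workdir, tag)
        results[tag] = (f1, counts)
        logger.info("seed %d %s: SNP F1 %.4f %s", cfg.seed, tag, f1, counts)

    return RecoveryResult(
        full_snp_f1=results["full"][0],
        baseline_snp_f1=results["baseline"][0],
        full_counts=results["full"][1],
        baseline_counts=results["baseline"][1],
        n_train_examples=len(examples),
    )


def run_recovery_seeds(base_cfg: RecoveryConfig, workdir, seeds=(0, 1, 2)):
    """The multi-seed comparison; returns per-seed results and the number
    of seeds in which the full pipeline beat the baseline."""
    results = []
    for seed in seeds:
        cfg = RecoveryConfig(**{**base_cfg.__dict__, "seed": seed})
        results.append(run_recovery(cfg, os.path.join(str(workdir), f"seed{seed}")))
    wins = sum(r.generator_helps for r in results)
    return results, wins
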