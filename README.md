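# depthcall

Variant calling from **low-depth** long-read (ONT-style) alignments with a
depth-projection generative network.

A candidate site's local read stack is summarised into a 33×8×4 counting
tensor (window position × stranded read base × {ref-match, insertion,
deletion, alternative}) and flattened to a 33×32 image. A U-Net-style
generator **G** projects the low-depth image to a predicted high-depth image;
a conditional discriminator **D** provides an adversarial signal during
training; a two-layer BiLSTM caller **C** consumes the (projected, observed)
image pair and predicts four variant attributes — 21 genotype-pair classes,
3 zygosity classes, and two 33-way allele-length-change classes — which are
decoded into VCF records. Training alternates two Adam optimizers: G and C
are updated jointly under `λ1·MSE + λ2·(focal losses) + λ3·(−log D(G(I),I))`,
then D under the usual binary adversarial loss.

The package is fully self-contained for testing: a diploid read simulator
plants SNPs/indels into a random reference, emits noisy reads with their
true CIGARs, and supports seeded read-level down-sampling, so paired
low/high-depth labelled pileups can be generated on demand.

Networks run on plain NumPy via [autograd], with custom fast primitives
(im2col convolution, hand-written LSTM backprop) — no GPU or deep-learning
framework required.

## Layout

| module | contents |
|---|---|
| `depthcall.pileup` | candidate scanning, pileup tensors/images, labels, training pairs |
| `depthcall.nnops` / `depthcall.models` | differentiable primitives; G, D, C definitions + checkpoints |
| `depthcall.train` | focal/MSE/adversarial losses, Adam, alternating `train_step`, `fit`, augmentation |
| `depthcall.decode` | attribute-probability → variant-call decoding, VCF writing |
| `depthcall.simulate` | diploid genome + read simulator, down-sampling |
| `depthcall.metrics` | genotype-aware VCF matching, precision/recall/F1 |
| `depthcall.experiment` | desk-scale full-vs-baseline low-depth recovery comparison |
| `depthcall.cli` | `depthcall` command-line app |

## CLI

```bash
depthcall simulate --outdir sim --genome-length 100000 --depth 30 --seed 1
depthcall downsample --bam sim/reads.bam --rate 0.33 --seed 2 --out sim/low.bam
depthcall make-dataset --low-bam sim/low.bam --high-bam sim/reads.bam \
    --truth-vcf sim/truth.vcf --fasta sim/ref.fa --region sim1:300-80000 --out sim/ds
depthcall train --dataset sim/ds --outdir sim/ckpt --profile desk --seed 1
depthcall call --checkpoint-dir sim/ckpt --bam sim/low.bam --fasta sim/ref.fa \
    --region sim1:80000-99700 --out sim/calls.vcf
depthcall evaluate --called sim/calls.vcf --truth sim/truth.vcf --bed sim/confident.bed
depthcall evaluate --counts 2815372,140722,187362   # table arithmetic
```

Training profiles: `--profile paper` (batch 5000, 30 epochs, lr 3e-4 —
documents the full-fidelity configuration) and `--profile desk` (batch 256,
5 epochs — CI-sized). Ablation switches: `--no-adversarial` (G+C without D)
and `--caller-only` (the baseline caller on low-depth images alone).

Exit codes: 0 ok, 2 configuration error, 3 data error.

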