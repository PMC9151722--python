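"""Dataset archive: training pairs as arrays + a JSON sidecar."""

from __future__ import annotations

import json
import os

import numpy as onp

from .pileup import CandidateSite, PileupImage, TrainingExample, VariantLabel


def examples_to_arrays(examples: list[TrainingExample]) -> dict:
    if not examples:
        width = 33
        return {
            "low": onp.zeros((0, width, 32), dtype=onp.float32),
            "high": onp.zeros((0, width, 32), dtype=onp.float32),
            "labels": onp.zeros((0, 4), dtype=onp.int64),
        }
    return {
        "low": onp.stack([e.low_image.data for e in examples]).astype(onp.float32),
        "high": onp.stack([e.high_image.data for e in examples]).astype(onp.float32),
        "labels": onp.asarray([e.label.as_tuple() for e in examples], dtype=onp.int64),
    }


def save_dataset(path, examples: list[TrainingExample], flank: int = 16) -> str:
    """Write arrays to ``<path>.npz`` plus a ``<path>.json`` sidecar with
    the flank, channel order and site list."""
    path = str(path)
    arrays = examples_to_arrays(examples)
    onp.savez(path + ".npz", **arrays)
    sidecar = {
        "flank": flank,
        "n_examples": len(examples),
        "channel_order": ["ref", "ins", "del", "alt"],
        "base_order": ["A", "C", "G", "T", "A-", "C-", "G-", "T-"],
        "flatten_rule": "column = 4*base_row + channel",
        "sites": [
            {
                "contig": e.site.contig,
                "pos": e.site.pos,
                "ref_base": e.site.ref_base,
                "depth": e.site.depth,
                "alt_support": e.site.alt_support,
            }
            for e in examples
        ],
    }
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh)
    return path


def load_dataset(path) -> tuple[dict, dict]:
    path = str(path)
    with onp.load(path + ".npz") as data:
        arrays = {k: data[k] for k in data.files}
    with open(path + ".json") as fh:
        sidecar = json.load(fh)
    return arrays, sidecar


def load_examples(path) -> list[TrainingExample]:
    arrays, sidecar = load_dataset(path)
    out = []
    for i, meta in enumerate(sidecar["sites"]):
        site = CandidateSite(**meta)
        label = VariantLabel(*(int(v) for v in arrays["labels"][i]))
        out.append(
            TrainingExample(
                low_image=PileupImage(arrays["low"][i], "observed_low"),
                high_image=PileupImage(arrays["high"][i], "observed_high"),
                label=label,
                site=site,
            )
        )
    return out
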