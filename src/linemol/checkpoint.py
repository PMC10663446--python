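"""Versioned model checkpoints.

A checkpoint is a directory:

    meta.json        format version, head layout
    config.json      LiGhTConfig fields
    params.npz       every parameter array, keyed by its documented name
                     (encoder names like ``layer3.Wq``; head parameters are
                     namespaced by the head's own name, e.g. ``desc_head.W1``)
    normalizer.json  descriptor normalizer (locations, scales, names, clip)
    vocab.json       node-type vocabulary (pre-training checkpoints)

The same format is read by pre-training, finetuning and feature extraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .knowledge import DescriptorNormalizer
from .light import LiGhTConfig, LiGhTModel, PredictionHead
from .nn import Tensor

__all__ = ["Checkpoint", "save_checkpoint", "load_checkpoint"]

FORMAT_VERSION = 1


@dataclass
class Checkpoint:
    model: LiGhTModel
    normalizer: DescriptorNormalizer | None
    vocab_dict: dict | None
    heads: dict[str, PredictionHead]
    meta: dict

    def vocab(self):
        from .pretrain import NodeTypeVocab

        return None if self.vocab_dict is None else NodeTypeVocab.from_dict(self.vocab_dict)


def save_checkpoint(path, model: LiGhTModel,
                    normalizer: DescriptorNormalizer | None = None,
                    vocab=None,
                    heads: dict[str, PredictionHead] | None = None,
                    extra_meta: dict | None = None) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    heads = heads or {}
    meta = {
        "format_version": FORMAT_VERSION,
        "heads": {
            key: {"name": h.name, "in_dim": h.in_dim, "n_tasks": h.n_tasks,
                  "hidden": h.hidden}
            for key, h in heads.items()
        },
        **(extra_meta or {}),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    (path / "config.json").write_text(json.dumps(model.config.to_dict(), indent=1))
    arrays = {name: t.data for name, t in model.params.items()}
    for h in heads.values():
        arrays.update({name: t.data for name, t in h.params.items()})
    np.savez(path / "params.npz", **arrays)
    if normalizer is not None:
        (path / "normalizer.json").write_text(normalizer.to_json())
    if vocab is not None:
        vd = vocab if isinstance(vocab, dict) else vocab.to_dict()
        (path / "vocab.json").write_text(json.dumps(vd))
    return path


def load_checkpoint(path) -> Checkpoint:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    if meta.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"unsupported checkpoint format: {meta.get('format_version')}")
    config = LiGhTConfig.from_dict(json.loads((path / "config.json").read_text()))
    with np.load(path / "params.npz") as npz:
        arrays = {k: npz[k] for k in npz.files}

    heads: dict[str, PredictionHead] = {}
    head_param_names = set()
    for key, spec in meta.get("heads", {}).items():
        head = PredictionHead(spec["in_dim"], spec["n_tasks"], hidden=spec["hidden"],
                              name=spec["name"])
        for pname in head.params:
            head.params[pname] = Tensor(arrays[pname].copy(), requires_grad=True)
            head_param_names.add(pname)
        heads[key] = head

    params = {name: Tensor(arr.copy(), requires_grad=True)
              for name, arr in arrays.items() if name not in head_param_names}
    model = LiGhTModel(config, params)

    normalizer = None
    if (path / "normalizer.json").exists():
        normalizer = DescriptorNormalizer.from_json((path / "normalizer.json").read_text())
    vocab_dict = None
    if (path / "vocab.json").exists():
        vocab_dict = json.loads((path / "vocab.json").read_text())
    return Checkpoint(model, normalizer, vocab_dict, heads, meta)
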