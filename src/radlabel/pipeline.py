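"""Batch label assignment and workflow plumbing shared by the CLI.

Once the eight per-category classifiers are trained, their weights are
fixed and they run in inference mode over an arbitrarily large corpus,
emitting one row of probabilities and thresholded calls per report with
bounded memory (the corpus is streamed in chunks).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict

import numpy as np
import pandas as pd

from .corpus import ALL_LABELS

__all__ = ["model_version", "assign_labels", "provenance"]


def model_version(model):
    """Short content hash of a model's configuration and parameters."""
    h = hashlib.sha256()
    h.update(json.dumps(asdict(model.config), sort_keys=True).encode())
    for p in model.params():
        h.update(np.ascontiguousarray(p.value).tobytes())
    return h.hexdigest()[:12]


def assign_labels(frame, models, threshold=0.5, chunk_size=256):
    """Per-report probabilities and binary calls for all eight categories.

    ``models`` maps every label name (abnormal + 7 granular) to a trained
    classifier exposing ``predict_proba``. Deterministic; memory bounded
    in the corpus size via chunked inference.
    """
    missing = [c for c in ALL_LABELS if c not in models]
    if missing:
        raise ValueError(f"missing model for categories: {missing}")
    versions = {c: model_version(models[c]) for c in ALL_LABELS}
    chunks = []
    for start in range(0, len(frame), chunk_size):
        part = frame.iloc[start:start + chunk_size]
        out = {"report_id": part["report_id"].to_numpy()}
        texts = part["text"].tolist()
        for cat in ALL_LABELS:
            probs = models[cat].predict_proba(texts)
            out[f"{cat}_prob"] = probs
            out[f"{cat}_call"] = (probs >= threshold).astype(int)
        chunks.append(pd.DataFrame(out))
    if not chunks:
        result = pd.DataFrame(columns=["report_id"] + [
            f"{c}_{s}" for c in ALL_LABELS for s in ("prob", "call")])
    else:
        result = pd.concat(chunks, ignore_index=True)
    result.attrs["model_versions"] = versions
    result.attrs["threshold"] = threshold
    return result


def provenance(config_obj, seed):
    """Provenance header written next to every CLI output."""
    from . import __version__

    blob = json.dumps(config_obj, sort_keys=True, default=str)
    return {
        "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
        "config": config_obj,
        "seed": seed,
        "package_version": __version__,
    }
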