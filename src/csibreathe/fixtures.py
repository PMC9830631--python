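"""Deterministic mini-assets for tests and demos.

Everything is generated at call time from a seed; nothing is bundled.
"""

from __future__ import annotations

import json
import os

from .channel import ChannelConfig, NoiseConfig, simulate_csi
from .experiments import ExperimentSpec, build_study_dataset
from .io import write_container
from .patterns import PATTERN_TABLE

__all__ = ["generate_fixtures", "TOY_CONFUSION"]

#: Toy confusion matrix (rows = predicted) shared across evaluation examples.
TOY_CONFUSION = [[3, 1], [0, 2]]

#: The two most contrasting reference motions: slow/deep vs fast/shallow-ish.
FIXTURE_PATTERN_IDS = (2, 4)


def generate_fixtures(seed: int, out_dir: str) -> dict:
    """Write small deterministic assets; returns a name -> path mapping.

    Contents: one raw CSI tensor per fixture pattern (8 subcarriers, 15 s),
    a labeled two-class feature dataset (20 streams per class), and the toy
    confusion matrix as JSON. Same seed, same bytes of payload data.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    cfg = ChannelConfig(n_subcarriers=8, n_tx=1, n_rx=2, duration_s=15.0)
    for pid in FIXTURE_PATTERN_IDS:
        tensor = simulate_csi(PATTERN_TABLE[pid], cfg, NoiseConfig(seed=seed + pid))
        p = os.path.join(out_dir, f"csi_pattern{pid}.h5")
        write_container(tensor, p)
        paths[f"csi_pattern{pid}"] = p

    spec = ExperimentSpec(task="pattern-9", n_subcarriers=8, n_tx=1, n_rx=2,
                          duration_s=15.0, seed=seed, scale=1.0)
    ds = _two_class_dataset(spec, n_per_class=20)
    p = os.path.join(out_dir, "mini_dataset.h5")
    write_container(ds, p)
    paths["mini_dataset"] = p

    p = os.path.join(out_dir, "toy_confusion.json")
    with open(p, "w") as fh:
        json.dump({"counts": TOY_CONFUSION, "convention": "rows=predicted, columns=true"}, fh)
    paths["toy_confusion"] = p
    return paths


def _two_class_dataset(spec: ExperimentSpec, n_per_class: int = 20):
    """Two-pattern feature dataset at fixture scale."""
    import numpy as np

    from .preprocess import FeatureDataset, build_dataset

    cfg = ChannelConfig(n_subcarriers=spec.n_subcarriers, n_tx=spec.n_tx, n_rx=spec.n_rx,
                        duration_s=spec.duration_s, frame_rate_hz=spec.frame_rate_hz)
    tensors, labels = [], []
    per_tensor = cfg.n_streams
    for pid in FIXTURE_PATTERN_IDS:
        need = n_per_class
        rep = 0
        while need > 0:
            tensors.append(simulate_csi(PATTERN_TABLE[pid], cfg,
                                        NoiseConfig(seed=spec.seed * 1000 + pid * 10 + rep)))
            labels.append(pid)
            need -= per_tensor
            rep += 1
    ds = build_dataset(tensors, spec.feature_mode, spec.band_hz, labels=labels,
                       label_names={pid: f"pattern-{pid}" for pid in FIXTURE_PATTERN_IDS})
    keep = np.concatenate([np.flatnonzero(ds.y == pid)[:n_per_class]
                           for pid in FIXTURE_PATTERN_IDS])
    keep.sort()
    return FeatureDataset(X=ds.X[keep], y=ds.y[keep], label_names=ds.label_names,
                          stream_indices=ds.stream_indices[keep], meta=ds.meta)
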