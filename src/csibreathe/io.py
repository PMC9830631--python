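"""Container format for CSI tensors, feature datasets and model checkpoints.

One HDF5 file per artifact with an embedded structured header (root
attributes): format version, artifact kind, shapes, radio plan, labels and
seeds. Complex CSI data is stored as paired real/imaginary float arrays for
portability. Round trips are lossless: ``read_container(write_container(x))``
reproduces values bit-exactly and metadata field-for-field.

Unit sheet (all artifacts): time in seconds, frequencies in Hz, angles in
radians, attenuation in dB, displacement in mm.
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile

import h5py
import numpy as np

from .channel import ChannelConfig, CSITensor
from .classifier import BiLSTMClassifier
from .patterns import BreathingPattern
from .preprocess import FeatureDataset

__all__ = [
    "FORMAT_VERSION",
    "ContainerError",
    "ContainerFormatError",
    "ContainerVersionError",
    "write_container",
    "read_container",
]

FORMAT_VERSION = 1


class ContainerError(Exception):
    """Base class for container format failures."""


class ContainerFormatError(ContainerError):
    """Malformed or truncated container payload/header."""


class ContainerVersionError(ContainerError):
    """Container written with an unsupported format version."""


def _atomic_h5(path):
    """Write to a temp file in the target directory, then rename."""
    d = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(suffix=".h5.tmp", dir=d)
    os.close(fd)
    return tmp


def _json_attr(obj) -> str:
    return json.dumps(obj, sort_keys=True)


def _write_csi(f: h5py.File, tensor: CSITensor):
    f.attrs["kind"] = "csi_tensor"
    g = f.create_group("csi")
    g.create_dataset("real", data=tensor.values.real)
    g.create_dataset("imag", data=tensor.values.imag)
    f.attrs["channel"] = _json_attr(dataclasses.asdict(tensor.channel))
    f.attrs["shape"] = tensor.values.shape
    if tensor.pattern is not None:
        f.attrs["pattern"] = _json_attr(dataclasses.asdict(tensor.pattern))
    if tensor.seed is not None:
        f.attrs["seed"] = int(tensor.seed)
    f.attrs["meta"] = _json_attr(tensor.meta)


def _read_csi(f: h5py.File) -> CSITensor:
    try:
        values = f["csi/real"][...] + 1j * f["csi/imag"][...]
    except KeyError as e:
        raise ContainerFormatError(f"missing CSI payload: {e}") from e
    if tuple(f.attrs["shape"]) != values.shape:
        raise ContainerFormatError(
            f"header shape {tuple(f.attrs['shape'])} does not match payload {values.shape}")
    channel = ChannelConfig(**json.loads(f.attrs["channel"]))
    pattern = None
    if "pattern" in f.attrs:
        pd = json.loads(f.attrs["pattern"])
        pd["harmonic_weights"] = tuple(pd["harmonic_weights"])
        pattern = BreathingPattern(**pd)
    seed = int(f.attrs["seed"]) if "seed" in f.attrs else None
    meta = json.loads(f.attrs["meta"]) if "meta" in f.attrs else {}
    return CSITensor(values=values, channel=channel, pattern=pattern, seed=seed, meta=meta)


def _write_dataset(f: h5py.File, ds: FeatureDataset):
    f.attrs["kind"] = "feature_dataset"
    g = f.create_group("dataset")
    g.create_dataset("X", data=ds.X)
    g.create_dataset("y", data=ds.y)
    if ds.stream_indices is not None:
        g.create_dataset("stream_indices", data=ds.stream_indices)
    f.attrs["label_names"] = _json_attr({str(k): v for k, v in ds.label_names.items()})
    f.attrs["meta"] = _json_attr(ds.meta)


def _read_dataset(f: h5py.File) -> FeatureDataset:
    try:
        X = f["dataset/X"][...]
        y = f["dataset/y"][...]
    except KeyError as e:
        raise ContainerFormatError(f"missing dataset payload: {e}") from e
    si = f["dataset/stream_indices"][...] if "dataset/stream_indices" in f else None
    label_names = {int(k): v for k, v in json.loads(f.attrs["label_names"]).items()}
    meta = json.loads(f.attrs["meta"]) if "meta" in f.attrs else {}
    return FeatureDataset(X=X, y=y, label_names=label_names, stream_indices=si, meta=meta)


def _write_model(f: h5py.File, model: BiLSTMClassifier):
    model._check_fitted()
    f.attrs["kind"] = "model"
    g = f.create_group("params")
    for k, v in model.params_.items():
        g.create_dataset(k, data=v)
    f.create_dataset("classes", data=np.asarray(model.classes_))
    f.attrs["config"] = _json_attr(dataclasses.asdict(model.config))
    f.attrs["loss_curve"] = np.asarray(model.loss_curve_)
    f.attrs["n_timesteps"] = int(model.n_timesteps_)
    f.attrs["n_channels"] = int(model.n_features_in_)


def _read_model(f: h5py.File) -> BiLSTMClassifier:
    cfg = json.loads(f.attrs["config"])
    clf = BiLSTMClassifier(
        hidden_units=cfg["hidden_units"], learning_rate=cfg["learning_rate"],
        batch_size=cfg["batch_size"], max_epochs=cfg["max_epochs"],
        patience=cfg["patience"], tol=cfg["tol"], random_state=cfg["seed"])
    try:
        clf.params_ = {k: f["params"][k][...] for k in f["params"]}
        clf.classes_ = f["classes"][...]
    except KeyError as e:
        raise ContainerFormatError(f"missing model payload: {e}") from e
    clf.loss_curve_ = list(f.attrs["loss_curve"])
    clf.n_timesteps_ = int(f.attrs["n_timesteps"])
    clf.n_features_in_ = int(f.attrs["n_channels"])
    return clf


_WRITERS = [
    (CSITensor, _write_csi),
    (FeatureDataset, _write_dataset),
    (BiLSTMClassifier, _write_model),
]
_READERS = {"csi_tensor": _read_csi, "feature_dataset": _read_dataset, "model": _read_model}


def write_container(obj, path) -> str:
    """Serialize a CSITensor, FeatureDataset or fitted BiLSTMClassifier.

    The file is written atomically (temp file + rename). Returns the path.
    """
    writer = next((w for t, w in _WRITERS if isinstance(obj, t)), None)
    if writer is None:
        raise TypeError(f"cannot serialize object of type {type(obj).__name__}")
    tmp = _atomic_h5(path)
    try:
        with h5py.File(tmp, "w") as f:
            f.attrs["format_version"] = FORMAT_VERSION
            writer(f, obj)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.remove(tmp)
    return str(path)


def read_container(path):
    """Read any container written by :func:`write_container`.

    Raises ContainerVersionError on version mismatch and
    ContainerFormatError on truncated or malformed files.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        f = h5py.File(path, "r")
    except OSError as e:
        raise ContainerFormatError(f"not a readable container: {e}") from e
    with f:
        version = f.attrs.get("format_version")
        if version is None:
            raise ContainerFormatError("missing format_version header")
        if int(version) != FORMAT_VERSION:
            raise ContainerVersionError(
                f"container version {version} not supported (expected {FORMAT_VERSION})")
        kind = f.attrs.get("kind")
        if kind not in _READERS:
            raise ContainerFormatError(f"unknown artifact kind {kind!r}")
        return _READERS[kind](f)
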