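"""Characterization campaigns on simulated CSI data.

Dataset recipes for the four classification tasks:

``pattern-9``
    The nine reference patterns, 336 streams each at full scale (3024).
``normal-vs-abnormal``
    The eight abnormal patterns pooled (2688 streams) against an equal
    number of normal-breathing streams (336 + 2352 extra acquisitions),
    5376 streams total, exactly class-balanced.
``rate-28``
    Normal-shaped breathing at every integer rate 3..30 BPM, 336 streams
    per rate (9408 total).
``rate-3-band``
    The same streams relabeled into clinical bands: bradypnea (<= 11 BPM),
    eupnea (12-20), tachypnea (>= 21).

plus cross-validated sweeps over added attenuation, acquisition length and
Wi-Fi frame rate, and a pooled mixed-attenuation robustness study. A
scale-down factor shrinks streams-per-class and the subcarrier count
proportionally for desk-scale runs.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .channel import ChannelConfig, NoiseConfig, simulate_csi, CSITensor
from .classifier import BiLSTMClassifier
from .evaluation import kfold_cross_validate, CrossValidationResult
from .patterns import PATTERN_TABLE, NORMAL_PATTERN_ID, normal_pattern_at
from .preprocess import (BREATHING_BAND_HZ, FeatureDataset, SequenceStandardizer,
                         build_dataset, stream_features)

__all__ = [
    "TASKS",
    "ExperimentSpec",
    "build_study_dataset",
    "make_trainer",
    "run_cv",
    "run_holdout",
    "run_sweep",
    "mixed_attenuation_study",
]

TASKS = ("pattern-9", "normal-vs-abnormal", "rate-28", "rate-3-band")

#: full-scale streams per class, per task
_FULL_STREAMS = {"pattern-9": 336, "normal-vs-abnormal": 2688,
                 "rate-28": 336, "rate-3-band": 336}


@dataclass(frozen=True)
class ExperimentSpec:
    """One characterization run: task, channel operating point, sweep plan."""

    task: str = "pattern-9"
    sweep_variable: str = "none"  # attenuation_db | duration_s | frame_rate_hz | none
    sweep_values: tuple = ()
    scale: float = 1.0
    n_subcarriers: int = 56
    n_tx: int = 2
    n_rx: int = 3
    attenuation_db: float = 0.0
    duration_s: float = 60.0
    frame_rate_hz: float = 10.0
    snr_db: float = 30.0
    feature_mode: str = "hybrid"
    band_hz: tuple = BREATHING_BAND_HZ
    cv_folds: int = 10
    seed: int = 0
    net: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if self.sweep_variable not in ("none", "attenuation_db", "duration_s", "frame_rate_hz"):
            raise ValueError(f"unknown sweep variable {self.sweep_variable!r}")
        if self.sweep_variable != "none" and len(self.sweep_values) == 0:
            raise ValueError("sweep_values must be non-empty for a sweep")
        if not 0 < self.scale <= 1:
            raise ValueError("scale must be in (0, 1]")

    @property
    def streams_per_class(self) -> int:
        return max(1, int(round(_FULL_STREAMS[self.task] * self.scale)))

    @classmethod
    def scaled(cls, task="pattern-9", **overrides):
        """Desk-scale operating point: 1/6 streams per class, 8 of 56
        subcarriers, 3-fold CV, shortened epoch budget."""
        kw = dict(task=task, scale=1.0 / 6.0, n_subcarriers=8, cv_folds=3,
                  net=dict(max_epochs=80, patience=20))
        kw.update(overrides)
        return cls(**kw)


def _max_class_freq_hz(task: str) -> float:
    if task in ("rate-28", "rate-3-band"):
        return 30.0 / 60.0
    return max(p.rate_bpm for p in PATTERN_TABLE.values()) / 60.0


def _class_patterns(task: str):
    """(label, pattern, label_name) triples for a task."""
    if task == "pattern-9":
        return [(pid, p, f"pattern-{pid}") for pid, p in PATTERN_TABLE.items()]
    if task == "rate-28":
        return [(bpm, normal_pattern_at(bpm), f"{bpm}-bpm") for bpm in range(3, 31)]
    if task == "rate-3-band":
        out = []
        for bpm in range(3, 31):
            band = 0 if bpm <= 11 else (1 if bpm <= 20 else 2)
            out.append((band, normal_pattern_at(bpm), ("bradypnea", "eupnea", "tachypnea")[band]))
        return out
    raise ValueError(task)


def _even_split(total: int, parts: int) -> list[int]:
    """Split a count into near-equal integer parts (first ones larger)."""
    base, extra = divmod(total, parts)
    return [base + (1 if i < extra else 0) for i in range(parts)]


def _seed_for(spec_seed, *keys) -> int:
    # process-independent key hashing (crc32, not Python hash())
    ints = [zlib.crc32(str(k).encode()) for k in keys]
    ss = np.random.SeedSequence([int(spec_seed)] + ints)
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _simulate_class(pattern, label, n_streams, cfg, snr_db, seeds):
    """Generate enough acquisitions of one motion to yield n_streams
    streams; deterministic truncation to the first n_streams."""
    per_tensor = cfg.n_streams
    tensors, labels = [], []
    need = n_streams
    rep = 0
    while need > 0:
        ncfg = NoiseConfig(snr_db=snr_db, seed=seeds(rep))
        tensors.append(simulate_csi(pattern, cfg, ncfg))
        labels.append(label)
        need -= per_tensor
        rep += 1
    return tensors, labels


def build_study_dataset(spec: ExperimentSpec, attenuation_db=None, duration_s=None,
                        frame_rate_hz=None) -> FeatureDataset:
    """Labeled feature dataset for a task at one channel operating point.

    Optional overrides support sweeps. Refuses frame rates below twice the
    highest class breathing frequency (aliasing guard).
    """
    att = spec.attenuation_db if attenuation_db is None else attenuation_db
    dur = spec.duration_s if duration_s is None else duration_s
    fr = spec.frame_rate_hz if frame_rate_hz is None else frame_rate_hz
    fmax = _max_class_freq_hz(spec.task)
    if fr < 2.0 * fmax:
        raise ValueError(
            f"frame rate {fr} Hz is below the Nyquist rate {2 * fmax:.2f} Hz "
            f"for the highest class breathing frequency {fmax:.2f} Hz")

    cfg = ChannelConfig(n_subcarriers=spec.n_subcarriers, n_tx=spec.n_tx, n_rx=spec.n_rx,
                        added_attenuation_db=att, frame_rate_hz=fr, duration_s=dur)
    n_per_class = spec.streams_per_class

    def entry_features(pattern, label, n_streams, key):
        """Features of exactly n_streams streams of one motion."""
        tns, labs = _simulate_class(
            pattern, label, n_streams, cfg, spec.snr_db,
            lambda rep: _seed_for(spec.seed, spec.task, key, rep, att, dur, fr))
        ds = build_dataset(tns, spec.feature_mode, spec.band_hz, labels=labs)
        return ds.X[:n_streams], ds.y[:n_streams], ds.stream_indices[:n_streams], ds.meta

    parts, names = [], {}
    if spec.task == "normal-vs-abnormal":
        # 8 abnormal patterns pooled vs an equal number of normal streams
        names = {0: "normal", 1: "abnormal"}
        per_abn = _even_split(n_per_class, 8)
        for take, (pid, p) in zip(per_abn, ((pid, p) for pid, p in PATTERN_TABLE.items()
                                            if pid != NORMAL_PATTERN_ID)):
            if take > 0:
                parts.append(entry_features(p, 1, take, pid))
        parts.append(entry_features(PATTERN_TABLE[NORMAL_PATTERN_ID], 0, n_per_class, "normal"))
    else:
        for label, pattern, name in _class_patterns(spec.task):
            names[label] = name
            # n_per_class is per generator class (per rate for the band task)
            parts.append(entry_features(pattern, label, n_per_class, (label, name)))

    meta = parts[0][3]
    return FeatureDataset(
        X=np.concatenate([p[0] for p in parts]),
        y=np.concatenate([p[1] for p in parts]),
        label_names=names,
        stream_indices=np.concatenate([p[2] for p in parts]),
        meta=meta)


class _StandardizedModel:
    """Standardizer + classifier pair fitted on a training fold."""

    def __init__(self, scaler, clf):
        self.scaler = scaler
        self.clf = clf

    def predict(self, X):
        return self.clf.predict(self.scaler.transform(X))

    def predict_proba(self, X):
        return self.clf.predict_proba(self.scaler.transform(X))


def make_trainer(net: dict | None = None, seed: int = 0):
    """Trainer callable for cross-validation: fits the per-channel
    standardizer on the training fold only, then the BiLSTM."""
    net = dict(net or {})
    net.setdefault("random_state", seed)

    def trainer(X, y):
        scaler = SequenceStandardizer().fit(X)
        clf = BiLSTMClassifier(**net).fit(scaler.transform(X), y)
        return _StandardizedModel(scaler, clf)

    return trainer


def run_cv(spec: ExperimentSpec, dataset: FeatureDataset | None = None,
           **overrides) -> CrossValidationResult:
    """Cross-validate the pipeline on one operating point."""
    ds = dataset if dataset is not None else build_study_dataset(spec, **overrides)
    trainer = make_trainer(spec.net, seed=spec.seed)
    return kfold_cross_validate(ds.X, ds.y, trainer, k=spec.cv_folds, seed=spec.seed)


def run_holdout(spec: ExperimentSpec, dataset: FeatureDataset | None = None,
                **overrides) -> tuple[float, int]:
    """Single stratified hold-out evaluation (first of cv_folds folds).

    A cheaper alternative to full cross-validation for large tasks;
    returns (accuracy, n_test).
    """
    from .evaluation import stratified_folds

    ds = dataset if dataset is not None else build_study_dataset(spec, **overrides)
    folds = stratified_folds(ds.y, spec.cv_folds, seed=spec.seed)
    test = folds[0]
    mask = np.ones(len(ds.y), dtype=bool)
    mask[test] = False
    model = make_trainer(spec.net, seed=spec.seed)(ds.X[mask], ds.y[mask])
    acc = float(np.mean(model.predict(ds.X[test]) == ds.y[test]))
    return acc, int(len(test))


def _row_from_result(value, res: CrossValidationResult) -> dict:
    rep = res.pooled_report
    return {
        "value": value,
        "accuracy": res.mean_accuracy,
        "accuracy_std": res.std_accuracy,
        "accuracy_min": res.min_accuracy,
        "accuracy_max": res.max_accuracy,
        "macro_precision": rep.macro_precision,
        "macro_recall": rep.macro_recall,
        "macro_specificity": rep.macro_specificity,
        "macro_f1": rep.macro_f1,
    }


def run_sweep(spec: ExperimentSpec, return_results=False, repeats: int = 1):
    """Cross-validated metrics per sweep value.

    One seeded run per cell by default; ``repeats > 1`` reruns each cell
    with consecutive seeds and reports the across-repeat mean accuracy and
    its spread alongside the first run's metrics. Returns a pandas
    DataFrame (one row per value, characterization-table column layout);
    with ``return_results=True`` also the per-value CrossValidationResult
    of the first repeat.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if spec.sweep_variable == "none":
        values = [None]
    else:
        values = list(spec.sweep_values)
    rows, results = [], {}
    for v in values:
        overrides = {} if v is None else {spec.sweep_variable: v}
        reps = []
        for r in range(repeats):
            spec_r = spec if r == 0 else dataclasses.replace(spec, seed=spec.seed + r)
            reps.append(run_cv(spec_r, **overrides))
        row = _row_from_result(v, reps[0])
        if repeats > 1:
            rep_accs = np.array([res.mean_accuracy for res in reps])
            row["accuracy_repeat_mean"] = float(rep_accs.mean())
            row["accuracy_repeat_std"] = float(rep_accs.std(ddof=1))
        rows.append(row)
        results[v] = reps[0]
    table = pd.DataFrame(rows)
    table.attrs["spec"] = dataclasses.asdict(spec)
    if return_results:
        return table, results
    return table


def mixed_attenuation_study(spec: ExperimentSpec, levels=(0.0, 10.0, 20.0, 30.0)) -> CrossValidationResult:
    """Pooled robustness study: each stream attenuated by a level drawn
    at random (seeded) from ``levels``, then cross-validated.

    Streams are generated clean and degraded individually: the stream is
    scaled by 10^(-att/20) and complex Gaussian noise at the fixed
    receiver floor is added, mirroring acquisitions taken at different
    distances pooled into one dataset.
    """
    levels = [float(v) for v in levels]
    if len(levels) < 2:
        raise ValueError("need at least 2 attenuation levels")
    cfg = ChannelConfig(n_subcarriers=spec.n_subcarriers, n_tx=spec.n_tx, n_rx=spec.n_rx,
                        added_attenuation_db=0.0, frame_rate_hz=spec.frame_rate_hz,
                        duration_s=spec.duration_s)
    fmax = _max_class_freq_hz(spec.task)
    if spec.frame_rate_hz < 2 * fmax:
        raise ValueError("frame rate below Nyquist for the task's breathing rates")

    rng = np.random.default_rng(_seed_for(spec.seed, "mixed-att", spec.task))
    feats, ys = [], []
    names = {}
    n_per_class = spec.streams_per_class
    for label, pattern, name in _class_patterns(spec.task):
        names[label] = name
        made = 0
        rep = 0
        while made < n_per_class:
            ncfg = NoiseConfig(noise_power=0.0,
                               seed=_seed_for(spec.seed, "mixed", spec.task, label, rep))
            clean = simulate_csi(pattern, cfg, ncfg)
            p_signal = float(np.mean(np.abs(clean.values) ** 2))
            noise_power = p_signal * 10.0 ** (-spec.snr_db / 10.0)
            for h in clean.streams():
                if made >= n_per_class:
                    break
                att = levels[rng.integers(len(levels))]
                hn = h * 10.0 ** (-att / 20.0)
                hn = hn + np.sqrt(noise_power / 2.0) * (
                    rng.standard_normal(h.shape) + 1j * rng.standard_normal(h.shape))
                feats.append(stream_features(hn, cfg.frame_rate_hz, spec.feature_mode, spec.band_hz))
                ys.append(label)
                made += 1
            rep += 1
    ds = FeatureDataset(X=np.stack(feats), y=np.asarray(ys, dtype=int), label_names=names,
                        meta=dict(mixed_attenuation_levels=levels))
    return run_cv(spec, dataset=ds)
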