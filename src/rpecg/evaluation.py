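"""Splitting, per-class metrics and experiment orchestration.

The evaluation protocol holds out a stratified 20% test set per class, then
partitions the remainder with a stratified 5-fold split: four fifths train,
one fifth validation, rotating. Stratification can operate at the recording
level (default — all segments of a recording travel together, preventing
same-recording leakage between splits) or at the segment level.

Metrics follow the usual per-class definitions: precision = TP/(TP+FP),
recall = TP/(TP+FN), F1 = 2PR/(P+R), with 0/0 cases defined as 0 (warned);
the macro scores are unweighted means over classes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classifier import ArchConfig, TrainConfig, build_network, train
from .preprocess import (AugmentationPolicy, SegmentDataset, build_dataset,
                         resample_record)
from .records import ClassLabelSet, ECGRecord
from .recurrence_imaging import RPParams, encode_segment


# ------------------------------------------------------------------ splits

@dataclass
class SplitPlan:
    """Hold-out test indices plus k rotated (train, val) folds."""

    test: List[int]
    folds: List[Tuple[List[int], List[int]]]
    stratify_level: str
    seed: int


def split_dataset(dataset: SegmentDataset, test_frac: float = 0.2,
                  n_folds: int = 5, seed: int = 0,
                  stratify_level: str = "recording") -> SplitPlan:
    """Stratified hold-out test selection + stratified k-fold on the rest.

    At recording level the stratification units are recordings and every
    unit's segments move together; at segment level units are segments.
    """
    if stratify_level not in ("recording", "segment"):
        raise ValueError("stratify_level must be 'recording' or 'segment'")
    labels = dataset.labels()
    rids = dataset.record_ids()

    if stratify_level == "recording":
        units: List[str] = []
        unit_label: Dict[str, str] = {}
        unit_segments: Dict[str, List[int]] = {}
        for i, (rid, lab) in enumerate(zip(rids, labels)):
            if rid not in unit_label:
                units.append(rid)
                unit_label[rid] = lab
                unit_segments[rid] = []
            unit_segments[rid].append(i)
        unit_labels = [unit_label[u] for u in units]
        expand = lambda us: [i for u in us for i in unit_segments[u]]  # noqa: E731
    else:
        units = list(range(len(dataset)))
        unit_labels = labels
        expand = lambda us: list(us)  # noqa: E731

    by_class: Dict[str, List] = {}
    for u, lab in zip(units, unit_labels):
        by_class.setdefault(lab, []).append(u)
    for cls, members in by_class.items():
        if len(members) < n_folds + 1:
            raise ValueError(
                f"class {cls!r} has only {len(members)} unit(s) at "
                f"{stratify_level} level; need at least {n_folds + 1}")

    rng = np.random.default_rng(seed)
    test_units, pool_units = [], []
    for cls in sorted(by_class):
        members = list(by_class[cls])
        order = rng.permutation(len(members))
        n_test = int(round(test_frac * len(members)))
        n_test = min(max(n_test, 1), len(members) - n_folds)
        chosen = [members[i] for i in order[:n_test]]
        test_units.extend(chosen)
        pool_units.extend(members[i] for i in order[n_test:])

    pool_labels = [unit_label[u] if stratify_level == "recording" else
                   labels[u] for u in pool_units]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=int(seed) % (2 ** 32))
    folds = []
    pool_arr = np.array(pool_units, dtype=object)
    for tr, va in skf.split(np.zeros(len(pool_units)), pool_labels):
        folds.append((sorted(expand(pool_arr[tr])),
                      sorted(expand(pool_arr[va]))))
    return SplitPlan(test=sorted(expand(test_units)), folds=folds,
                     stratify_level=stratify_level, seed=seed)


# ----------------------------------------------------------------- metrics

@dataclass
class MetricsReport:
    """Per-class counts and scores, macro averages, confusion matrix."""

    classes: ClassLabelSet
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    confusion: np.ndarray  # rows = true class, cols = predicted

    @property
    def macro_precision(self) -> float:
        return float(self.precision.mean())

    @property
    def macro_recall(self) -> float:
        return float(self.recall.mean())

    @property
    def macro_f1(self) -> float:
        return float(self.f1.mean())

    def rounded(self, digits: int = 3) -> dict:
        """Report-style rounding: `digits` decimals, half-up."""
        q = Decimal(10) ** -digits

        def r(x):
            return float(Decimal(repr(float(x))).quantize(
                q, rounding=ROUND_HALF_UP))

        return {
            "per_class": {
                name: {"precision": r(self.precision[i]),
                       "recall": r(self.recall[i]), "f1": r(self.f1[i])}
                for i, name in enumerate(self.classes.names)},
            "macro": {"precision": r(self.macro_precision),
                      "recall": r(self.macro_recall),
                      "f1": r(self.macro_f1)},
        }

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes.names),
            "tp": self.tp.tolist(), "fp": self.fp.tolist(),
            "fn": self.fn.tolist(),
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(), "f1": self.f1.tolist(),
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall, "macro_f1": self.macro_f1,
            "confusion": self.confusion.tolist(),
        }


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def compute_metrics(y_true: Sequence[str], y_pred: Sequence[str],
                    classes: ClassLabelSet) -> MetricsReport:
    """Per-class TP/FP/FN, precision/recall/F1 and the confusion matrix."""
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    k = len(classes)
    confusion = np.zeros((k, k), dtype=int)
    ti = [classes.index(l) for l in y_true]
    pi = [classes.index(l) for l in y_pred]
    np.add.at(confusion, (ti, pi), 1)
    tp = np.diag(confusion).astype(float)
    fp = confusion.sum(axis=0) - tp
    fn = confusion.sum(axis=1) - tp

    def _safe(num, den, what):
        out = np.zeros_like(num, dtype=float)
        ok = den > 0
        out[ok] = num[ok] / den[ok]
        if not ok.all():
            bad = [classes.names[i] for i in np.flatnonzero(~ok)]
            warnings.warn(f"{what} undefined (0/0) for {bad}; reported as 0")
        return out

    precision = _safe(tp, tp + fp, "precision")
    recall = _safe(tp, tp + fn, "recall")
    f1 = np.array([f1_score(p, r) for p, r in zip(precision, recall)])
    return MetricsReport(classes=classes, tp=tp.astype(int),
                         fp=fp.astype(int), fn=fn.astype(int),
                         precision=precision, recall=recall, f1=f1,
                         confusion=confusion)


# ------------------------------------------------------------- experiments

ENCODER_TAGS = ("rp", "waveform")  # plus "cwt:<wavelet>"


def encode_dataset(dataset: SegmentDataset, encoder: str,
                   out_size: int = 299) -> np.ndarray:
    """Encode every segment into an (n, out_size, out_size, 3) image stack."""
    from .baseline_imaging import CWTParams, cwt_image, waveform_image

    images = np.empty((len(dataset), out_size, out_size, 3))
    if encoder == "rp":
        params = RPParams(out_size=out_size)
        for i, seg in enumerate(dataset):
            images[i] = encode_segment(seg.samples, params).pixels
    elif encoder.startswith("cwt:"):
        params = CWTParams(wavelet=encoder.split(":", 1)[1],
                           out_size=out_size)
        for i, seg in enumerate(dataset):
            images[i] = cwt_image(seg, params).pixels
    elif encoder == "waveform":
        for i, seg in enumerate(dataset):
            images[i] = waveform_image(seg, out_size=out_size).pixels
    else:
        raise ValueError(
            f"unknown encoder {encoder!r}; expected 'rp', 'waveform' or "
            "'cwt:<wavelet>'")
    return images


@dataclass
class ExperimentReport:
    """Results and full configuration fingerprint of one experiment."""

    encoder: str
    leads: tuple
    fingerprint: dict
    fold_val_metrics: List[dict] = field(default_factory=list)
    fold_test_metrics: List[dict] = field(default_factory=list)
    test_macro_f1_mean: float = 0.0

    def save(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        out = directory / "report.json"
        out.write_text(json.dumps({
            "encoder": self.encoder, "leads": list(self.leads),
            "fingerprint": self.fingerprint,
            "fold_val_metrics": self.fold_val_metrics,
            "fold_test_metrics": self.fold_test_metrics,
            "test_macro_f1_mean": self.test_macro_f1_mean}, indent=1))
        # per-class CSV of the averaged test metrics
        if self.fold_test_metrics:
            classes = self.fold_test_metrics[0]["classes"]
            with open(directory / "test_metrics.csv", "w") as fh:
                fh.write("class,precision,recall,f1\n")
                k = len(classes)
                for i in range(k):
                    p = np.mean([m["precision"][i]
                                 for m in self.fold_test_metrics])
                    r = np.mean([m["recall"][i]
                                 for m in self.fold_test_metrics])
                    f = np.mean([m["f1"][i] for m in self.fold_test_metrics])
                    fh.write(f"{classes[i]},{p:.3f},{r:.3f},{f:.3f}\n")
        return out


def run_experiment(records: Sequence[ECGRecord], encoder: str = "rp",
                   leads: Optional[Sequence[str]] = ("II", "aVR"),
                   arch: Optional[ArchConfig] = None,
                   train_cfg: Optional[TrainConfig] = None,
                   policy: Optional[AugmentationPolicy] = None,
                   classes: Optional[ClassLabelSet] = None,
                   seed: int = 0, out_size: Optional[int] = None,
                   test_frac: float = 0.2, n_folds: int = 5,
                   stratify_level: str = "recording",
                   max_folds: Optional[int] = None) -> ExperimentReport:
    """Full pipeline: resample -> segment -> encode -> split -> train -> test.

    ``max_folds`` caps how many of the k folds are actually trained (compute
    control for desk-scale runs); the split itself is always the full k-fold
    plan.
    """
    if not records:
        raise ValueError("no records supplied")
    classes = classes or ClassLabelSet(
        tuple(dict.fromkeys(r.label for r in records)))
    policy = policy or AugmentationPolicy()
    arch = arch or ArchConfig.tiny(n_classes=len(classes))
    train_cfg = train_cfg or TrainConfig(seed=seed)
    out_size = out_size or arch.input_size

    def stage(name, fn, *a, **kw):
        try:
            return fn(*a, **kw)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    resampled = stage("resample",
                      lambda: [resample_record(r) for r in records])
    dataset = stage("augment", build_dataset, resampled, policy, leads)
    images = stage("encode", encode_dataset, dataset, encoder, out_size)
    labels = dataset.labels()
    plan = stage("split", split_dataset, dataset, test_frac, n_folds, seed,
                 stratify_level)

    fingerprint = {
        "encoder": encoder, "leads": list(leads) if leads else None,
        "seed": seed, "out_size": out_size,
        "n_records": len(records), "n_segments": len(dataset),
        "arch": {"input_size": arch.input_size, "n_classes": arch.n_classes,
                 "block_counts": list(arch.block_counts),
                 "width_scale": arch.width_scale, "profile": arch.profile},
        "train": {"learning_rate": train_cfg.learning_rate,
                  "batch_size": train_cfg.batch_size,
                  "epochs": train_cfg.epochs, "seed": train_cfg.seed},
        "split": {"test_frac": test_frac, "n_folds": n_folds,
                  "stratify_level": stratify_level},
        "class_counts": dataset.class_counts(),
    }
    report = ExperimentReport(encoder=encoder,
                              leads=tuple(leads) if leads else (),
                              fingerprint=fingerprint)

    x_test = images[plan.test]
    y_test = [labels[i] for i in plan.test]
    folds = plan.folds if max_folds is None else plan.folds[:max_folds]
    test_f1s = []
    for fi, (tr, va) in enumerate(folds):
        net = build_network(arch, seed=seed + fi)
        model = stage(
            f"train fold {fi}", train, net,
            (images[tr], [labels[i] for i in tr]),
            (images[va], [labels[i] for i in va]),
            train_cfg, classes)
        report.fold_val_metrics.append(
            {"fold": fi, "log": model.log,
             "best_val_macro_f1": max(e["val_macro_f1"] for e in model.log)})
        _, pred = model.predict(x_test)
        m = compute_metrics(y_test, pred, classes)
        d = m.to_dict()
        d["fold"] = fi
        report.fold_test_metrics.append(d)
        test_f1s.append(m.macro_f1)
    report.test_macro_f1_mean = float(np.mean(test_f1s))
    return report


def rank_leads(records: Sequence[ECGRecord], leads: Sequence[str],
               **experiment_kw) -> List[Tuple[str, float]]:
    """Run one single-lead experiment per lead; sort by test macro-F1."""
    scores = []
    for lead in leads:
        rep = run_experiment(records, leads=[lead], **experiment_kw)
        scores.append((lead, rep.test_macro_f1_mean))
    return sorted(scores, key=lambda t: -t[1])
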