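"""Resampling and class-conditional 5 s segmentation/augmentation.

Records are first brought to the 200 Hz working rate, then cut into
1,000-sample (5 s) windows per lead. The number and placement of windows
depends on the rhythm class, balancing the dataset against the largest
never-augmented class (right bundle branch block):

``two_if_long`` (Normal, AF, STD)
    2 consecutive non-overlapping windows from sample 0 when the record
    lasts at least 10 s, else 1.
``three_if_long`` (I-AVB, PAC, PVC)
    3 windows when >= 15 s, 2 when 10-15 s, else 1.
``multi_pass`` (LBBB, STE)
    Three passes starting at sample offsets 0, 200 and 400; each pass takes
    consecutive non-overlapping windows, at most 8; all passes concatenated
    (duplicate sample coverage between passes is intended).
``single`` (RBBB)
    1 window from sample 0.

Duration thresholds are inclusive (a 10.00 s record counts as "10 s or
longer"). Records shorter than the threshold still contribute one window so
every recording is represented.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import scipy.signal

from .records import ECGRecord

WORKING_FS = 200.0
SEGMENT_SAMPLES = 1000  # 5 s at 200 Hz

RULE_TAGS = ("two_if_long", "three_if_long", "multi_pass", "single")

#: rhythm class -> segmentation rule for the nine-class setting
DEFAULT_CLASS_RULES: Dict[str, str] = {
    "Normal": "two_if_long",
    "AF": "two_if_long",
    "STD": "two_if_long",
    "I-AVB": "three_if_long",
    "PAC": "three_if_long",
    "PVC": "three_if_long",
    "LBBB": "multi_pass",
    "STE": "multi_pass",
    "RBBB": "single",
}


@dataclass(frozen=True)
class AugmentationPolicy:
    """Maps each rhythm class to one segmentation rule.

    ``passes`` are the 0-based start offsets of the multi_pass rule and
    ``max_windows_per_pass`` caps each pass; segment length is ``L``.
    """

    class_rules: Dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_RULES))
    L: int = SEGMENT_SAMPLES
    two_threshold_s: float = 10.0
    three_threshold_s: float = 15.0
    passes: tuple = (0, 200, 400)
    max_windows_per_pass: int = 8

    def __post_init__(self):
        for cls, rule in self.class_rules.items():
            if rule not in RULE_TAGS:
                raise ValueError(f"class {cls!r}: unknown rule {rule!r}")
        if any(off < 0 or off >= self.L for off in self.passes):
            raise ValueError("pass offsets must lie in [0, L)")

    def rule_for(self, label: str) -> str:
        try:
            return self.class_rules[label]
        except KeyError:
            raise ValueError(
                f"no segmentation rule configured for class {label!r}"
            ) from None


@dataclass
class ECGSegment:
    """One fixed-length single-lead window with provenance."""

    record_id: str
    lead_name: str
    start_index: int
    samples: np.ndarray
    label: str

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be 1-D")
        if self.start_index < 0:
            raise ValueError("start_index must be >= 0")


def resample_record(record: ECGRecord, fs_out: float = WORKING_FS) -> ECGRecord:
    """Resample every lead to ``fs_out`` (Fourier-method polyphase).

    Output length is ``round(n_samples * fs_out / fs_in)``; a no-op when the
    rates already match.
    """
    if fs_out <= 0:
        raise ValueError("fs_out must be positive")
    if fs_out == record.fs:
        return record
    n_out = int(round(record.n_samples * fs_out / record.fs))
    sig = scipy.signal.resample(record.signal, n_out, axis=1)
    return replace(record, signal=sig, fs=fs_out)


def _window_starts(n_samples: int, duration_s: float, rule: str,
                   policy: AugmentationPolicy) -> List[int]:
    """Start indices of the 5 s windows mandated by `rule` for one lead."""
    L = policy.L
    if n_samples < L:
        raise ValueError(
            f"record of {n_samples} samples shorter than segment length {L}")
    if rule == "two_if_long":
        k = 2 if duration_s >= policy.two_threshold_s else 1
        k = min(k, n_samples // L)
        return [i * L for i in range(max(k, 1))]
    if rule == "three_if_long":
        if duration_s >= policy.three_threshold_s:
            k = 3
        elif duration_s >= policy.two_threshold_s:
            k = 2
        else:
            k = 1
        k = min(k, n_samples // L)
        return [i * L for i in range(max(k, 1))]
    if rule == "single":
        return [0]
    # multi_pass
    starts: List[int] = []
    for off in policy.passes:
        n_windows = min(policy.max_windows_per_pass, (n_samples - off) // L)
        starts.extend(off + i * L for i in range(max(n_windows, 0)))
    return starts


def augment_segments(record: ECGRecord,
                     policy: AugmentationPolicy = AugmentationPolicy()
                     ) -> List[ECGSegment]:
    """Apply the record's class rule to every lead independently.

    The record must already be at the working rate. Each lead yields its own
    segments (downstream imaging treats leads as separate samples).
    """
    rule = policy.rule_for(record.label)
    starts = _window_starts(record.n_samples, record.duration_s, rule, policy)
    segments = []
    for li, lead in enumerate(record.lead_names):
        row = record.signal[li]
        for s in starts:
            segments.append(ECGSegment(
                record_id=record.record_id,
                lead_name=lead,
                start_index=s,
                samples=row[s:s + policy.L].copy(),
                label=record.label,
            ))
    return segments


class SegmentDataset:
    """Flat, deterministically ordered list of segments with count summaries."""

    def __init__(self, segments: Sequence[ECGSegment]):
        self.segments = list(segments)

    def __len__(self):
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def __getitem__(self, i):
        return self.segments[i]

    def labels(self) -> list:
        return [s.label for s in self.segments]

    def record_ids(self) -> list:
        return [s.record_id for s in self.segments]

    def class_counts(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for s in self.segments:
            counts[s.label] = counts.get(s.label, 0) + 1
        return counts

    def record_counts(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for s in self.segments:
            counts[s.record_id] = counts.get(s.record_id, 0) + 1
        return counts

    def sorted(self) -> "SegmentDataset":
        return SegmentDataset(sorted(
            self.segments,
            key=lambda s: (s.record_id, s.lead_name, s.start_index)))

    def save(self, directory) -> Path:
        """Serialize as one vector file per segment plus a manifest CSV."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = directory / "manifest.csv"
        with open(manifest, "w") as fh:
            fh.write("file,record_id,lead,start_index,label\n")
            for i, seg in enumerate(self.segments):
                fname = f"seg{i:06d}.csv"
                np.savetxt(directory / fname, seg.samples[None], delimiter=",",
                           fmt="%.9g")
                fh.write(f"{fname},{seg.record_id},{seg.lead_name},"
                         f"{seg.start_index},{seg.label}\n")
        return manifest

    @classmethod
    def load(cls, directory) -> "SegmentDataset":
        directory = Path(directory)
        segments = []
        with open(directory / "manifest.csv") as fh:
            next(fh)
            for line in fh:
                fname, rid, lead, start, label = line.strip().split(",")
                samples = np.loadtxt(directory / fname, delimiter=",")
                segments.append(ECGSegment(rid, lead, int(start),
                                           np.atleast_1d(samples), label))
        return cls(segments)


def build_dataset(records: Sequence[ECGRecord],
                  policy: AugmentationPolicy = AugmentationPolicy(),
                  leads: Sequence[str] = None) -> SegmentDataset:
    """Segment every record (optionally restricted to `leads`).

    Ordering is deterministic: input record order, then lead order as
    requested, then start index.
    """
    from .records import select_leads

    if not records:
        raise ValueError("empty record list")
    segments: List[ECGSegment] = []
    for rec in records:
        if leads is not None:
            rec = select_leads(rec, leads)
        segments.extend(augment_segments(rec, policy))
    return SegmentDataset(segments)
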