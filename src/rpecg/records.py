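"""Core record containers shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

#: Standard 12-lead order used by the CPSC-2018 distribution.
STANDARD_12_LEADS = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

#: The nine rhythm classes, in the fixed order that defines metric axes.
DEFAULT_CLASSES = (
    "Normal", "AF", "I-AVB", "LBBB", "RBBB", "PAC", "PVC", "STD", "STE",
)


class ClassLabelSet:
    """Ordered, unique set of rhythm-class names.

    The order is fixed and defines the axes of confusion matrices and the
    output dimension ordering of trained classifiers.
    """

    def __init__(self, names: Sequence[str] = DEFAULT_CLASSES):
        names = tuple(names)
        if len(set(names)) != len(names):
            raise ValueError("class names must be unique")
        if not names:
            raise ValueError("class set must be non-empty")
        self.names = names
        self._index = {n: i for i, n in enumerate(names)}

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __eq__(self, other) -> bool:
        return isinstance(other, ClassLabelSet) and self.names == other.names

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise ValueError(
                f"unknown class {name!r}; known classes: {list(self.names)}"
            ) from None

    def __repr__(self) -> str:
        return f"ClassLabelSet({list(self.names)})"


@dataclass
class ECGRecord:
    """A multi-lead ECG recording with one rhythm label.

    Attributes
    ----------
    record_id : str
        Identifier carried through segmentation for provenance.
    signal : ndarray, shape (n_leads, n_samples)
        Millivolt-scale samples, one row per lead.
    fs : float
        Sampling rate in Hz.
    lead_names : tuple of str
        One name per signal row, standard 12-lead names where applicable.
    label : str
        Rhythm class of the whole recording.
    beat_times : ndarray or None
        Optional ground-truth beat (R-peak) times in seconds; populated by
        the synthetic generator, absent for real data.
    """

    record_id: str
    signal: np.ndarray
    fs: float
    lead_names: tuple
    label: str
    beat_times: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (n_leads, n_samples)")
        self.lead_names = tuple(self.lead_names)
        if len(self.lead_names) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.lead_names)} lead names for "
                f"{self.signal.shape[0]} signal rows"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.signal.shape[1] < 1:
            raise ValueError("record must contain at least one sample")

    @property
    def n_leads(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.signal.shape[1] / self.fs

    def _lead_index(self, name: str) -> int:
        # case-insensitive: dataset headers disagree on aVR vs AVR
        lowered = {ln.lower(): i for i, ln in enumerate(self.lead_names)}
        try:
            return lowered[name.lower()]
        except KeyError:
            raise ValueError(
                f"unknown lead {name!r}; available leads: {list(self.lead_names)}"
            ) from None

    def lead(self, name: str) -> np.ndarray:
        """Return the 1-D samples of one lead by (case-insensitive) name."""
        return self.signal[self._lead_index(name)]


def select_leads(record: ECGRecord, leads: Sequence[str]) -> ECGRecord:
    """Restrict a record to the requested leads, in the requested order.

    Lead-name matching is case-insensitive. Samples are never reordered or
    rescaled. The default experimental configuration uses ["II", "aVR"].
    """
    idx = [record._lead_index(name) for name in leads]
    return replace(
        record,
        signal=record.signal[idx].copy(),
        lead_names=tuple(record.lead_names[i] for i in idx),
    )
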