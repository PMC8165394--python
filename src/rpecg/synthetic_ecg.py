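"""Seedable generator of labeled multi-lead ECG-like records.

Each record is built from beat templates — sums of Gaussian bumps standing in
for the P wave, QRS complex, and T wave — placed at generated beat times.
Class-dependent morphology rules make the nine rhythm classes distinguishable
without attempting physiological fidelity:

====== ==============================================================
class  morphology rule
====== ==============================================================
Normal regular RR, full P-QRS-T
AF     irregular RR (CV >= 0.15), suppressed P wave, fibrillatory
       baseline ripple
I-AVB  regular RR, prolonged PR interval (0.30 s vs 0.16 s)
LBBB   wide QRS on every beat, discordant T
RBBB   wide, notched (double-peaked) QRS on every beat
PAC    premature narrow beats in a trigeminal pattern (every 3rd beat
       early, followed by a compensatory pause)
PVC    premature wide beats without P wave, same trigeminal pattern
STD    ST-segment depressed by 0.15 mV
STE    ST-segment elevated by 0.20 mV
====== ==============================================================

Leads beyond the first are fixed scaled/sign-flipped copies of the primary
waveform plus independent noise, which suffices because downstream stages
treat leads independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import DEFAULT_CLASSES, STANDARD_12_LEADS, ECGRecord

#: Reduced, well-separated class set used for desk-scale classifier tests:
#: a regular rhythm, an irregular-RR rhythm and a wide-premature-beat rhythm.
TOY3_CLASSES = ("Normal", "AF", "PVC")

# Per-lead projection of the primary waveform onto the remaining 11 leads.
_LEAD_GAINS = (1.0, 1.0, 0.7, -0.8, 0.45, 0.85, -0.35, 0.5, 0.75, 0.9, 0.95, 0.8)


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic record.

    Identical specs (including ``seed``) produce bit-identical records.
    """

    class_label: str = "Normal"
    duration_s: float = 10.0
    fs: float = 500.0
    n_leads: int = 12
    heart_rate_bpm: float = 75.0
    rr_cv: float = 0.0
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_leads < 1:
            raise ValueError("n_leads must be >= 1")
        if self.rr_cv < 0:
            raise ValueError("rr_cv must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.class_label not in DEFAULT_CLASSES:
            raise ValueError(
                f"unknown class_label {self.class_label!r}; "
                f"known classes: {list(DEFAULT_CLASSES)}"
            )


# morphology knobs per class: rr_cv floor, pr interval s, qrs width factor,
# p amplitude, st offset mV, premature-beat cycle (0 = none, 3 = trigeminy),
# premature beats wide?, notched qrs?, fibrillatory ripple?
_CLASS_RULES = {
    "Normal": dict(rr_cv=0.02, pr=0.16, qrs_w=1.0, p_amp=0.15, st=0.0,
                   prem_cycle=0, prem_wide=False, notch=False, fib=False),
    "AF":     dict(rr_cv=0.25, pr=0.16, qrs_w=1.0, p_amp=0.0, st=0.0,
                   prem_cycle=0, prem_wide=False, notch=False, fib=True),
    "I-AVB":  dict(rr_cv=0.02, pr=0.30, qrs_w=1.0, p_amp=0.15, st=0.0,
                   prem_cycle=0, prem_wide=False, notch=False, fib=False),
    "LBBB":   dict(rr_cv=0.02, pr=0.16, qrs_w=2.8, p_amp=0.15, st=0.0,
                   prem_cycle=0, prem_wide=False, notch=False, fib=False),
    "RBBB":   dict(rr_cv=0.02, pr=0.16, qrs_w=2.2, p_amp=0.15, st=0.0,
                   prem_cycle=0, prem_wide=False, notch=True, fib=False),
    "PAC":    dict(rr_cv=0.02, pr=0.16, qrs_w=1.0, p_amp=0.15, st=0.0,
                   prem_cycle=3, prem_wide=False, notch=False, fib=False),
    "PVC":    dict(rr_cv=0.02, pr=0.16, qrs_w=1.0, p_amp=0.15, st=0.0,
                   prem_cycle=3, prem_wide=True, notch=False, fib=False),
    "STD":    dict(rr_cv=0.02, pr=0.16, qrs_w=1.0, p_amp=0.15, st=-0.15,
                   prem_cycle=0, prem_wide=False, notch=False, fib=False),
    "STE":    dict(rr_cv=0.02, pr=0.16, qrs_w=1.0, p_amp=0.15, st=0.20,
                   prem_cycle=0, prem_wide=False, notch=False, fib=False),
}


def _gauss(t: np.ndarray, center: float, width: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - center) / width) ** 2)


def _beat(t, r_time, rule, wide: bool, premature_narrow: bool):
    """One beat rendered onto the time axis `t` (seconds)."""
    qw = rule["qrs_w"] * (2.8 if wide else 1.0)
    y = np.zeros_like(t)
    # P wave (absent on wide/ventricular beats)
    if rule["p_amp"] > 0 and not wide:
        y += _gauss(t, r_time - rule["pr"], 0.025, rule["p_amp"])
    # QRS: Q, R, S bumps
    y += _gauss(t, r_time - 0.025 * qw, 0.012 * qw, -0.10)
    y += _gauss(t, r_time, 0.014 * qw, 1.0 if not wide else 1.25)
    if rule["notch"] and not wide:
        y += _gauss(t, r_time + 0.035 * qw, 0.014 * qw, 0.55)
    y += _gauss(t, r_time + 0.030 * qw, 0.015 * qw, -0.18)
    # ST segment shift: plateau between S and T rendered as a broad bump
    if rule["st"] != 0.0:
        y += _gauss(t, r_time + 0.12, 0.05, rule["st"])
    # T wave, discordant (inverted) after wide beats
    t_amp = -0.25 if wide else 0.30
    y += _gauss(t, r_time + 0.28 * (1.0 if not wide else 1.2), 0.055, t_amp)
    if premature_narrow:
        y *= 0.85
    return y


def synth_record(spec: SynthSpec) -> ECGRecord:
    """Generate one labeled multi-lead record from a :class:`SynthSpec`.

    Ground-truth beat times (seconds) are stored on ``record.beat_times``.
    """
    rule = _CLASS_RULES[spec.class_label]
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs

    rr_mean = 60.0 / spec.heart_rate_bpm
    rr_cv = max(spec.rr_cv, rule["rr_cv"])

    # generate beat times covering the record with a margin; premature beats
    # follow a trigeminal cycle: every `prem_cycle`-th beat arrives early
    # (coupling 0.65 RR) and is followed by a compensatory pause (1.35 RR)
    beat_times = []
    wide_flags = []
    prem_flags = []
    tt = 0.25
    k = 0
    cycle = rule["prem_cycle"]
    while tt < spec.duration_s + rr_mean:
        premature = cycle > 0 and (k % cycle == cycle - 1)
        beat_times.append(tt)
        wide_flags.append(premature and rule["prem_wide"])
        prem_flags.append(premature and not rule["prem_wide"])
        rr = rr_mean * max(0.35, 1.0 + rr_cv * rng.standard_normal())
        if cycle > 0 and (k + 1) % cycle == cycle - 1:
            rr *= 0.65  # next beat is premature: shortened coupling interval
        elif premature:
            rr *= 1.35  # compensatory pause after the ectopic beat
        tt += rr
        k += 1
    beat_times = np.asarray(beat_times)

    primary = np.zeros(n)
    for bt, wide, prem in zip(beat_times, wide_flags, prem_flags):
        lo = np.searchsorted(t, bt - 0.6)
        hi = np.searchsorted(t, bt + 0.6)
        primary[lo:hi] += _beat(t[lo:hi], bt, rule, wide, prem)

    if rule["fib"]:  # fibrillatory baseline ripple replaces organized P waves
        phase = rng.uniform(0, 2 * np.pi)
        primary += 0.05 * np.sin(2 * np.pi * 6.5 * t + phase)
        primary += 0.03 * np.sin(2 * np.pi * 8.1 * t + 2.1 * phase)

    lead_names = tuple(STANDARD_12_LEADS[: spec.n_leads]) if spec.n_leads <= 12 \
        else tuple(STANDARD_12_LEADS) + tuple(
            f"X{i}" for i in range(spec.n_leads - 12))
    signal = np.empty((spec.n_leads, n))
    for li in range(spec.n_leads):
        gain = _LEAD_GAINS[li % len(_LEAD_GAINS)]
        signal[li] = gain * primary + spec.noise_sd * rng.standard_normal(n)

    in_range = beat_times[beat_times < spec.duration_s]
    return ECGRecord(
        record_id=f"synth-{spec.class_label}-{spec.seed}",
        signal=signal,
        fs=spec.fs,
        lead_names=lead_names,
        label=spec.class_label,
        beat_times=in_range,
        meta={"spec": spec},
    )


def synth_dataset(classes, n_per_class, duration_s=10.0, fs=500.0, n_leads=2,
                  seed=0, **spec_kw):
    """Generate ``n_per_class`` records for each class with distinct seeds."""
    records = []
    for ci, cls in enumerate(classes):
        for k in range(n_per_class):
            spec = SynthSpec(class_label=cls, duration_s=duration_s, fs=fs,
                             n_leads=n_leads,
                             seed=seed + 100_000 * ci + k, **spec_kw)
            rec = synth_record(spec)
            records.append(rec)
    return records
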