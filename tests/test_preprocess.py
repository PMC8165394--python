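import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rpecg as r
from rpecg.preprocess import (SEGMENT_SAMPLES, AugmentationPolicy,
                              SegmentDataset, _window_starts,
                              augment_segments, build_dataset,
                              resample_record)
from rpecg.records import ECGRecord

L = SEGMENT_SAMPLES
POLICY = AugmentationPolicy()


def _record(label, n_samples, n_leads=1, fs=200.0):
    sig = np.arange(n_leads * n_samples, dtype=float).reshape(n_leads, -1)
    leads = ("II", "aVR", "V4")[:n_leads]
    return ECGRecord(f"{label}-{n_samples}", sig, fs, leads, label)


def brute_force_starts(n_samples, duration_s, rule, policy=POLICY):
    """Independent window enumerator implementing the stated rules directly."""
    if rule == "single":
        return [0]
    if rule == "two_if_long":
        want = 2 if duration_s >= 10.0 else 1
    elif rule == "three_if_long":
        want = 3 if duration_s >= 15.0 else (2 if duration_s >= 10.0 else 1)
    else:  # multi_pass: enumerate each pass independently
        out = []
        for off in policy.passes:
            pos, taken = off, 0
            while pos + policy.L <= n_samples and taken < 8:
                out.append(pos)
                pos += policy.L
                taken += 1
        return out
    out = []
    pos = 0
    while pos + policy.L <= n_samples and len(out) < want:
        out.append(pos)
        pos += policy.L
    return out or [0]


# ------------------------------------------------------------- resampling

def test_resample_length_500_to_200():
    rec = _record("Normal", 5000, fs=500.0)
    out = resample_record(rec, 200.0)
    assert out.n_samples == 2000 and out.fs == 200.0


def test_resample_noop_when_rates_match():
    rec = _record("Normal", 2000, fs=200.0)
    assert resample_record(rec, 200.0) is rec


def test_resample_preserves_dominant_frequency():
    """A pure 5 Hz sine keeps its spectral peak at 5 Hz after resampling."""
    fs_in, dur = 500.0, 10.0
    t = np.arange(int(fs_in * dur)) / fs_in
    rec = ECGRecord("s", np.sin(2 * np.pi * 5.0 * t)[None], fs_in, ("II",),
                    "Normal")
    out = resample_record(rec, 200.0)
    spec = np.abs(np.fft.rfft(out.signal[0]))
    freqs = np.fft.rfftfreq(out.n_samples, d=1.0 / 200.0)
    assert abs(freqs[spec.argmax()] - 5.0) < 0.2


# ------------------------------------------------------------ segmentation

@pytest.mark.parametrize("label,n_samples,expected_starts", [
    # 13 s Normal -> two 5 s patches
    ("Normal", 2600, [0, 1000]),
    ("Normal", 1900, [0]),            # 9.5 s -> single window
    ("AF", 2000, [0, 1000]),          # exactly 10 s is inclusive
    ("I-AVB", 3000, [0, 1000, 2000]), # exactly 15 s -> three strips
    ("PAC", 2400, [0, 1000]),         # 12 s -> middle band, two
    ("PVC", 1600, [0]),               # 8 s -> one
    ("RBBB", 12000, [0]),             # reference class: never augmented
])
def test_rule_window_starts(label, n_samples, expected_starts):
    rec = _record(label, n_samples)
    segs = augment_segments(rec, POLICY)
    assert [s.start_index for s in segs] == expected_starts
    assert all(len(s.samples) == L for s in segs)


def test_multi_pass_60s_gives_24_segments():
    """60 s record: 8 windows per pass x 3 offset passes."""
    segs = augment_segments(_record("LBBB", 12000), POLICY)
    starts = [s.start_index for s in segs]
    assert len(starts) == 24
    assert starts[:3] == [0, 1000, 2000]
    assert starts[8] == 200 and starts[16] == 400


def test_multi_pass_9s_gives_one_per_pass():
    segs = augment_segments(_record("STE", 1800), POLICY)
    assert [s.start_index for s in segs] == [0, 200, 400]


def test_segments_copy_correct_samples_and_respect_bounds():
    rec = _record("LBBB", 2700, n_leads=2)
    for seg in augment_segments(rec, POLICY):
        assert seg.start_index + L <= rec.n_samples
        lead_row = rec.signal[rec.lead_names.index(seg.lead_name)]
        assert np.array_equal(
            seg.samples, lead_row[seg.start_index:seg.start_index + L])


def test_record_shorter_than_window_rejected():
    with pytest.raises(ValueError, match="shorter"):
        augment_segments(_record("Normal", 900), POLICY)


def test_unconfigured_class_rejected():
    rec = _record("Normal", 2000)
    rec.label = "VT"
    with pytest.raises(ValueError, match="VT"):
        augment_segments(rec, POLICY)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    rule=st.sampled_from(["two_if_long", "three_if_long", "multi_pass",
                          "single"]),
    n_samples=st.integers(min_value=1200, max_value=12000),
)
def test_window_starts_match_brute_force_enumerator(rule, n_samples):
    """Property: the rule implementation equals an independent enumerator
    over random record durations (6-60 s at 200 Hz)."""
    got = _window_starts(n_samples, n_samples / 200.0, rule, POLICY)
    assert got == brute_force_starts(n_samples, n_samples / 200.0, rule)


# ----------------------------------------------------------- build_dataset

def test_build_dataset_counts(toy_records):
    recs = [resample_record(x) for x in toy_records]
    ds = build_dataset(recs, POLICY, leads=["I", "II"])
    # 10 s records, 2 leads: Normal/AF 2 windows, PVC (three_if_long) 2
    per_record = {rec.record_id: len(augment_segments(rec, POLICY))
                  for rec in recs}
    assert len(ds) == sum(per_record.values())
    counts = ds.class_counts()
    assert sum(counts.values()) == len(ds)


def test_build_dataset_order_is_permutation_invariant(toy_records):
    recs = [resample_record(x) for x in toy_records]
    ds1 = build_dataset(recs, POLICY, leads=["II"])
    rng = np.random.default_rng(0)
    shuffled = [recs[i] for i in rng.permutation(len(recs))]
    ds2 = build_dataset(shuffled, POLICY, leads=["II"])
    key = lambda s: (s.record_id, s.lead_name, s.start_index)  # noqa: E731
    assert [key(s) for s in ds1.sorted()] == [key(s) for s in ds2.sorted()]


def test_build_dataset_rejects_empty_list():
    with pytest.raises(ValueError, match="empty"):
        build_dataset([], POLICY)


def test_segment_dataset_save_load_round_trip(tmp_path, toy_records):
    recs = [resample_record(x) for x in toy_records[:2]]
    ds = build_dataset(recs, POLICY, leads=["II"])
    ds.save(tmp_path / "segs")
    back = SegmentDataset.load(tmp_path / "segs")
    assert len(back) == len(ds)
    for a, b in zip(ds, back):
        assert (a.record_id, a.lead_name, a.start_index, a.label) == \
            (b.record_id, b.lead_name, b.start_index, b.label)
        assert np.allclose(a.samples, b.samples)
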