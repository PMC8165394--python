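import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

import rpecg as r
from rpecg.evaluation import (MetricsReport, compute_metrics, encode_dataset,
                              f1_score, split_dataset)
from rpecg.preprocess import AugmentationPolicy, build_dataset, resample_record
from rpecg.records import ClassLabelSet

CLASSES = ClassLabelSet(("x", "y", "z"))


@pytest.fixture(scope="module")
def toy_dataset(toy_records):
    recs = [resample_record(x) for x in toy_records]
    return build_dataset(recs, AugmentationPolicy(), leads=["II"])


# ----------------------------------------------------------------- metrics

def test_f1_harmonic_mean_published_row():
    """Precision 0.916 and recall 0.930 combine to F1 0.923 (3 decimals)."""
    assert round(f1_score(0.916, 0.930), 3) == 0.923


def test_macro_f1_of_published_per_class_column():
    """The unweighted mean of the nine per-class F1 values reproduces the
    printed macro average 0.844."""
    f1s = [0.812, 0.875, 0.923, 0.929, 0.776, 0.753, 0.793, 0.837, 0.900]
    assert round(float(np.mean(f1s)), 3) == 0.844


def test_perfect_predictions():
    y = ["x", "y", "z", "x", "y", "z"]
    m = compute_metrics(y, y, CLASSES)
    assert np.all(m.precision == 1.0) and np.all(m.recall == 1.0)
    assert m.macro_f1 == 1.0
    assert np.array_equal(m.confusion, np.diag([2, 2, 2]))


def test_metrics_match_counting_oracle_on_random_labels():
    """Property: per-class P/R/F1 equal an independent implementation
    (scikit-learn) on random label vectors of several sizes."""
    rng = np.random.default_rng(0)
    for n in (10, 100, 2000, 10_000):
        y_true = rng.choice(CLASSES.names, size=n)
        y_pred = rng.choice(CLASSES.names, size=n)
        m = compute_metrics(list(y_true), list(y_pred), CLASSES)
        p, r_, f, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=list(CLASSES.names), zero_division=0)
        assert np.allclose(m.precision, p)
        assert np.allclose(m.recall, r_)
        assert np.allclose(m.f1, f)


def test_confusion_matrix_consistency():
    rng = np.random.default_rng(1)
    y_true = list(rng.choice(CLASSES.names, size=500))
    y_pred = list(rng.choice(CLASSES.names, size=500))
    m = compute_metrics(y_true, y_pred, CLASSES)
    # row sums = class supports; total = n; trace = total TP
    for i, name in enumerate(CLASSES.names):
        assert m.confusion[i].sum() == y_true.count(name)
    assert m.confusion.sum() == 500
    assert np.trace(m.confusion) == m.tp.sum()


def test_zero_division_convention_warns_and_reports_zero():
    with pytest.warns(UserWarning, match="undefined"):
        m = compute_metrics(["x", "x"], ["y", "y"], CLASSES)
    assert m.precision[CLASSES.index("x")] == 0.0
    assert m.f1[CLASSES.index("x")] == 0.0


def test_rounding_is_half_up():
    m = compute_metrics(["x"] * 3 + ["y"], ["x"] * 3 + ["x"], CLASSES)
    rounded = m.rounded(3)
    assert rounded["per_class"]["x"]["precision"] == 0.75


def test_label_outside_class_set_rejected():
    with pytest.raises(ValueError, match="unknown class"):
        compute_metrics(["x"], ["q"], CLASSES)
    with pytest.raises(ValueError, match="equal length"):
        compute_metrics(["x"], ["x", "y"], CLASSES)


# ------------------------------------------------------------------ splits

def test_segment_level_split_counts():
    """100 segments/class, 3 classes: 20 test per class; each fold's
    validation set has 16 per class."""
    import rpecg.preprocess as pp
    segs = [pp.ECGSegment(f"r{c}{i}", "II", 0, np.zeros(10), c)
            for c in CLASSES.names for i in range(100)]
    ds = pp.SegmentDataset(segs)
    plan = split_dataset(ds, test_frac=0.2, n_folds=5, seed=0,
                         stratify_level="segment")
    labels = ds.labels()
    test_labels = [labels[i] for i in plan.test]
    assert all(test_labels.count(c) == 20 for c in CLASSES.names)
    for tr, va in plan.folds:
        va_labels = [labels[i] for i in va]
        assert all(va_labels.count(c) == 16 for c in CLASSES.names)


def test_split_plan_invariants_over_many_seeds(toy_dataset):
    """Leakage and coverage invariants hold across 100 seeds at recording
    level: test/train/val disjoint, fold val sets partition the pool, no
    record id straddles splits."""
    ds = toy_dataset
    rids = ds.record_ids()
    n = len(ds)
    for seed in range(100):
        plan = split_dataset(ds, seed=seed, stratify_level="recording")
        test = set(plan.test)
        val_union = set()
        for tr, va in plan.folds:
            tr, va = set(tr), set(va)
            assert not (test & (tr | va))
            assert not (tr & va)
            assert not (val_union & va)
            val_union |= va
            test_rids = {rids[i] for i in test}
            assert not (test_rids & {rids[i] for i in tr | va})
        assert val_union == set(range(n)) - test


def test_recording_level_keeps_segments_together(toy_dataset):
    plan = split_dataset(toy_dataset, seed=3, stratify_level="recording")
    rids = toy_dataset.record_ids()
    test_rids = {rids[i] for i in plan.test}
    for tr, va in plan.folds:
        assert not (test_rids & {rids[i] for i in tr})
        assert not ({rids[i] for i in va} & {rids[i] for i in tr})


def test_same_seed_same_plan(toy_dataset):
    a = split_dataset(toy_dataset, seed=9)
    b = split_dataset(toy_dataset, seed=9)
    assert a.test == b.test and a.folds == b.folds


def test_test_fraction_stratified_within_one_item(toy_dataset):
    plan = split_dataset(toy_dataset, test_frac=0.2, seed=1,
                         stratify_level="recording")
    rids = toy_dataset.record_ids()
    labels = toy_dataset.labels()
    unit_label = {}
    for rid, lab in zip(rids, labels):
        unit_label.setdefault(rid, lab)
    test_units = {rids[i] for i in plan.test}
    for cls in set(unit_label.values()):
        total = sum(1 for v in unit_label.values() if v == cls)
        got = sum(1 for u in test_units if unit_label[u] == cls)
        assert abs(got - 0.2 * total) <= 1


def test_class_too_small_names_the_class():
    import rpecg.preprocess as pp
    segs = [pp.ECGSegment(f"r{i}", "II", 0, np.zeros(10), "x")
            for i in range(10)]
    segs += [pp.ECGSegment("solo", "II", 0, np.zeros(10), "y")]
    ds = pp.SegmentDataset(segs)
    with pytest.raises(ValueError, match="'y'"):
        split_dataset(ds, stratify_level="recording")


# ------------------------------------------------------------- experiments

def test_encode_dataset_tags_and_shapes(toy_dataset):
    sub = r.SegmentDataset(list(toy_dataset)[:3])
    for tag in ("rp", "waveform", "cwt:mexh"):
        imgs = encode_dataset(sub, tag, out_size=48)
        assert imgs.shape == (3, 48, 48, 3)
    with pytest.raises(ValueError, match="unknown encoder"):
        encode_dataset(sub, "gaf")


def test_run_experiment_report_provenance(toy_records):
    """Same records/seed with different encoders differ only in encoder
    fingerprint (and metric values)."""
    kw = dict(leads=["II"], arch=r.ArchConfig.tiny(n_classes=3, input_size=75),
              train_cfg=r.TrainConfig(epochs=1, batch_size=16, seed=2),
              seed=2, max_folds=1, out_size=75)
    rep_rp = r.run_experiment(toy_records, encoder="rp", **kw)
    rep_wf = r.run_experiment(toy_records, encoder="waveform", **kw)
    fp1, fp2 = dict(rep_rp.fingerprint), dict(rep_wf.fingerprint)
    assert fp1.pop("encoder") == "rp" and fp2.pop("encoder") == "waveform"
    assert fp1 == fp2
    assert rep_rp.fold_test_metrics[0]["classes"] == list(r.TOY3_CLASSES)


def test_run_experiment_stage_errors_are_labeled(toy_records):
    with pytest.raises(RuntimeError, match="stage 'encode'"):
        r.run_experiment(toy_records, encoder="nope", leads=["II"],
                         max_folds=1)


def test_lead_ranking_prefers_signal_lead():
    """Two leads: lead I carries the class signal, an added pure-noise lead
    does not; the ranking must put the signal lead first."""
    rng = np.random.default_rng(0)
    records = []
    for rec in r.synth_dataset(r.TOY3_CLASSES, 8, duration_s=10.0,
                               fs=500.0, n_leads=1, seed=21):
        noise = rng.standard_normal((1, rec.n_samples)) * 0.3
        sig = np.vstack([rec.signal, noise])
        records.append(r.ECGRecord(rec.record_id, sig, rec.fs,
                                   ("I", "NOISE"), rec.label,
                                   rec.beat_times))
    ranking = r.rank_leads(
        records, ["I", "NOISE"],
        arch=r.ArchConfig.tiny(n_classes=3, input_size=75),
        train_cfg=r.TrainConfig(epochs=4, batch_size=16, seed=4),
        seed=4, max_folds=1, out_size=75)
    assert ranking[0][0] == "I"
    assert ranking[0][1] >= ranking[1][1]


def test_experiment_report_save(tmp_path, toy_records):
    rep = r.run_experiment(
        toy_records, encoder="rp", leads=["II"],
        arch=r.ArchConfig.tiny(n_classes=3, input_size=75),
        train_cfg=r.TrainConfig(epochs=1, batch_size=16, seed=0),
        seed=0, max_folds=1, out_size=75)
    out = rep.save(tmp_path / "exp")
    assert out.exists()
    assert (tmp_path / "exp" / "test_metrics.csv").exists()
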