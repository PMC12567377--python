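"""Protocol tests: split integrity, the cosine schedule, training
determinism, evaluation metrics, paired t-tests, and attention attribution."""

import numpy as np
import pandas as pd
import pytest

from mmha.autodiff import Tensor
from mmha.features import EMOTIONS
from mmha.networks import FusionModel, ModelConfig, UnimodalModel
from mmha.protocol import (ArrayDataset, EvalReport, ScheduleConfig,
                           TrainConfig, attention_attribution,
                           attribution_from_records, build_arrays, cosine_lr,
                           default_face_region_masks, evaluate,
                           make_clip_folds, make_loso_splits, paired_ttest,
                           report_from_predictions, run_experiment,
                           train_model, ExperimentConfig)
from mmha.synthgen import SynthConfig, synth_dataset


def toy_manifest(n_subjects=3, clips_per_emotion=5, windows=4):
    rows = []
    for s in range(n_subjects):
        ci = 0
        for _ in range(clips_per_emotion):
            for emo in EMOTIONS:
                for w in range(windows):
                    rows.append({"subject": f"s{s:02d}", "clip": f"c{ci:02d}",
                                 "emotion": emo, "window": w})
                ci += 1
    return pd.DataFrame(rows)


def random_arrays(n=48, size=16, seed=0, n_subjects=2):
    rng = np.random.default_rng(seed)
    subjects = np.array([f"s{i % n_subjects:02d}" for i in range(n)])
    manifest = pd.DataFrame({"subject": subjects,
                             "clip": [f"c{i:02d}" for i in range(n)],
                             "emotion": ["happy"] * n,
                             "window": np.zeros(n, int)})
    return ArrayDataset(
        rng.standard_normal((n, 5, size, size)).astype(np.float32),
        rng.standard_normal((n, 3, size, size)).astype(np.float32),
        rng.integers(0, 4, n), subjects, manifest)


def tiny_model_cfg(**kw):
    base = dict(d_model=16, n_heads=2, n_blocks=1, mlp_ratio=2,
                efem_stem=4, efem_widths=(4, 8), efem_blocks=1,
                efem_expansion=2, fefem_widths=(4, 8), fefem_blocks=(1, 1),
                fefem_expansion=2, seed=0)
    base.update(kw)
    return ModelConfig(**base)


# --------------------------------------------------------------------- splits


def test_clip_folds_one_clip_per_emotion_per_fold():
    manifest = toy_manifest()
    split = make_clip_folds(manifest, k=5, seed=0)
    clips = manifest[["subject", "clip", "emotion"]].drop_duplicates()
    for subject, group in clips.groupby("subject"):
        for fold in range(1, 6):
            in_fold = [e for (s, c), f in split.assignments.items()
                       for e in group[(group["clip"] == c)
                                      & (group["subject"] == s)]["emotion"]
                       if f == fold and s == subject]
            assert sorted(in_fold) == sorted(EMOTIONS)


def test_clip_folds_no_leakage_and_cover():
    manifest = toy_manifest()
    split = make_clip_folds(manifest, k=5, seed=3)
    n = 0
    for fold in range(1, 6):
        train, val = split.window_indices(manifest, fold)
        tr = set(map(tuple, manifest.iloc[train][["subject", "clip"]].values))
        va = set(map(tuple, manifest.iloc[val][["subject", "clip"]].values))
        assert not tr & va
        assert len(train) + len(val) == len(manifest)
        n += len(val)
    assert n == len(manifest)  # every window validated exactly once


def test_clip_folds_seed_sensitivity_and_divisibility():
    manifest = toy_manifest()
    a = make_clip_folds(manifest, k=5, seed=1)
    b = make_clip_folds(manifest, k=5, seed=2)
    assert a.assignments != b.assignments
    with pytest.raises(ValueError, match="divisible"):
        make_clip_folds(toy_manifest(clips_per_emotion=3), k=5)


def test_loso_splits():
    manifest = toy_manifest(n_subjects=4)
    splits = make_loso_splits(manifest)
    assert len(splits) == 4
    for train_subjects, held in splits:
        assert held not in train_subjects
        assert len(train_subjects) == 3
    with pytest.raises(ValueError):
        make_loso_splits(toy_manifest(n_subjects=1))


# ------------------------------------------------------------------- schedule


def test_cosine_schedule_endpoints_and_midpoint():
    assert cosine_lr(ScheduleConfig(1e-3, 0.0, 100, 0)) == pytest.approx(1e-3)
    assert cosine_lr(ScheduleConfig(1e-3, 0.0, 100, 100)) == pytest.approx(0.0)
    assert cosine_lr(ScheduleConfig(1e-3, 0.0, 100, 50)) == pytest.approx(5e-4)
    assert cosine_lr(ScheduleConfig(1e-3, 1e-5, 40, 20)) \
        == pytest.approx((1e-3 + 1e-5) / 2)


def test_cosine_schedule_monotone_and_validation():
    lrs = [cosine_lr(ScheduleConfig(1e-3, 0.0, 100, t)) for t in range(101)]
    assert all(a >= b for a, b in zip(lrs, lrs[1:]))
    with pytest.raises(ValueError):
        ScheduleConfig(t_max=0)
    with pytest.raises(ValueError):
        ScheduleConfig(eta_max=1e-4, eta_min=1e-3)


# ------------------------------------------------------------------- training


def test_untrained_loss_near_log4():
    from mmha.autodiff import cross_entropy_logits
    data = random_arrays(n=32)
    model = UnimodalModel(tiny_model_cfg(), "eeg")
    loss = cross_entropy_logits(model(Tensor(data.topo)), data.labels)
    assert abs(float(loss.data) - np.log(4)) < 0.3


def test_training_deterministic_same_seed():
    data = random_arrays(n=32)
    idx = np.arange(32)
    states = []
    for _ in range(2):
        model = UnimodalModel(tiny_model_cfg(), "eeg")
        train_model(model, data, idx, TrainConfig(epochs=2, seed=4))
        states.append(model.named_state())
    assert states[0].keys() == states[1].keys()
    for k in states[0]:
        assert np.array_equal(states[0][k], states[1][k]), k


def test_training_rejects_empty_and_records_schedule():
    data = random_arrays(n=32)
    model = UnimodalModel(tiny_model_cfg(), "eeg")
    with pytest.raises(ValueError):
        train_model(model, data, np.array([], int))
    hist = train_model(model, data, np.arange(32),
                       TrainConfig(epochs=3, seed=0))
    assert len(hist) == 3
    assert hist[0]["lr"] == pytest.approx(1e-3)
    assert hist[0]["lr"] > hist[1]["lr"] > hist[2]["lr"]


# ----------------------------------------------------------------- evaluation


def test_perfect_predictor_identity_confusion():
    labels = np.repeat(np.arange(4), 10)
    subjects = np.array(["s01"] * 40)
    rep = report_from_predictions(labels.copy(), labels, subjects)
    assert rep.accuracy == 100.0
    assert np.allclose(rep.confusion, np.eye(4))
    assert rep.per_subject["s01"] == 100.0


def test_random_predictor_near_chance():
    rng = np.random.default_rng(0)
    n = 4000
    labels = np.repeat(np.arange(4), n // 4)
    pred = rng.integers(0, 4, n)
    rep = report_from_predictions(pred, labels, np.array(["s"] * n))
    # 99% binomial interval around 25% at n = 4000
    se = np.sqrt(0.25 * 0.75 / n)
    assert abs(rep.accuracy / 100 - 0.25) < 2.58 * se
    assert np.allclose(rep.confusion.sum(axis=1), 1.0)


def test_paired_ttest_closed_form():
    assert paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 1.0)
    b = np.zeros(3)
    a = np.array([1.0, 2.0, 3.0])
    t, p = paired_ttest(a, b)
    assert t == pytest.approx(2 * np.sqrt(3), rel=1e-6)  # mean 2, sd 1, n 3
    t2, p2 = paired_ttest(b, a)
    assert t2 == pytest.approx(-t) and p2 == pytest.approx(p)
    with pytest.warns(UserWarning):
        t3, _ = paired_ttest([1.0, 1.0], [0.0, 0.0])
    assert np.isnan(t3)


# ---------------------------------------------------------------- attribution


def test_region_masks_partition():
    for g in (2, 4, 7):
        masks = default_face_region_masks(g)
        total = np.zeros(g * g, int)
        for m in masks.values():
            total += m.astype(int)
        assert np.all(total == 1)


def test_attribution_from_records_matches_explicit_loop():
    rng = np.random.default_rng(0)
    n_eeg, n_face, t_band = 10, 4, 2
    T = 1 + n_eeg + n_face
    raw = rng.random((3, 2, T, T))
    rec = raw / raw.sum(-1, keepdims=True)
    masks = default_face_region_masks(2)
    rep = attribution_from_records([rec], n_eeg, n_face,
                                   ["delta", "theta", "alpha", "beta", "gamma"],
                                   t_band, masks)
    # explicit loop over the recorded tensor
    mass = np.zeros(T)
    for b in range(3):
        for h in range(2):
            mass += rec[b, h, 0]
    mass /= 6
    eeg = mass[1:11]
    band_ref = {}
    for i, name in enumerate(["delta", "theta", "alpha", "beta", "gamma"]):
        band_ref[name] = eeg[2 * i] + eeg[2 * i + 1]
    s = sum(band_ref.values())
    for name in band_ref:
        assert rep.band_weights[name] == pytest.approx(band_ref[name] / s)
    assert sum(rep.band_weights.values()) == pytest.approx(1.0)
    assert sum(rep.region_weights.values()) == pytest.approx(1.0)


def test_uniform_attention_gives_token_count_proportions():
    cfg = tiny_model_cfg()
    model = FusionModel(cfg)
    # zero the query projection of the last block -> equal logits -> uniform
    blk = model.blocks[-1]
    blk.msa.wq.weight.data[:] = 0
    blk.msa.wq.bias.data[:] = 0
    data = random_arrays(n=6, size=32)
    rep = attention_attribution(model, data, np.arange(6))
    t_band = model.efem.tokens_per_band(32)
    assert set(rep.band_weights) == {"delta", "theta", "alpha", "beta", "gamma"}
    for w in rep.band_weights.values():
        assert w == pytest.approx(1 / 5, abs=1e-6)  # equal tokens per band
    n_face = 16  # 32 -> stem/2 -> pool/2 -> one stride-2 stage: 4x4 grid
    masks = default_face_region_masks(4)
    for name, m in masks.items():
        assert rep.region_weights[name] == pytest.approx(m.sum() / n_face,
                                                         abs=1e-6)
    assert sum(rep.region_weights.values()) == pytest.approx(1.0)


def test_attribution_rejects_bad_masks():
    rng = np.random.default_rng(0)
    rec = rng.random((1, 1, 8, 8))
    masks = default_face_region_masks(2)
    masks["eyes"] = masks["eyes"].copy()
    masks["eyes"][:] = True  # overlaps other regions
    with pytest.raises(ValueError, match="partition"):
        attribution_from_records([rec], 3, 4, ["a", "b", "c"], 1, masks)


# ----------------------------------------------------------------- experiment


def test_run_experiment_smoke_and_integrity():
    cfg = ExperimentConfig(
        synth=SynthConfig(n_subjects=2, clips_per_emotion=5,
                          clip_duration=4.0, seed=2),
        model=tiny_model_cfg(),
        train=TrainConfig(epochs=2, seed=0),
        map_size=32, face_size=32, folds=(1,), seed=0)
    result = run_experiment(cfg)
    assert set(result.summary["method"]) == \
        {"efem", "fefem", "mmha", "concat", "decision"}
    assert {"accuracy_mean", "accuracy_std"} <= set(result.summary.columns)
    for method, reps in result.reports.items():
        for r in reps:
            assert 0.0 <= r.accuracy <= 100.0
            assert np.allclose(r.confusion.sum(axis=1), 1.0)
            assert set(r.per_subject) == {"s01", "s02"}
    assert "mmha_vs_efem" in result.ttests
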