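"""Training loops, estimators, checkpoints and the CLI glue."""

import numpy as np
import pytest
from sklearn.base import clone

from hemafuse import (AugmentConfig, MAEPretrainer, ScheduleConfig,
                      ViTFusionClassifier, load_checkpoint, save_checkpoint,
                      toy_backbone_config, train_classifier)
from hemafuse.training import export_embeddings, write_embeddings


def _split(records):
    train = [r for r in records if r.split == "train"]
    val = [r for r in records if r.split == "val"]
    return train, val


def _short_sched(epochs=2):
    return ScheduleConfig(base_lr=1e-3, warmup_epochs=min(1, epochs - 1),
                          total_epochs=epochs)


def _take_per_class(records, n_per_class):
    out = []
    for label in {r.label for r in records}:
        out.extend([r for r in records if r.label == label][:n_per_class])
    return out


def test_training_is_deterministic_per_seed(four_class_records, toy_cfg):
    train, val = _split(four_class_records)
    kw = dict(backbone_cfg=toy_cfg, n_classes=4, sched_cfg=_short_sched(),
              batch_size=32, seed=11)
    _, r1 = train_classifier(train[:48], val[:16], **kw)
    _, r2 = train_classifier(train[:48], val[:16], **kw)
    assert r1.history[0]["train_loss"] == r2.history[0]["train_loss"]
    assert r1.history[-1]["val_acc"] == r2.history[-1]["val_acc"]


def test_single_class_training_rejected(four_class_records, toy_cfg):
    train, val = _split(four_class_records)
    only = [r for r in train if r.label == 0]
    with pytest.raises(ValueError):
        train_classifier(only, val, toy_cfg, 4)


def test_empty_validation_warns_and_keeps_final(four_class_records, toy_cfg):
    train, _ = _split(four_class_records)
    subset = _take_per_class(train, 8)
    with pytest.warns(UserWarning):
        model, result = train_classifier(subset, [], toy_cfg, 4,
                                         sched_cfg=_short_sched(),
                                         batch_size=32, seed=0)
    assert result.state  # final checkpoint retained


def test_margins_follow_training_set_imbalance(four_class_records, toy_cfg):
    train, val = _split(four_class_records)
    skewed = [r for r in _take_per_class(train, 20) if r.label != 0] + \
             [r for r in train if r.label == 0][:5]
    _, result = train_classifier(skewed, val[:8], toy_cfg, 4,
                                 sched_cfg=_short_sched(), batch_size=32,
                                 seed=0)
    m = result.margins.margins
    counts = np.bincount([r.label for r in skewed], minlength=4)
    assert m[0] == max(m)
    assert counts[0] == min(counts)


def test_embedding_export_shape_and_determinism(four_class_records, toy_cfg,
                                                tmp_path):
    train, val = _split(four_class_records)
    model, _ = train_classifier(_take_per_class(train, 8), val[:8], toy_cfg,
                                4, sched_cfg=_short_sched(1), batch_size=32,
                                seed=0)
    feats, labels = export_embeddings(model, val[:8])
    assert feats.shape == (8, toy_cfg.dim)
    assert labels.shape == (8,)
    feats2, _ = export_embeddings(model, val[:8])
    assert np.array_equal(feats, feats2)
    out = tmp_path / "emb.tsv"
    write_embeddings(out, feats, labels)
    header = out.read_text().splitlines()[0].split("\t")
    assert header[0] == "feat_0" and header[-1] == "label"
    assert len(out.read_text().splitlines()) == 9


def test_checkpoint_roundtrip(tmp_path, rng):
    state = {"encoder.norm.weight": rng.normal(size=5),
             "arcface.subcenters": rng.normal(size=(2, 3, 4))}
    path = save_checkpoint(tmp_path / "ck.npz", state, meta={"n_classes": 2})
    loaded, meta = load_checkpoint(path)
    assert meta == {"n_classes": 2}
    assert set(loaded) == set(state)
    assert np.array_equal(loaded["arcface.subcenters"],
                          state["arcface.subcenters"])


class TestEstimators:
    def test_classifier_params_roundtrip_and_clone(self):
        est = ViTFusionClassifier(depth=3, loss="ce", seed=5)
        params = est.get_params()
        assert params["depth"] == 3 and params["loss"] == "ce"
        cloned = clone(est)
        assert cloned.get_params() == params

    def test_fit_predict_on_tiny_set(self, four_class_records):
        train, val = _split(four_class_records)
        X = [r.pixels for r in train[:40]]
        y = np.array([r.label for r in train[:40]])
        est = ViTFusionClassifier(epochs=3, warmup_epochs=1, base_lr=1e-3,
                                  batch_size=32, seed=0)
        est.fit(X, y)
        assert set(est.classes_) <= set(y)
        preds = est.predict(X[:5])
        assert preds.shape == (5,)
        assert set(preds) <= set(est.classes_)
        feats = est.transform(X[:5])
        assert feats.shape == (5, est.dim)
        assert len(est.history_) == 3

    def test_unfitted_predict_raises(self):
        from sklearn.exceptions import NotFittedError
        with pytest.raises(NotFittedError):
            ViTFusionClassifier().predict([np.zeros((32, 32, 3), np.uint8)])

    def test_mae_pretrainer_fit_transform(self, four_class_records):
        X = [r.pixels for r in four_class_records[:24]]
        est = MAEPretrainer(steps=5, batch_size=8, seed=0)
        est.fit(X)
        assert est.loss_history_[0] > 0
        assert any(k.startswith("encoder.") for k in est.checkpoint_)
        feats = est.transform(X[:4])
        assert feats.shape == (4, est.dim)


def test_cli_synth_count_train_eval(tmp_path, capsys):
    """End-to-end CLI smoke: synth folder, toy train, evaluate, embed."""
    import json
    import yaml
    from hemafuse.cli import main

    data = tmp_path / "cells"
    cfg = tmp_path / "cfg.yaml"
    cfg.write_text(yaml.safe_dump({
        "classes": [
            {"name": "a", "count": 12, "hue": 0.0},
            {"name": "b", "count": 12, "hue": 180.0},
        ],
        "image_size_range": [64, 80],
        "backbone": {"image_size": 32, "patch_size": 8, "depth": 1,
                     "dim": 32, "heads": 4},
        "schedule": {"base_lr": 1e-3, "warmup_epochs": 1, "total_epochs": 2},
        "augment": {"n_rand_ops": 1},
    }))
    assert main(["synth", "--config", str(cfg), "--out", str(data),
                 "--seed", "1"]) == 0
    ck = tmp_path / "clf.npz"
    assert main(["train", "--data", str(data), "--config", str(cfg),
                 "--out", str(ck), "--epochs", "2", "--batch-size", "16",
                 "--seed", "1"]) == 0
    assert ck.exists() and ck.with_suffix(".log.csv").exists()
    assert main(["evaluate", "--checkpoint", str(ck), "--data", str(data),
                 "--out", str(tmp_path / "report.json")]) == 0
    report = json.loads((tmp_path / "report.json").read_text())
    assert 0.0 <= report["accuracy"] <= 100.0
    assert main(["embed", "--checkpoint", str(ck), "--data", str(data),
                 "--out", str(tmp_path / "emb.tsv")]) == 0
    assert (tmp_path / "emb.tsv").exists()
    assert main(["count", "--preset", "fusion-base-p16"]) == 0
    out = capsys.readouterr().out
    assert "85.82" in out
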