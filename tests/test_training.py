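"""Two-step training, folds, freezing, determinism, experiment bookkeeping."""

import numpy as np
import pytest

from falarm import (
    AlarmClassification,
    AlarmType,
    ChannelRole,
    ConfigError,
    ContractError,
    InsufficientDataError,
    Label,
    LossConfig,
    MissingModalityError,
    ModalConfig,
    PreprocessConfig,
    SyntheticSpec,
    TrainConfig,
    generate_dataset,
    kfold_split,
    run_experiment,
    strip_softmax,
    train_fusion,
    train_modal_net,
)

ECG = ChannelRole.ECG_II

#: miniature but full-pipeline configuration used throughout this module
def fast_config(**kw):
    defaults = dict(
        seed=0,
        n_epochs=2,
        k_folds=2,
        preprocess=PreprocessConfig(window_seconds=6.0),
        modal=ModalConfig(
            conv1_filters=4, conv2_filters=8, n_slices=3, attention_width=8,
            lstm_size=16, fc_size=16,
        ),
    )
    defaults.update(kw)
    return TrainConfig(**defaults)


@pytest.fixture(scope="module")
def records20():
    return generate_dataset(SyntheticSpec(n_records=20, seed=4))[0]


class TestTrainModalNet:
    def test_zero_epochs_returns_seeded_initialization(self, records20):
        cfg = fast_config(n_epochs=0)
        net, trace = train_modal_net(records20, ECG, cfg)
        fresh_seed = net.seed
        from falarm import ModalNet

        fresh = ModalNet(cfg.modal, seed=fresh_seed)
        for k in net.params:
            np.testing.assert_array_equal(net.params[k], fresh.params[k])
        assert trace == []

    def test_loss_decreases_on_synthetic_set(self, records20):
        cfg = fast_config(n_epochs=6)
        _, trace = train_modal_net(records20, ECG, cfg)
        assert trace[-1] < trace[0]

    def test_same_seed_bit_identical_nets(self, records20):
        cfg = fast_config()
        net1, _ = train_modal_net(records20, ECG, cfg)
        net2, _ = train_modal_net(records20, ECG, cfg)
        for k in net1.params:
            np.testing.assert_array_equal(net1.params[k], net2.params[k])

    def test_empty_record_list_rejected(self):
        with pytest.raises(InsufficientDataError):
            train_modal_net([], ECG, fast_config())

    def test_frozen_net_untouched_by_training_step(self, records20):
        """One full training pass over a frozen backbone must leave every
        parameter bitwise identical."""
        cfg = fast_config(n_epochs=1)
        net, _ = train_modal_net(records20, ECG, cfg)
        frozen = net.copy()
        frozen.frozen = True  # frozen but head intact: forward still classifies
        before = {k: v.copy() for k, v in frozen.params.items()}
        from falarm.training import _fit, _prepare

        X, y = _prepare(records20, ECG, cfg)
        _fit(frozen, X, y, cfg, order_seed=1)
        for k, v in frozen.params.items():
            np.testing.assert_array_equal(v, before[k])


class TestStripSoftmax:
    def test_stripped_net_embeds_but_refuses_probabilities(self, records20):
        cfg = fast_config(n_epochs=0)
        net, _ = train_modal_net(records20, ECG, cfg)
        stripped = strip_softmax(net)
        from falarm.training import _prepare

        X, _ = _prepare(records20[:3], ECG, cfg)
        emb = stripped.embed(X)
        assert emb.shape == (3, cfg.modal.fc_size)
        with pytest.raises(ContractError):
            stripped.predict_proba(X)

    def test_idempotent(self, records20):
        net, _ = train_modal_net(records20, ECG, fast_config(n_epochs=0))
        once = strip_softmax(net)
        twice = strip_softmax(once)
        assert twice.stripped and twice.frozen
        for k in once.params:
            np.testing.assert_array_equal(once.params[k], twice.params[k])

    def test_default_embedding_is_256(self):
        from falarm import ModalNet

        net = strip_softmax(ModalNet(ModalConfig(), seed=0))
        emb = net.embed(np.random.default_rng(0).random((1, 2, 200)))
        assert emb.shape == (1, 256)


class TestTrainFusion:
    def test_backbones_bit_identical_after_fusion_training(self, records20):
        cfg = fast_config(n_epochs=2)
        nets = {}
        for role in (ChannelRole.ECG_II, ChannelRole.ABP, ChannelRole.PPG):
            net, _ = train_modal_net(records20, role, cfg)
            nets[role] = strip_softmax(net)
        before = {
            role: {k: v.copy() for k, v in net.params.items()}
            for role, net in nets.items()
        }
        head, trace = train_fusion(records20, nets, cfg)
        for role, net in nets.items():
            for k, v in net.params.items():
                np.testing.assert_array_equal(v, before[role][k])
        assert len(trace) == 2

    def test_unfrozen_backbone_rejected(self, records20):
        cfg = fast_config(n_epochs=0)
        net, _ = train_modal_net(records20, ECG, cfg)
        with pytest.raises(ContractError):
            train_fusion(records20, {ECG: net}, cfg)

    def test_missing_modality_rejected(self, records20):
        cfg = fast_config(n_epochs=0)
        net, _ = train_modal_net(records20, ECG, cfg)
        frozen = strip_softmax(net)
        crippled = [r for r in records20]
        crippled[0] = type(r := records20[0])(
            record_id=r.record_id, fs=r.fs,
            channels={ECG: r.channels[ECG]},
            alarm_type=r.alarm_type, label=r.label, onset_index=r.onset_index,
        )
        with pytest.raises(MissingModalityError):
            train_fusion(crippled, {ECG: frozen, ChannelRole.ABP: frozen}, cfg)

    def test_zero_epochs_head_is_initialization(self, records20):
        cfg = fast_config(n_epochs=0)
        net, _ = train_modal_net(records20, ECG, cfg)
        frozen = strip_softmax(net)
        head, _ = train_fusion(records20, {ECG: frozen}, cfg)
        from falarm import FusionHead
        from falarm.training import _derived_seed

        fresh = FusionHead(cfg.modal.fc_size, seed=_derived_seed(cfg.seed, 2),
                           fc_size=cfg.modal.fc_size, dtype=cfg.modal.dtype)
        for k in head.params:
            np.testing.assert_array_equal(head.params[k], fresh.params[k])


class TestKfoldSplit:
    def test_20_records_10_folds_of_2(self, records20):
        folds = kfold_split(records20, 10, stratified=True, seed=0)
        assert len(folds) == 10
        assert all(len(te) == 2 for _, te in folds)

    def test_partition_property(self, records20):
        folds = kfold_split(records20, 4, stratified=True, seed=1)
        all_test = [rid for _, te in folds for rid in te]
        assert sorted(all_test) == sorted(r.record_id for r in records20)
        for train, test in folds:
            assert not set(train) & set(test)
            assert len(train) + len(test) == 20

    def test_stratification_on_imbalanced_set(self):
        records, _ = generate_dataset(
            SyntheticSpec(n_records=40, true_fraction=0.1, seed=5)
        )
        by_id = {r.record_id: r for r in records}
        folds = kfold_split(records, 4, stratified=True, seed=0)
        for _, test in folds:
            n_true = sum(by_id[rid].label is Label.TRUE_ALARM for rid in test)
            assert n_true == 1  # 4 minority records over 4 folds

    def test_too_many_folds_rejected(self, records20):
        with pytest.raises(ConfigError):
            kfold_split(records20, 21, True, 0)


class TestRunExperiment:
    def test_single_modal_pools_every_record(self, records20):
        res = run_experiment(records20, fast_config())
        assert len(res.record_ids) == 20
        assert res.probs.shape == (20, 2)
        assert sorted(res.record_ids) == sorted(r.record_id for r in records20)
        assert res.metrics.n == 20
        assert res.n_folds == 2
        assert "Cross-validated" in res.summary()

    def test_missing_modality_records_are_excluded_and_counted(self, records20):
        import dataclasses

        crippled = []
        for i, r in enumerate(records20):
            if i < 4:  # strip ABP from four records
                channels = {k: v for k, v in r.channels.items() if k is not ChannelRole.ABP}
                r = dataclasses.replace(r, channels=channels)
            crippled.append(r)
        cfg = fast_config(modalities=(ChannelRole.ECG_II, ChannelRole.ABP,
                                      ChannelRole.PPG))
        model = AlarmClassification(crippled, cfg)
        assert len(model.excluded) == 4
        res = model.fit()
        assert len(res.record_ids) == 16
        assert set(res.excluded_ids) == {r.record_id for r in crippled[:4]}

    def test_same_config_and_seed_reproduce_metrics_exactly(self, records20):
        cfg = fast_config()
        r1 = run_experiment(records20, cfg)
        r2 = run_experiment(records20, cfg)
        np.testing.assert_array_equal(r1.probs, r2.probs)
        assert r1.metrics == r2.metrics

    def test_alarm_filter_restricts_records(self):
        records, _ = generate_dataset(SyntheticSpec(n_records=30, seed=6))
        cfg = fast_config(alarm_filter=AlarmType.VTA, k_folds=2)
        model = AlarmClassification(records, cfg)
        assert all(r.alarm_type is AlarmType.VTA for r in model.records)

    def test_disabled_attention_still_yields_valid_result(self, records20):
        import dataclasses

        cfg = fast_config()
        cfg = dataclasses.replace(cfg, modal=dataclasses.replace(
            cfg.modal, attention_enabled=False))
        res = run_experiment(records20, cfg)
        assert res.metrics.n == 20
        assert np.isfinite(res.probs).all()

    def test_checkpoint_provenance_matches_fold_split(self, records20):
        """No test-fold leakage: each fold's net is tagged with a digest of
        exactly that fold's training ids."""
        from falarm.training import _train_ids_digest

        cfg = fast_config()
        res = run_experiment(records20, cfg)
        by_id = {r.record_id: r for r in records20}
        folds = kfold_split(records20, cfg.k_folds, cfg.stratified, cfg.seed)
        for i, (train_ids, _) in enumerate(folds):
            net = res.checkpoints[(i, ECG.value)]
            assert net.provenance["fold"] == i
            assert net.provenance["train_ids_digest"] == _train_ids_digest(
                [by_id[r] for r in train_ids]
            )

    def test_multimodal_experiment_end_to_end(self, records20):
        cfg = fast_config(modalities=(ChannelRole.ECG_II, ChannelRole.ABP,
                                      ChannelRole.PPG))
        res = run_experiment(records20, cfg)
        assert len(res.record_ids) == 20
        assert (0, "fusion") in res.checkpoints
        np.testing.assert_allclose(res.probs.sum(axis=1), 1.0, atol=1e-5)
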