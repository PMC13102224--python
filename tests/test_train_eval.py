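"""Metrics, Wilcoxon test, max-norm constraint and the training protocols."""

import dataclasses

import numpy as np
import pytest

from rmetnet import nn
from rmetnet.eeg_io import split_subject_dependent
from rmetnet.network import RMETNet
from rmetnet.synthetic_data import SynthConfig, generate_subjects
from rmetnet.train_eval import (
    EvalReport,
    TrainConfig,
    classification_metrics,
    confusion_matrix,
    load_checkpoint,
    summarize,
    train_loso,
    train_subject_dependent,
    wilcoxon_paired,
)


class TestMetrics:
    def test_closed_forms(self):
        assert classification_metrics(np.diag([10, 20, 5])) == (1.0, 1.0)
        acc, kappa = classification_metrics(np.array([[40, 10], [20, 30]]))
        assert acc == pytest.approx(0.7)
        assert kappa == pytest.approx(0.4)
        # everything predicted as one class with balanced truth: kappa 0
        _, kappa = classification_metrics(np.array([[50, 0], [50, 0]]))
        assert kappa == pytest.approx(0.0)

    def test_degenerate_all_one_cell(self):
        acc, kappa = classification_metrics(np.array([[7, 0], [0, 0]]))
        assert (acc, kappa) == (1.0, 0.0)

    def test_agrees_with_sklearn_on_random_predictions(self, rng):
        from sklearn.metrics import accuracy_score, cohen_kappa_score

        for _ in range(25):
            y = rng.integers(0, 4, size=60)
            p = rng.integers(0, 4, size=60)
            acc, kappa = classification_metrics(confusion_matrix(y, p, 4))
            assert acc == pytest.approx(accuracy_score(y, p), abs=1e-12)
            assert kappa == pytest.approx(cohen_kappa_score(y, p), abs=1e-12)


class TestWilcoxon:
    def test_five_positive_differences_exact(self):
        stat, p = wilcoxon_paired([1, 2, 3, 4, 5], [0, 0, 0, 0, 0])
        assert stat == 15.0  # W+ - W- with all ranks positive
        assert p == pytest.approx(0.0625, abs=1e-12)

    def test_identical_vectors_conventional_result(self):
        assert wilcoxon_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 1.0)

    def test_symmetry_in_arguments(self, rng):
        a, b = rng.normal(size=12), rng.normal(size=12)
        sa, pa = wilcoxon_paired(a, b)
        sb, pb = wilcoxon_paired(b, a)
        assert abs(sa) == abs(sb) and pa == pb

    def test_matches_scipy_exact_without_ties(self, rng):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        a = rng.normal(size=10)
        b = a + rng.normal(size=10) * 0.5
        _, p = wilcoxon_paired(a, b)
        ref = scipy_wilcoxon(a, b, alternative="two-sided", method="exact").pvalue
        assert p == pytest.approx(ref, abs=1e-12)

    def test_large_n_normal_approximation_is_sane(self, rng):
        a = rng.normal(size=40)
        b = a + 1.0
        _, p = wilcoxon_paired(a, b)
        assert p < 1e-4

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_paired([1, 2], [1, 2, 3])


class TestMaxnorm:
    def _model_with_kernel(self, norm):
        conv = nn.Conv2d(1, 1, (1, 4))
        conv.weight.data[:] = 0.0
        conv.weight.data[0, 0, 0, 0] = norm
        return conv

    def test_oversized_kernel_rescaled_direction_preserved(self):
        conv = self._model_with_kernel(3.0)
        before = conv.weight.data.copy()
        nn.apply_maxnorm(conv, 2.0)
        after = conv.weight.data
        assert np.linalg.norm(after) == pytest.approx(2.0)
        cos = (before * after).sum() / (np.linalg.norm(before) * np.linalg.norm(after))
        assert cos == pytest.approx(1.0)

    def test_small_kernel_untouched_bitwise(self):
        conv = self._model_with_kernel(1.0)
        before = conv.weight.data.copy()
        nn.apply_maxnorm(conv, 2.0)
        assert np.array_equal(conv.weight.data, before)

    def test_idempotent(self):
        conv = self._model_with_kernel(5.0)
        nn.apply_maxnorm(conv, 2.0)
        once = conv.weight.data.copy()
        nn.apply_maxnorm(conv, 2.0)
        assert np.array_equal(conv.weight.data, once)

    def test_nonpositive_cap_rejected(self):
        with pytest.raises(ValueError):
            nn.apply_maxnorm(nn.Conv2d(1, 1, (1, 2)), 0.0)


class TestSummarize:
    def test_mean_and_sample_sd(self):
        rep = summarize([(0, 0.8, 0.6), (1, 0.6, 0.2)])
        assert rep.mean_acc == pytest.approx(0.7)
        assert rep.sd_acc == pytest.approx(0.1414, abs=1e-4)

    def test_single_subject_flagged_with_zero_sd(self):
        rep = summarize([(0, 0.9, 0.8)])
        assert rep.single_subject and rep.sd_acc == 0.0

    def test_csv_roundtrip_lossless(self, tmp_path):
        rep = summarize([(0, 0.8125, 0.625), (1, 0.55, 0.1)])
        rep.to_csv(tmp_path / "r.csv")
        back = EvalReport.from_csv(tmp_path / "r.csv")
        assert np.array_equal(back.per_subject.values, rep.per_subject.values)

    def test_comparisons_produce_p_values(self):
        rep = summarize([(0, 0.8, 0.6)], {"vs_base": ([1, 2, 3], [0, 0, 0])})
        assert 0 < rep.comparisons["vs_base"] <= 1


def _tiny_run_ingredients(seed=0, n_subjects=2, trials_per_class=12):
    cfg = SynthConfig(n_subjects=n_subjects, trials_per_class=trials_per_class,
                      n_channels=4, n_samples=250, seed=seed)
    return generate_subjects(cfg)


@pytest.fixture(scope="module")
def tiny_cfg():
    from rmetnet.network import preset

    return dataclasses.replace(preset("synthetic-small"), C=4, F1=4, F2=8,
                               tslanet_layers=1, hidden_width=32)


class TestTrainingProtocols:
    def test_seed_determinism_of_training_traces(self, tiny_cfg):
        ts = _tiny_run_ingredients()
        tc = TrainConfig(batch_size=16, epochs=2, learning_rate=1e-3, weight_decay=0.0,
                         lam=1.0, seed=5, mode="cross_subject")
        a = train_loso(ts, 0, tiny_cfg, tc)
        b = train_loso(ts, 0, tiny_cfg, tc)
        assert np.array_equal(a.log.values, b.log.values)
        assert np.array_equal(a.predictions, b.predictions)

    def test_checkpoint_has_lowest_validation_loss(self, tiny_cfg):
        ts = _tiny_run_ingredients(seed=1)
        sub = ts.subset(np.flatnonzero(ts.subjects == 0))
        split = split_subject_dependent(sub, seed=0)
        tc = TrainConfig(batch_size=16, epochs=4, learning_rate=1e-3, weight_decay=0.0,
                         seed=2, mode="subject_dependent")
        res = train_subject_dependent(sub, split, tiny_cfg, tc)
        assert res.best_epoch == int(res.log["val_loss"].idxmin())
        assert res.log["val_loss"].min() == res.log["val_loss"][res.best_epoch]

    def test_target_labels_never_influence_loso_training(self, tiny_cfg):
        """Scrambling the held-out subject's labels changes nothing but the
        final score bookkeeping: weights, logs and predictions are identical."""
        ts = _tiny_run_ingredients(seed=3)
        tc = TrainConfig(batch_size=16, epochs=2, learning_rate=1e-3, weight_decay=0.0,
                         lam=1.0, seed=7, mode="cross_subject")
        res_a = train_loso(ts, 1, tiny_cfg, tc)
        scrambled = ts.subset(np.arange(ts.n_trials))
        mask = scrambled.subjects == 1
        scrambled.labels[mask] = 1 - scrambled.labels[mask]
        res_b = train_loso(scrambled, 1, tiny_cfg, tc)
        assert np.array_equal(res_a.log.values, res_b.log.values)
        assert np.array_equal(res_a.predictions, res_b.predictions)
        for k in res_a.state:
            assert np.array_equal(res_a.state[k], res_b.state[k])

    def test_maxnorm_enforced_on_final_weights(self, tiny_cfg):
        ts = _tiny_run_ingredients(seed=4)
        tc = TrainConfig(batch_size=16, epochs=2, learning_rate=0.1, weight_decay=0.0,
                         lam=0.0, seed=1, mode="cross_subject", maxnorm=2.0)
        res = train_loso(ts, 0, tiny_cfg, tc)
        model = RMETNet(tiny_cfg, seed=1)
        model.load_state_dict(res.state)
        for p in model.parameters():
            if getattr(p, "constrain", False):
                norms = np.linalg.norm(p.data.reshape(p.data.shape[0], -1), axis=1)
                assert (norms <= 2.0 + 1e-9).all()

    def test_empty_validation_split_rejected(self, tiny_cfg):
        ts = _tiny_run_ingredients(seed=5, n_subjects=1)
        split = split_subject_dependent(ts, ratios=(1, 0, 1), seed=0)
        tc = TrainConfig(epochs=1, mode="subject_dependent")
        with pytest.raises(ValueError, match="validation"):
            train_subject_dependent(ts, split, tiny_cfg, tc)

    def test_checkpoint_roundtrip(self, tiny_cfg, tmp_path):
        ts = _tiny_run_ingredients(seed=6)
        tc = TrainConfig(batch_size=16, epochs=1, learning_rate=1e-3, weight_decay=0.0,
                         lam=0.0, seed=3, mode="cross_subject")
        res = train_loso(ts, 0, tiny_cfg, tc)
        path = tmp_path / "ckpt.npz"
        res.save(path)
        model, model_cfg, train_cfg, mode = load_checkpoint(path)
        assert mode == "full"
        assert model_cfg.C == tiny_cfg.C
        for k, v in res.state.items():
            assert np.array_equal(dict(model.named_parameters())[k].data, v)


class TestLearningBehaviour:
    """Stochastic end-to-end checks on the separable synthetic generator."""

    def test_subject_dependent_reaches_high_accuracy(self):
        from rmetnet.network import preset

        mc = preset("synthetic-small")
        accs = []
        for seed in range(5):
            cfg = SynthConfig(n_subjects=1, trials_per_class=100, n_channels=6,
                              n_samples=250, erd_depth=0.8, snr_db=10.0,
                              subject_shift=0.0, seed=seed)
            ts = generate_subjects(cfg)
            split = split_subject_dependent(ts, seed=seed)
            tc = TrainConfig(batch_size=64, epochs=30, learning_rate=1e-3,
                             weight_decay=0.0, lam=0.0, seed=seed,
                             mode="subject_dependent")
            accs.append(train_subject_dependent(ts, split, mc, tc).accuracy)
        assert np.mean(accs) >= 0.80

    def test_randomized_labels_stay_at_chance(self):
        from rmetnet.network import preset

        mc = preset("synthetic-small")
        accs = []
        for seed in range(5):
            cfg = SynthConfig(n_subjects=1, trials_per_class=100, n_channels=6,
                              n_samples=250, erd_depth=0.8, snr_db=10.0,
                              subject_shift=0.0, seed=seed)
            ts = generate_subjects(cfg)
            ts.labels = np.random.default_rng(seed + 100).permutation(ts.labels)
            split = split_subject_dependent(ts, seed=seed)
            tc = TrainConfig(batch_size=64, epochs=30, learning_rate=1e-3,
                             weight_decay=0.0, lam=0.0, seed=seed,
                             mode="subject_dependent")
            accs.append(train_subject_dependent(ts, split, mc, tc).accuracy)
        assert 0.35 <= np.mean(accs) <= 0.65
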