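"""Schedule, optimizer, two-step training loop, folds, fine-tune plumbing.

Training runs here are miniature (short recordings, few epochs) and check
structural contracts — determinism, ablation wiring, label hygiene — not
learning quality, which the acceptance suite measures.
"""

import numpy as np
import pytest

from crossfatigue.eegsim import SynthConfig, make_domain_pair
from crossfatigue.model import ModelSpec, build_model
from crossfatigue.training import (
    SGD,
    TrainSpec,
    adapt,
    cross_validate,
    fine_tune,
    lr_schedule,
    make_folds,
    predict,
    pretrain,
)
from crossfatigue.types import LabelAccessError, Segment, stack_labels

TINY = ModelSpec(backbone_depth="tiny", in_channels=17)


def quick_spec(**kw):
    base = dict(epochs=2, warmup_epochs=1, cosine_half_period_epochs=4,
                lr_max=0.01, lr_min=0.001, seed=0, segment_len=512)
    base.update(kw)
    return TrainSpec(**base)


@pytest.fixture(scope="module")
def pair():
    cfg = SynthConfig(duration=16.0, n_recordings_per_domain=2, shift=1.0, seed=5)
    return make_domain_pair(cfg)


class TestLrSchedule:
    SPEC = TrainSpec()  # full-scale constants

    def test_peak_at_end_of_warmup(self):
        assert lr_schedule(10, self.SPEC) == pytest.approx(0.05)

    def test_trough_one_half_period_later(self):
        assert lr_schedule(110, self.SPEC) == pytest.approx(0.001)

    def test_bounded_everywhere(self):
        lrs = [lr_schedule(e, self.SPEC) for e in range(0, 400)]
        assert min(lrs) >= 0.001 - 1e-12
        assert max(lrs) <= 0.05 + 1e-12

    def test_continuous_at_warmup_junction(self):
        just_before = lr_schedule(9, self.SPEC) + (0.05 - 0.001) / 10
        assert abs(just_before - lr_schedule(10, self.SPEC)) < 1e-12

    def test_negative_epoch_rejected(self):
        with pytest.raises(ValueError):
            lr_schedule(-1, self.SPEC)


class TestSGD:
    def test_momentum_free_step_is_plain_descent(self):
        from crossfatigue.nn.autograd import Tensor

        p = Tensor(np.array([1.0]), requires_grad=True)
        p.grad = np.array([0.5])
        SGD([p], momentum=0.0, weight_decay=0.0, clip_norm=None).step(0.1)
        assert np.allclose(p.data, [0.95])

    def test_weight_decay_shrinks_parameters(self):
        from crossfatigue.nn.autograd import Tensor

        p = Tensor(np.array([2.0]), requires_grad=True)
        p.grad = np.array([0.0])
        SGD([p], momentum=0.0, weight_decay=0.1, clip_norm=None).step(0.5)
        assert np.allclose(p.data, [2.0 - 0.5 * 0.1 * 2.0])

    def test_clipping_bounds_update_norm(self):
        from crossfatigue.nn.autograd import Tensor

        p = Tensor(np.zeros(4), requires_grad=True)
        p.grad = np.full(4, 100.0)
        SGD([p], momentum=0.0, weight_decay=0.0, clip_norm=1.0).step(1.0)
        assert np.linalg.norm(p.data) <= 1.0 + 1e-9


class TestPretrain:
    def test_deterministic_given_seed(self, pair):
        source, target = pair
        _, r1 = pretrain(source, target, TINY, quick_spec())
        _, r2 = pretrain(source, target, TINY, quick_spec())
        assert r1["loss"] == r2["loss"]
        assert r1["holdout_accuracy"] == r2["holdout_accuracy"]

    def test_empty_domain_rejected(self, pair):
        source, _ = pair
        with pytest.raises(ValueError):
            pretrain(source, [], TINY, quick_spec())

    def test_report_has_one_row_per_epoch(self, pair):
        source, target = pair
        _, rep = pretrain(source, target, TINY, quick_spec(epochs=3))
        assert rep["epoch"] == [0, 1, 2]
        assert len(rep["loss"]) == 3


class TestAdapt:
    def test_alpha_zero_trains_without_alignment_pressure(self, pair):
        source, target = pair
        model, rep = adapt(None, source, target, TINY, quick_spec(alpha=0.0))
        assert rep["mmd"][-1] >= 0  # logged but unused
        assert all(np.isfinite(rep["total"]))

    def test_target_labels_never_reach_supervised_term(self, pair):
        source, target = pair
        # the contract itself: eval-only segment labels refuse training access
        from crossfatigue.training import _draw_segments

        segs = _draw_segments(target, 512, np.random.default_rng(0))
        with pytest.raises(LabelAccessError):
            stack_labels(segs, training=True)

    def test_warm_start_differs_from_cold_start(self, pair):
        source, target = pair
        pre, _ = pretrain(source, target, TINY, quick_spec())
        warm, _ = adapt(pre, source, target, TINY, quick_spec())
        cold, _ = adapt(pre, source, target, TINY,
                        quick_spec(ablation={"no_pretraining"}))
        w = warm.extractor.state_dict()
        c = cold.extractor.state_dict()
        assert any(not np.allclose(w[k], c[k]) for k in w)

    def test_ablation_changes_only_named_block(self):
        full = build_model(TINY, seed=0)
        no_attn = build_model(
            ModelSpec(backbone_depth="tiny", in_channels=17, use_attention=False),
            seed=0,
        )
        no_gru = build_model(
            ModelSpec(backbone_depth="tiny", in_channels=17, use_gru=False), seed=0
        )
        full_names = set(full.state_dict())
        attn_names = set(no_attn.state_dict())
        gru_names = set(no_gru.state_dict())
        removed_attn = full_names - attn_names
        assert removed_attn and all(".attn." in n for n in removed_attn)
        removed_gru = {n for n in full_names - gru_names if ".gru." in n or n.startswith("extractor.gru")}
        assert removed_gru
        assert not (attn_names - full_names)


class TestFineTune:
    def test_unlocked_count_matches_fraction(self, pair):
        source, target = pair
        spec = quick_spec(epochs=1)
        from crossfatigue.training import _materialize_segments

        n_t = len(_materialize_segments(target, spec.segment_len,
                                        np.random.default_rng(spec.seed + 3)))
        _, rep = fine_tune(build_model(TINY, 0), source, target, 0.5, spec)
        assert rep["n_unlocked"] == round(0.5 * n_t)

    def test_fraction_out_of_range_rejected(self, pair):
        source, target = pair
        with pytest.raises(ValueError):
            fine_tune(build_model(TINY, 0), source, target, 0.0, quick_spec())
        with pytest.raises(ValueError):
            fine_tune(build_model(TINY, 0), source, target, 1.2, quick_spec())


class TestFolds:
    def test_partition_property(self):
        rng = np.random.default_rng(0)
        folds = make_folds(11, 5, rng)
        assert len(folds) == 5
        joined = np.sort(np.concatenate(folds))
        assert np.array_equal(joined, np.arange(11))

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            make_folds(3, 5, np.random.default_rng(0))

    def test_cross_validate_runs_folds_times_runs_fits(self):
        cfg = SynthConfig(duration=16.0, n_recordings_per_domain=2, shift=0.5,
                          seed=2)
        source, target = make_domain_pair(cfg)
        spec = quick_spec(epochs=1, folds=2, runs=2)
        report = cross_validate(source, target, TINY, spec)
        assert report["n_fits"] == 4
        # every recording lands in exactly one test fold per run
        for run in range(2):
            folds = [f["fold"] for f in report["per_fold"] if f["run"] == run]
            assert sorted(folds) == [0, 1]
        # aggregation equals hand-computed mean of the per-fold metrics
        accs = [f["metrics"]["accuracy"] for f in report["per_fold"]]
        assert report["accuracy_mean"] == pytest.approx(np.mean(accs))


class TestPredict:
    def test_truth_comes_from_assessment_labels(self, pair):
        _, target = pair
        model = build_model(TINY, 0)
        pred, truth = predict(model, target, segment_len=512, seed=0)
        assert pred.shape == truth.shape
        assert np.all((pred >= 0) & (pred <= 1))
        assert np.all((truth >= 0) & (truth <= 1))
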