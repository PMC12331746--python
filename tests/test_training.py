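"""Losses, phase bookkeeping, accumulation oracle, cohort splitting."""

import numpy as np
import pytest

from iecad.network import IECadNetwork, ModelConfig
from iecad.nn import Adam, Linear, Tensor
from iecad.training import (
    PHASE_TASKS, TrainConfig, cross_entropy, dice_loss, make_training_samples,
    phase_parameters, run_phase, split_cohort, task_losses,
)


class TestLosses:
    def test_uniform_two_class_cross_entropy_is_ln2(self):
        logits = Tensor(np.zeros((5, 2)))
        ce = cross_entropy(logits, np.array([0, 1, 0, 1, 1]), 2)
        assert float(ce.data) == pytest.approx(np.log(2), abs=1e-6)

    def test_perfect_onehot_segmentation_dice_loss_near_zero(self):
        labels = np.random.default_rng(0).integers(0, 3, (2, 4, 8, 8))
        onehot = np.moveaxis(np.eye(3)[labels], -1, 1)
        logits = Tensor((onehot * 2 - 1) * 50.0)  # saturated softmax
        assert float(dice_loss(logits, labels).data) == pytest.approx(
            0.0, abs=1e-4)

    def test_matching_curve_mse_zero(self):
        from iecad.training import _mse
        curve = np.linspace(0, -20, 20)
        assert float(_mse(Tensor(curve), curve).data) == 0.0

    def test_dice_loss_bounded(self):
        rng = np.random.default_rng(1)
        logits = Tensor(rng.normal(size=(1, 3, 2, 6, 6)))
        labels = rng.integers(0, 3, (1, 2, 6, 6))
        val = float(dice_loss(logits, labels).data)
        assert 0.0 <= val <= 1.0


class TestAccumulationOracle:
    def test_accumulated_updates_equal_large_batch_on_linear_model(self):
        """Mean-scaled accumulation over k micro-batches reproduces the
        large-batch gradient, hence the identical Adam update."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 4)).astype(np.float32)
        y = rng.normal(size=(12, 1)).astype(np.float32)

        def fresh():
            return Linear(4, 1, np.random.default_rng(42))

        def mse(model, xb, yb):
            d = model(Tensor(xb)) - Tensor(yb)
            return (d * d).mean()

        big = fresh()
        opt_big = Adam(big.parameters(), lr=1e-2)
        mse(big, X, y).backward()
        opt_big.step()

        acc = fresh()
        opt_acc = Adam(acc.parameters(), lr=1e-2)
        for k in range(3):
            loss = mse(acc, X[k * 4:(k + 1) * 4], y[k * 4:(k + 1) * 4])
            (loss * (1.0 / 3.0)).backward()
        opt_acc.step()

        for pb, pa in zip(big.parameters(), acc.parameters()):
            assert np.allclose(pb.data, pa.data, atol=1e-6)


@pytest.fixture(scope="module")
def tiny_setup():
    from iecad.synthetic import make_cohort
    records = make_cohort(4, prevalence=0.5, rng_seed=2, frame_size=32)
    net = IECadNetwork(ModelConfig(frame_size=32, width=0.0625, seed=2))
    cfg = TrainConfig(phase_epochs=(1, 1, 1), lr=1e-3, batch_size=4,
                      grad_accum=1, seed=2)
    return net, records, cfg


class TestPhases:
    def test_phase_parameter_partition(self):
        net = IECadNetwork(ModelConfig(frame_size=32, width=0.0625, seed=0))
        names3, _ = phase_parameters(net, 3)
        assert all(not n.startswith("encoder") for n in names3)
        names1, _ = phase_parameters(net, 1)
        assert any(n.startswith("encoder") for n in names1)
        with pytest.raises(ValueError):
            phase_parameters(net, 4)

    def test_phase3_frozen_parameters_bit_identical(self, tiny_setup):
        net, records, cfg = tiny_setup
        samples = make_training_samples(records)
        frozen_names = set(dict(net.named_parameters())) - \
            set(phase_parameters(net, 3)[0])
        before = {n: p.data.copy() for n, p in net.named_parameters()
                  if n in frozen_names}
        bn_before = {k: v.copy() for k, v in net.state_dict().items()
                     if "running" in k}
        run_phase(net, samples, cfg, 3)
        after = dict(net.named_parameters())
        for name, data in before.items():
            assert np.array_equal(data, after[name].data), name
        # frozen normalisation statistics must not drift either
        for k, v in bn_before.items():
            if not k.startswith("lowrank_gensini") and "gensini" not in k \
                    and "cad" not in k:
                assert np.array_equal(v, net.state_dict()[k]), k

    def test_phase3_trains_its_own_heads(self, tiny_setup):
        net, records, cfg = tiny_setup
        samples = make_training_samples(records)
        name, param = next(
            (n, p) for n, p in net.named_parameters()
            if n.startswith("cad_fc2"))
        before = param.data.copy()
        run_phase(net, samples, cfg, 3)
        assert not np.array_equal(before, param.data)

    def test_same_seed_identical_losses(self, tiny_setup):
        _, records, cfg = tiny_setup
        samples = make_training_samples(records)
        results = []
        for _ in range(2):
            net = IECadNetwork(ModelConfig(frame_size=32, width=0.0625,
                                           seed=5))
            st = run_phase(net, samples, cfg, 2)
            results.append(st.epoch_losses)
        assert results[0] == results[1]

    def test_empty_data_rejected(self, tiny_setup):
        net, _, cfg = tiny_setup
        with pytest.raises(ValueError):
            run_phase(net, [], cfg, 1)

    def test_lr_rewarmed_each_phase(self, tiny_setup):
        net, records, cfg = tiny_setup
        samples = make_training_samples(records)
        s1 = run_phase(net, samples, cfg, 1)
        s2 = run_phase(net, samples, cfg, 2)
        # warmup restarts: first update of each phase is below the peak rate
        assert s1.lr_history[0] <= cfg.lr
        assert s2.lr_history[0] <= max(s2.lr_history)


class _Rec:
    def __init__(self, significant, severe):
        self.significant = significant
        self.severe = severe


def _records(n_by_stratum):
    recs = []
    for (sig, sev), n in n_by_stratum.items():
        recs.extend(_Rec(sig, sev) for _ in range(n))
    return recs


class TestSplitCohort:
    def test_partition_property(self):
        recs = _records({(True, True): 10, (True, False): 10,
                         (False, True): 10, (False, False): 10})
        train, test = split_cohort(recs, ratio=0.8, seed=0)
        assert len(train) + len(test) == len(recs)
        ids = {id(r) for r in train} | {id(r) for r in test}
        assert len(ids) == len(recs)

    def test_reproduces_reference_cohort_sizes(self):
        """A 290-subject cohort with a clinically plausible label
        cross-tabulation splits 8:2 into (234, 56) subjects."""
        recs = _records({(True, True): 98, (True, False): 24,
                         (False, True): 30, (False, False): 138})
        train, test = split_cohort(recs, ratio=0.8, seed=1)
        assert (len(train), len(test)) == (234, 56)

    def test_uniform_labels_plain_split(self):
        recs = _records({(False, False): 20})
        train, test = split_cohort(recs, ratio=0.8, seed=3)
        assert (len(train), len(test)) == (16, 4)

    def test_label_proportions_screened(self):
        recs = _records({(True, True): 40, (False, False): 60})
        train, test = split_cohort(recs, ratio=0.8, seed=4)
        p_train = np.mean([r.significant for r in train])
        p_test = np.mean([r.significant for r in test])
        assert abs(p_train - p_test) < 0.15

    def test_too_small_to_stratify(self):
        with pytest.raises(ValueError):
            split_cohort([_Rec(True, True)], ratio=0.8, seed=0)

    def test_invalid_ratio(self):
        with pytest.raises(ValueError):
            split_cohort(_records({(False, False): 10}), ratio=1.2, seed=0)
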