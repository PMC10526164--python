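import math

import numpy as np
import pytest

from astromem.models import (
    HeadConfig,
    RecurrentHead,
    SynapticHead,
    TrainConfig,
    evaluate_head,
    make_head,
    readout,
    train_head,
)
from astromem.models import _bce
from astromem.synapse import DriveTrace, SynapseParams, simulate_trace
from astromem.task import TaskConfig, generate_session, make_batch


def tiny_batch(rng, B=3, T=12, dim=6):
    inputs = rng.uniform(0, 1.5, size=(B, T, dim)) * (rng.random((B, T, dim)) < 0.5)
    readout_steps = rng.integers(2, T, size=B)
    labels = np.where(rng.random(B) < 0.5, 1, -1)
    return inputs, readout_steps, labels


def numeric_gradients(head, inputs, readout_steps, targets, eps=1e-6):
    grads = {}
    for name, param in head.parameters().items():
        grad = np.zeros_like(param, dtype=float)
        it = np.nditer(param, flags=["multi_index"])
        while not it.finished:
            idx = it.multi_index
            orig = param[idx]
            for sign in (+1, -1):
                param[idx] = orig + sign * eps
                probs, _ = head.forward_batch(inputs)
                p = probs[np.arange(len(targets)), readout_steps]
                loss = _bce(p, targets)
                if sign > 0:
                    plus = loss
                else:
                    minus = loss
            param[idx] = orig
            grad[idx] = (plus - minus) / (2 * eps)
            it.iternext()
        grads[name] = grad
    return grads


class TestReductionContract:
    def test_astro_with_zeroed_feedback_equals_depression(self, bank):
        """The central reduction: delta_u0 = 0, beta = 0 pins u at u0."""
        params = SynapseParams()
        config = HeadConfig(model_kind="astro")
        rng_weights = np.random.default_rng(5)
        astro = SynapticHead(
            config, params.without_astrocyte(), astro=True,
            rng=np.random.default_rng(5),
        )
        depression = SynapticHead(
            HeadConfig(model_kind="depression"), params, astro=False,
            rng=np.random.default_rng(5),
        )
        batch = make_batch(TaskConfig(), 3, 3, bank, np.random.default_rng(1))
        pa, _ = astro.forward_batch(batch.inputs)
        pd, _ = depression.forward_batch(batch.inputs)
        assert np.array_equal(pa, pd)

    def test_full_astro_differs_from_depression(self, bank):
        params = SynapseParams()
        astro = SynapticHead(
            HeadConfig(model_kind="astro"), params, astro=True,
            rng=np.random.default_rng(5),
        )
        depression = SynapticHead(
            HeadConfig(model_kind="depression"), params, astro=False,
            rng=np.random.default_rng(5),
        )
        batch = make_batch(TaskConfig(), 3, 3, bank, np.random.default_rng(1))
        pa, _ = astro.forward_batch(batch.inputs)
        pd, _ = depression.forward_batch(batch.inputs)
        assert not np.allclose(pa, pd)


class TestSynapticForward:
    def test_negative_input_rejected(self):
        head = make_head(HeadConfig(model_kind="astro"))
        with pytest.raises(ValueError):
            head.forward(-np.ones((5, 64)))

    def test_zero_input_constant_output(self):
        head = make_head(HeadConfig(model_kind="astro"), rng=np.random.default_rng(2))
        probs, _ = head.forward(np.zeros((30, 64)))
        assert np.allclose(probs, probs[0])

    def test_repeated_flashes_depress_effective_input(self, bank):
        """Summed transmitted drive shrinks over successive flashes."""
        head = make_head(HeadConfig(model_kind="depression"))
        M = np.zeros((30, 64))
        M[::3] = bank.vectors[0]
        _, trajectory = head.forward(M)
        summed = trajectory.effective_series.sum(axis=1)[::3]
        assert np.all(np.diff(summed) <= 1e-10)
        assert summed[-1] < summed[0]

    def test_x_matches_simulate_trace(self, bank):
        """Shared-core contract with the synapse module."""
        head = make_head(HeadConfig(model_kind="depression"))
        M = np.zeros((24, 64))
        M[::3] = bank.vectors[1]
        _, trajectory = head.forward(M)
        reference = simulate_trace(
            DriveTrace(values=M), head.synapse_params, astro=False
        )
        assert np.array_equal(trajectory.x_series, reference.x_series)

    def test_batch_forward_matches_single(self, bank):
        head = make_head(HeadConfig(model_kind="astro"), rng=np.random.default_rng(8))
        batch = make_batch(TaskConfig(), 2, 2, bank, np.random.default_rng(3))
        batched, _ = head.forward_batch(batch.inputs)
        for i in range(len(batch)):
            single, _ = head.forward(batch.inputs[i])
            assert np.allclose(batched[i], single, atol=1e-12)

    def test_depression_limit_is_feedforward(self):
        """u0=1 and huge tau_d keep x ~ 1: output ~ plain feedforward."""
        params = SynapseParams(tau_d=1e9, u0=1.0, delta_u0=0.0, beta=0.0)
        head = SynapticHead(
            HeadConfig(model_kind="depression"), params, astro=False,
            rng=np.random.default_rng(4),
        )
        rng = np.random.default_rng(9)
        M = rng.uniform(0, 1, size=(10, 64)) * 1e-6  # tiny drive, x stays ~1
        probs, _ = head.forward(M)
        from scipy.special import expit

        hidden = np.maximum(M @ head.W1 + head.b1, 0.0)
        plain = expit(hidden @ head.w2 + float(head.b2))
        assert np.allclose(probs, plain, atol=1e-6)


class TestRecurrentForward:
    def test_zero_recurrence_is_feedforward(self):
        head = RecurrentHead(HeadConfig(model_kind="rnn"), rng=np.random.default_rng(3))
        head.W_rec[...] = 0.0
        rng = np.random.default_rng(10)
        M = rng.normal(size=(8, 64))
        probs, _ = head.forward(M)
        from scipy.special import expit

        per_step = expit(
            np.tanh(M @ head.W_in.T + head.b_h) @ head.w_out + float(head.b_out)
        )
        assert np.allclose(probs, per_step)

    def test_zero_everything_gives_half(self):
        head = RecurrentHead(HeadConfig(model_kind="rnn"))
        head.W_in[...] = 0.0
        head.W_rec[...] = 0.0
        head.w_out[...] = 0.0
        probs, _ = head.forward(np.zeros((6, 64)))
        assert np.allclose(probs, 0.5)

    def test_persistence_near_critical_recurrence(self):
        """Hidden activity outlives a single flash when the recurrent
        matrix has spectral radius near 1."""
        config = HeadConfig(model_kind="rnn")
        head = RecurrentHead(config, rng=np.random.default_rng(0))
        w = np.random.default_rng(1).normal(size=(16, 16))
        head.W_rec[...] = w / np.abs(np.linalg.eigvals(w)).max() * 0.98
        M = np.zeros((40, 64))
        M[0] = 1.0
        _, hidden = head.forward(M)
        norms = np.linalg.norm(hidden, axis=1)
        assert norms[0] > 0
        assert norms[20] > 0.05 * norms[0]  # activity persists 20 steps on


class TestGradients:
    @pytest.mark.parametrize("kind", ["astro", "depression", "rnn"])
    def test_backprop_matches_finite_differences(self, kind):
        rng = np.random.default_rng(21)
        config = HeadConfig(model_kind=kind, input_dim=6, hidden_dim=4)
        head = make_head(config, rng=np.random.default_rng(31))
        inputs, readout_steps, labels = tiny_batch(rng)
        targets = (labels + 1) / 2.0
        probs, cache = head.forward_batch(inputs)
        p = probs[np.arange(len(targets)), readout_steps]
        dz = (p - targets) / len(targets)
        analytic = head.backward_batch(cache, dz, readout_steps)
        numeric = numeric_gradients(head, inputs, readout_steps, targets)
        for name in analytic:
            a, n = analytic[name], numeric[name]
            scale = max(np.abs(n).max(), 1e-8)
            assert np.abs(a - n).max() / scale < 1e-4, name


class TestReadout:
    def _session(self):
        return generate_session(TaskConfig(), +1, np.random.default_rng(0))

    def test_constant_output(self):
        session = self._session()
        probs = np.full(200, 0.7)
        assert readout(probs, session) == pytest.approx(0.7)

    def test_window_one_is_single_step(self):
        session = self._session()
        probs = np.random.default_rng(0).random(200)
        assert readout(probs, session, window=1) == probs[session.event_step]

    def test_max_window_dominates(self):
        session = self._session()
        probs = np.random.default_rng(0).random(200)
        single = readout(probs, session, window=1)
        assert readout(probs, session, window=3, mode="max") >= single

    def test_out_of_range_rejected(self):
        session = self._session()
        with pytest.raises(ValueError):
            readout(np.ones(session.event_step), session)


class TestTraining:
    def test_infinite_threshold_runs_all_epochs(self, short_task, bank):
        head = make_head(HeadConfig(model_kind="depression"), rng=np.random.default_rng(0))
        config = TrainConfig(n_epochs=5, dprime_threshold=math.inf, seed=1)
        result = train_head(head, short_task, bank, config)
        assert result.epochs_run == 5
        assert result.stop_reason == "max_epochs"
        assert len(result.losses) == len(result.dprimes) == 5

    def test_separable_task_learns_and_stops_early(self, short_task):
        """Orthogonal features, no omissions: loss falls, early stop fires."""
        from astromem.encoder import FeatureBank

        vectors = np.zeros((8, 64))
        for i in range(8):
            vectors[i, i * 8 : (i + 1) * 8] = 1.0
        bank = FeatureBank(vectors=vectors)
        task = TaskConfig(
            length_ms=short_task.length_ms, omission_rate=0.0,
            min_repeats=short_task.min_repeats, max_repeats=short_task.max_repeats,
        )
        head = make_head(HeadConfig(model_kind="astro"), rng=np.random.default_rng(3))
        config = TrainConfig(
            n_epochs=400, dprime_threshold=1.5, patience=5, seed=4,
            learning_rate=5e-3,
        )
        result = train_head(head, task, bank, config)
        assert result.stop_reason == "early_stop"
        early = np.mean(result.losses[:10])
        late = np.mean(result.losses[-10:])
        assert late < early

    def test_fixed_seed_reproducible(self, short_task, bank):
        def run():
            head = make_head(
                HeadConfig(model_kind="rnn"), rng=np.random.default_rng(7)
            )
            return train_head(
                head, short_task, bank, TrainConfig(n_epochs=4, seed=2)
            )

        a, b = run(), run()
        assert a.losses == b.losses
        assert a.dprimes == b.dprimes

    def test_result_csv(self, short_task, bank, tmp_path):
        head = make_head(HeadConfig(model_kind="depression"))
        result = train_head(head, short_task, bank, TrainConfig(n_epochs=3, seed=0))
        path = tmp_path / "curves.csv"
        result.to_csv(path)
        import pandas as pd

        frame = pd.read_csv(path)
        assert list(frame.columns) == ["epoch", "loss", "dprime"]
        assert len(frame) == 3

    def test_weights_save_load(self, tmp_path):
        head = make_head(HeadConfig(model_kind="astro"), rng=np.random.default_rng(1))
        path = tmp_path / "weights.npz"
        head.save(path)
        other = make_head(HeadConfig(model_kind="astro"), rng=np.random.default_rng(99))
        other.load(path)
        for k, v in head.parameters().items():
            assert np.array_equal(other.parameters()[k], v)


class TestEvaluate:
    def test_paired_sessions_identical_inputs(self, short_task, bank):
        sessions = [
            generate_session(short_task, lab, np.random.default_rng(6))
            for lab in (1, 1, -1, -1)
        ]
        head = make_head(HeadConfig(model_kind="depression"))
        r1, o1 = evaluate_head(
            head, short_task, bank, 2, 2, np.random.default_rng(0), sessions=sessions
        )
        r2, o2 = evaluate_head(
            head, short_task, bank, 2, 2, np.random.default_rng(0), sessions=sessions
        )
        assert np.array_equal(o1.predictions, o2.predictions)
        assert r1.dprime == r2.dprime

    def test_outcome_annotations_recover_transitions(self, short_task, bank):
        rng = np.random.default_rng(12)
        _, outcome = evaluate_head(
            head=make_head(HeadConfig(model_kind="astro")),
            task_config=short_task,
            bank=bank,
            n_go=5,
            n_catch=5,
            rng=rng,
        )
        go = outcome.labels == 1
        assert np.all(outcome.pre_images[go] != outcome.post_images[go])
        assert np.all(outcome.pre_images[~go] == outcome.post_images[~go])
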