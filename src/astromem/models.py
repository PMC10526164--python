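"""Trainable short-term-memory heads and their training loop.

Three comparable heads share the 64-16-1 layout:

* ``"astro"`` — depressing synapses with astrocytic modulation of release
  probability gate the input (effective drive ``u * x * M[t]``) of a
  rectified feedforward layer;
* ``"depression"`` — same, but the release probability is pinned at its
  baseline (depression-only dynamics);
* ``"rnn"`` — a recurrent tanh layer with no synaptic state, carrying
  memory in its hidden activity.

All heads emit a per-step response probability through a logistic output
unit. Training minimizes binary cross-entropy at each trial's decision
step under the Adam optimizer, with early stopping driven by the d-prime
metric: the patience counter resets while d-prime is below threshold,
increments once it reaches it, and training halts when the counter hits
the patience limit.

Everything is plain NumPy with hand-written gradients (the heads are tiny),
which keeps runs exactly reproducible from a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.special import expit

from astromem import synapse as syn
from astromem.encoder import FeatureBank
from astromem.metrics import (
    DetectionOutcome,
    DPrimeResult,
    dprime,
    sample_responses,
)
from astromem.task import (
    Session,
    TaskConfig,
    encode_session,
    generate_session,
    make_batch,
)

__all__ = [
    "MODEL_KINDS",
    "HeadConfig",
    "TrainConfig",
    "TrainResult",
    "SynapticHead",
    "RecurrentHead",
    "make_head",
    "train_head",
    "evaluate_head",
    "readout",
]

MODEL_KINDS = ("astro", "depression", "rnn")


@dataclass(frozen=True)
class HeadConfig:
    """Architecture of one model head.

    ``detach_plasticity`` is kept for interface parity: because the synapse
    variables depend only on the input drive (never on trainable weights),
    detaching them from the gradient graph cannot change any weight
    gradient, so both settings are computationally identical here.
    """

    model_kind: str = "astro"
    input_dim: int = 64
    hidden_dim: int = 16
    output_dim: int = 1
    rec_gain: float = 0.9  # spectral scale of the recurrent matrix (rnn only)
    detach_plasticity: bool = True

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
        if self.output_dim != 1:
            raise ValueError("heads have a single output unit")
        if self.input_dim < 1 or self.hidden_dim < 1:
            raise ValueError("layer widths must be positive")


class _Head:
    """Shared parameter plumbing for the trainable heads."""

    config: HeadConfig

    def parameters(self) -> Dict[str, np.ndarray]:
        raise NotImplementedError

    def set_parameters(self, values: Dict[str, np.ndarray]) -> None:
        params = self.parameters()
        for name, value in values.items():
            params[name][...] = value

    def save(self, path) -> None:
        np.savez(path, **self.parameters())

    def load(self, path) -> "_Head":
        data = np.load(path)
        self.set_parameters({k: data[k] for k in data.files})
        return self

    def clone_weights_from(self, other: "_Head") -> None:
        self.set_parameters({k: v.copy() for k, v in other.parameters().items()})


class SynapticHead(_Head):
    """Feedforward 64-16-1 head gated by depressing-synapse dynamics.

    Each input unit carries an independent ``(x, y, u)`` synapse state; the
    hidden layer sees the effective drive ``u * x * M[t]``. With
    ``astro=False`` the release probability stays at ``u0``.
    """

    def __init__(
        self,
        config: HeadConfig,
        synapse_params: Optional[syn.SynapseParams] = None,
        astro: bool = True,
        rng: Optional[np.random.Generator] = None,
    ):
        if rng is None:
            rng = np.random.default_rng(0)
        self.config = config
        self.synapse_params = synapse_params or syn.SynapseParams()
        self.astro = astro
        n_in, n_hid = config.input_dim, config.hidden_dim
        self.W1 = rng.normal(0.0, math.sqrt(2.0 / n_in), size=(n_in, n_hid))
        self.b1 = np.zeros(n_hid)
        self.w2 = rng.normal(0.0, math.sqrt(2.0 / n_hid), size=n_hid)
        self.b2 = 0.0

    def parameters(self) -> Dict[str, np.ndarray]:
        if not isinstance(self.b2, np.ndarray):
            self.b2 = np.asarray(float(self.b2)).reshape(())
        return {"W1": self.W1, "b1": self.b1, "w2": self.w2, "b2": self.b2}

    # -- dynamics ----------------------------------------------------------

    def _gain(self, inputs: np.ndarray) -> np.ndarray:
        """Per-step synaptic gain ``u*x`` for a batch, shape = inputs."""
        p = self.synapse_params
        B, T, n = inputs.shape
        x = np.ones((B, n))
        y = np.zeros((B, n))
        u = (
            np.broadcast_to(syn.release_probability(0.0, p), (B, n)).copy()
            if self.astro
            else np.full((B, n), p.u0)
        )
        gain = np.empty_like(inputs)
        for t in range(T):
            gain[:, t] = u * x
            x, y, u = syn.advance(x, y, u, inputs[:, t], p, dt=1.0, astro=self.astro)
        return gain

    # -- forward / backward ------------------------------------------------

    def forward(
        self, M: np.ndarray, initial: Optional[syn.SynapseState] = None
    ) -> Tuple[np.ndarray, syn.SynapseTrajectory]:
        """Per-step response probabilities and the synapse trajectory.

        ``M`` has shape ``(T, input_dim)`` and must be nonnegative.
        """
        M = np.asarray(M, dtype=float)
        if np.any(M < 0):
            raise ValueError("synaptic heads require nonnegative input")
        trajectory = syn.simulate_trace(
            syn.DriveTrace(values=M), self.synapse_params, initial=initial,
            astro=self.astro,
        )
        e = trajectory.effective_series
        h = np.maximum(e @ self.W1 + self.b1, 0.0)
        probs = expit(h @ self.w2 + float(self.b2))
        return probs, trajectory

    def forward_batch(self, inputs: np.ndarray) -> Tuple[np.ndarray, tuple]:
        if np.any(inputs < 0):
            raise ValueError("synaptic heads require nonnegative input")
        e = self._gain(inputs) * inputs  # (B, T, n_in)
        hpre = e @ self.W1 + self.b1
        h = np.maximum(hpre, 0.0)
        probs = expit(h @ self.w2 + float(self.b2))  # (B, T)
        return probs, (e, hpre, h)

    def backward_batch(
        self, cache: tuple, dz: np.ndarray, readout_steps: np.ndarray
    ) -> Dict[str, np.ndarray]:
        """Gradients of the readout-step loss; ``dz`` is dL/dz per trial."""
        e, hpre, h = cache
        B = dz.shape[0]
        idx = np.arange(B)
        er = e[idx, readout_steps]
        hr = h[idx, readout_steps]
        relu_mask = hpre[idx, readout_steps] > 0
        dw2 = hr.T @ dz
        db2 = np.asarray(dz.sum()).reshape(())
        dh = dz[:, None] * self.w2
        dhpre = dh * relu_mask
        dW1 = er.T @ dhpre
        db1 = dhpre.sum(axis=0)
        return {"W1": dW1, "b1": db1, "w2": dw2, "b2": db2}


class RecurrentHead(_Head):
    """Recurrent 64-16-1 baseline carrying memory in its hidden state."""

    def __init__(self, config: HeadConfig, rng: Optional[np.random.Generator] = None):
        if rng is None:
            rng = np.random.default_rng(0)
        self.config = config
        n_in, n_hid = config.input_dim, config.hidden_dim
        self.W_in = rng.normal(0.0, 1.0 / math.sqrt(n_in), size=(n_hid, n_in))
        self.W_rec = rng.normal(0.0, 1.0 / math.sqrt(n_hid), size=(n_hid, n_hid))
        self.W_rec *= config.rec_gain
        self.b_h = np.zeros(n_hid)
        self.w_out = rng.normal(0.0, math.sqrt(2.0 / n_hid), size=n_hid)
        self.b_out = 0.0

    def parameters(self) -> Dict[str, np.ndarray]:
        if not isinstance(self.b_out, np.ndarray):
            self.b_out = np.asarray(float(self.b_out)).reshape(())
        return {
            "W_in": self.W_in,
            "W_rec": self.W_rec,
            "b_h": self.b_h,
            "w_out": self.w_out,
            "b_out": self.b_out,
        }

    def forward(
        self, M: np.ndarray, hidden: Optional[np.ndarray] = None
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Per-step response probabilities and the hidden-state series."""
        M = np.asarray(M, dtype=float)
        probs, (_, hs) = self.forward_batch(M[None], hidden=None if hidden is None else hidden[None])
        return probs[0], hs[0]

    def forward_batch(
        self, inputs: np.ndarray, hidden: Optional[np.ndarray] = None
    ) -> Tuple[np.ndarray, tuple]:
        B, T, _ = inputs.shape
        n_hid = self.config.hidden_dim
        h = np.zeros((B, n_hid)) if hidden is None else np.asarray(hidden, dtype=float)
        hs = np.empty((B, T, n_hid))
        for t in range(T):
            h = np.tanh(inputs[:, t] @ self.W_in.T + h @ self.W_rec.T + self.b_h)
            hs[:, t] = h
        probs = expit(hs @ self.w_out + float(self.b_out))
        return probs, (inputs, hs)

    def backward_batch(
        self, cache: tuple, dz: np.ndarray, readout_steps: np.ndarray
    ) -> Dict[str, np.ndarray]:
        """Backpropagation through time from each trial's readout step."""
        inputs, hs = cache
        B, T, n_hid = hs.shape
        grads = {
            "W_in": np.zeros_like(self.W_in),
            "W_rec": np.zeros_like(self.W_rec),
            "b_h": np.zeros_like(self.b_h),
            "w_out": np.zeros_like(self.w_out),
            "b_out": np.zeros(()),
        }
        dh = np.zeros((B, n_hid))
        for t in range(T - 1, -1, -1):
            at_readout = readout_steps == t
            if at_readout.any():
                grads["w_out"] += hs[at_readout, t].T @ dz[at_readout]
                grads["b_out"] += dz[at_readout].sum()
                dh[at_readout] += dz[at_readout, None] * self.w_out
            if not dh.any():
                continue
            da = dh * (1.0 - hs[:, t] ** 2)
            grads["W_in"] += da.T @ inputs[:, t]
            h_prev = hs[:, t - 1] if t > 0 else np.zeros((B, n_hid))
            grads["W_rec"] += da.T @ h_prev
            grads["b_h"] += da.sum(axis=0)
            dh = da @ self.W_rec
        return grads


def make_head(
    config: HeadConfig,
    synapse_params: Optional[syn.SynapseParams] = None,
    rng: Optional[np.random.Generator] = None,
) -> _Head:
    """Instantiate the head named by ``config.model_kind``."""
    if config.model_kind == "astro":
        return SynapticHead(config, synapse_params, astro=True, rng=rng)
    if config.model_kind == "depression":
        params = synapse_params or syn.SynapseParams()
        return SynapticHead(config, params, astro=False, rng=rng)
    return RecurrentHead(config, rng=rng)


def readout(
    probs: np.ndarray, session: Session, window: int = 1, mode: str = "max"
) -> float:
    """Per-trial response probability at the decision step.

    Takes the output at ``session.event_step``; with ``window > 1`` the
    probabilities over ``[event_step, event_step + window)`` (clipped to the
    session) are pooled by ``mode`` (``"max"`` or ``"mean"``).
    """
    T = len(probs)
    start = session.event_step
    if not 0 <= start < T:
        raise ValueError(f"readout step {start} out of range [0, {T})")
    if window < 1:
        raise ValueError("window must be at least 1")
    stop = min(start + window, T)
    chunk = np.asarray(probs[start:stop], dtype=float)
    if mode == "max":
        return float(chunk.max())
    if mode == "mean":
        return float(chunk.mean())
    raise ValueError(f"unknown readout mode {mode!r}")


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer, loss, and early-stopping settings."""

    n_epochs: int = 400
    learning_rate: float = 3e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    dprime_threshold: float = 1.5  # set to inf to disable early stopping
    patience: int = 10
    n_go: int = 16
    n_catch: int = 16
    sigma_mode: str = "pooled"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be at least 1")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be positive")
        if math.isnan(self.dprime_threshold):
            raise ValueError("dprime_threshold must be a number or +inf")


@dataclass
class TrainResult:
    """Per-epoch training diagnostics and the trained head."""

    losses: List[float]
    dprimes: List[float]
    epochs_run: int
    stop_reason: str  # "max_epochs" | "early_stop"
    head: _Head

    def __post_init__(self) -> None:
        if not (len(self.losses) == len(self.dprimes) == self.epochs_run):
            raise ValueError("diagnostic series must match epochs_run")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(self.epochs_run),
                "loss": self.losses,
                "dprime": self.dprimes,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class Adam:
    """Textbook adaptive-moment optimizer over a named parameter dict."""

    def __init__(self, params: Dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v, dtype=float) for k, v in params.items()}
        self.v = {k: np.zeros_like(v, dtype=float) for k, v in params.items()}
        self.t = 0

    def step(self, grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, grad in grads.items():
            self.m[key] = b1 * self.m[key] + (1 - b1) * grad
            self.v[key] = b2 * self.v[key] + (1 - b2) * grad**2
            m_hat = self.m[key] / (1 - b1**self.t)
            v_hat = self.v[key] / (1 - b2**self.t)
            self.params[key] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _bce(probs: np.ndarray, targets: np.ndarray) -> float:
    p = np.clip(probs, 1e-12, 1 - 1e-12)
    return float(-np.mean(targets * np.log(p) + (1 - targets) * np.log(1 - p)))


def train_head(
    head: _Head,
    task_config: TaskConfig,
    bank: FeatureBank,
    train_config: TrainConfig,
) -> TrainResult:
    """Fit a head on freshly generated sessions, epoch by epoch.

    Each epoch draws a new batch (``n_go`` Go + ``n_catch`` Catch
    sessions), runs the forward pass, computes binary cross-entropy between
    the readout-step probability and the binarized label (Go -> 1,
    Catch -> 0), backpropagates, and applies one Adam update. The epoch
    d-prime is computed on sampled responses from the same batch; early
    stopping follows the threshold/patience rule described in the module
    docstring.

    Raises
    ------
    FloatingPointError
        If the loss becomes non-finite.
    """
    root = np.random.SeedSequence(train_config.seed)
    batch_rng, response_rng = (np.random.default_rng(s) for s in root.spawn(2))
    optimizer = Adam(
        head.parameters(),
        lr=train_config.learning_rate,
        beta1=train_config.adam_beta1,
        beta2=train_config.adam_beta2,
        eps=train_config.adam_eps,
    )
    losses: List[float] = []
    dprimes: List[float] = []
    wait_count = 0
    stop_reason = "max_epochs"
    for epoch in range(train_config.n_epochs):
        batch = make_batch(
            task_config, train_config.n_go, train_config.n_catch, bank, batch_rng
        )
        probs, cache = head.forward_batch(batch.inputs)
        idx = np.arange(len(batch))
        readout_probs = probs[idx, batch.readout_steps]
        targets = (batch.labels + 1) / 2.0
        loss = _bce(readout_probs, targets)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch} (model {head.config.model_kind})"
            )
        dz = (readout_probs - targets) / len(batch)
        grads = head.backward_batch(cache, dz, batch.readout_steps)
        optimizer.step(grads)

        predictions = sample_responses(readout_probs, response_rng)
        outcome = DetectionOutcome(predictions=predictions, labels=batch.labels)
        d = dprime(outcome, sigma_mode=train_config.sigma_mode).dprime
        losses.append(loss)
        dprimes.append(d)
        if d < train_config.dprime_threshold:
            wait_count = 0
        else:
            wait_count += 1
            if wait_count >= train_config.patience:
                stop_reason = "early_stop"
                break
    return TrainResult(
        losses=losses,
        dprimes=dprimes,
        epochs_run=len(losses),
        stop_reason=stop_reason,
        head=head,
    )


def evaluate_head(
    head: _Head,
    task_config: TaskConfig,
    bank: FeatureBank,
    n_go: int,
    n_catch: int,
    rng: np.random.Generator,
    sigma_mode: str = "pooled",
    window: int = 1,
    sessions: Optional[List[Session]] = None,
    n_blocks: Optional[int] = None,
) -> Tuple[DPrimeResult, DetectionOutcome]:
    """Evaluate a trained head on fresh (or supplied) sessions.

    Returns the d-prime summary together with the full per-trial outcome,
    annotated with (pre_image, post_image) transitions for downstream
    response-matrix analysis. Passing the same ``sessions`` list to several
    heads yields a paired comparison.
    """
    if sessions is None:
        labels = [+1] * n_go + [-1] * n_catch
        sessions = [generate_session(task_config, lab, rng) for lab in labels]
    inputs = np.stack([encode_session(s, bank) for s in sessions])
    labels_arr = np.asarray([s.label for s in sessions], dtype=int)
    probs, _ = head.forward_batch(inputs)
    readout_probs = np.asarray(
        [readout(probs[i], s, window=window) for i, s in enumerate(sessions)]
    )
    predictions = sample_responses(readout_probs, rng)
    block_ids = None
    if n_blocks is not None:
        block_ids = np.arange(len(sessions)) % n_blocks
    outcome = DetectionOutcome(
        predictions=predictions,
        labels=labels_arr,
        s_omega=np.clip(readout_probs, 1e-12, 1 - 1e-12),
        block_ids=block_ids,
        pre_images=np.asarray([s.pre_image for s in sessions]),
        post_images=np.asarray([s.post_image for s in sessions]),
    )
    result = dprime(outcome, sigma_mode=sigma_mode)
    return result, outcome
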