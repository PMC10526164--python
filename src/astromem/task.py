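"""Simulated visual change-detection sessions.

A session is a train of image flashes (one flash = one 250 ms step)
separated by gray-screen steps (default 500 ms = 2 steps). The same image
repeats until a single event flash, at which the image either switches to a
different one (Go trial, label +1) or repeats unchanged (Catch trial,
label -1). A small fraction of flashes is omitted (replaced by gray), but
never the flash immediately preceding the event nor the event flash itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from astromem.encoder import FeatureBank

__all__ = [
    "TaskConfig",
    "Session",
    "TrialBatch",
    "n_steps",
    "generate_session",
    "encode_session",
    "make_batch",
]


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the change-detection task simulator.

    Defaults follow the behavioral protocol: 50,000 ms sessions sampled at
    250 ms (one flash duration, so 200 steps), 500 ms gray screens between
    flashes, 8 images, 5% omissions. ``min_repeats``/``max_repeats`` bound
    the number of same-image flashes shown before the (sham-)change event.
    """

    length_ms: int = 50_000
    time_step_ms: int = 250
    gray_steps: int = 2
    n_images: int = 8
    omission_rate: float = 0.05
    min_repeats: int = 4
    max_repeats: int = 11
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.time_step_ms <= 0 or self.length_ms <= 0:
            raise ValueError("durations must be positive")
        if self.length_ms % self.time_step_ms != 0:
            raise ValueError(
                f"length_ms ({self.length_ms}) must be divisible by "
                f"time_step_ms ({self.time_step_ms})"
            )
        if not 0 <= self.omission_rate < 1:
            raise ValueError("omission_rate must lie in [0, 1)")
        if self.n_images < 2:
            raise ValueError("n_images must be at least 2")
        if not 1 <= self.min_repeats <= self.max_repeats:
            raise ValueError("need 1 <= min_repeats <= max_repeats")
        if self.gray_steps < 0:
            raise ValueError("gray_steps must be nonnegative")
        period = 1 + self.gray_steps
        n_flashes = (self.length_ms // self.time_step_ms + period - 1) // period
        if self.max_repeats >= n_flashes:
            raise ValueError(
                f"max_repeats={self.max_repeats} leaves no room for the "
                f"event among {n_flashes} flashes"
            )


def n_steps(config: TaskConfig) -> int:
    """Number of simulation steps in one session (length / flash duration)."""
    return config.length_ms // config.time_step_ms


@dataclass(frozen=True)
class Session:
    """One simulated change-detection run.

    ``flash_steps`` are the step indices of scheduled flashes (period
    ``1 + gray_steps``); ``image_ids`` and ``omitted`` run parallel to it.
    ``event_flash`` indexes the (sham-)change flash within those arrays and
    ``event_step`` is the corresponding step index, where the decision
    readout happens.
    """

    n_steps: int
    flash_steps: np.ndarray
    image_ids: np.ndarray
    omitted: np.ndarray
    event_flash: int
    event_step: int
    label: int
    pre_image: int
    post_image: int

    def __post_init__(self) -> None:
        if self.label not in (+1, -1):
            raise ValueError("label must be +1 (Go) or -1 (Catch)")
        if self.label == +1 and self.post_image == self.pre_image:
            raise ValueError("Go trial requires post_image != pre_image")
        if self.label == -1 and self.post_image != self.pre_image:
            raise ValueError("Catch trial requires post_image == pre_image")
        if self.event_flash >= 1 and self.omitted[self.event_flash - 1]:
            raise ValueError("flash preceding the event must not be omitted")
        if self.omitted[self.event_flash]:
            raise ValueError("event flash must not be omitted")

    def to_dict(self) -> dict:
        return {
            "n_steps": int(self.n_steps),
            "flash_steps": [int(s) for s in self.flash_steps],
            "image_ids": [int(i) for i in self.image_ids],
            "omitted": [bool(o) for o in self.omitted],
            "event_flash": int(self.event_flash),
            "event_step": int(self.event_step),
            "label": int(self.label),
            "pre_image": int(self.pre_image),
            "post_image": int(self.post_image),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Session":
        return cls(
            n_steps=d["n_steps"],
            flash_steps=np.asarray(d["flash_steps"], dtype=int),
            image_ids=np.asarray(d["image_ids"], dtype=int),
            omitted=np.asarray(d["omitted"], dtype=bool),
            event_flash=d["event_flash"],
            event_step=d["event_step"],
            label=d["label"],
            pre_image=d["pre_image"],
            post_image=d["post_image"],
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "Session":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def generate_session(
    config: TaskConfig, label: int, rng: np.random.Generator
) -> Session:
    """Draw one Go (+1) or Catch (-1) session.

    The flash schedule covers the whole session with period
    ``1 + gray_steps``. The pre-event image is uniform over the bank; on Go
    trials the post-event image is uniform over the remaining images. The
    number of pre-event flashes is uniform on
    ``[min_repeats, max_repeats]``. Omissions are independent Bernoulli
    draws at ``omission_rate``, forced off at the event flash and the flash
    immediately before it.
    """
    if label not in (+1, -1):
        raise ValueError("label must be +1 or -1")
    T = n_steps(config)
    period = 1 + config.gray_steps
    flash_steps = np.arange(0, T, period)
    n_flashes = len(flash_steps)

    repeats = int(rng.integers(config.min_repeats, config.max_repeats + 1))
    event_flash = repeats  # flashes 0..repeats-1 show the pre-image
    pre_image = int(rng.integers(config.n_images))
    if label == +1:
        offset = int(rng.integers(1, config.n_images))
        post_image = (pre_image + offset) % config.n_images
    else:
        post_image = pre_image

    image_ids = np.full(n_flashes, post_image, dtype=int)
    image_ids[:event_flash] = pre_image

    omitted = rng.random(n_flashes) < config.omission_rate
    omitted[event_flash - 1] = False
    omitted[event_flash] = False

    return Session(
        n_steps=T,
        flash_steps=flash_steps,
        image_ids=image_ids,
        omitted=omitted,
        event_flash=event_flash,
        event_step=int(flash_steps[event_flash]),
        label=label,
        pre_image=pre_image,
        post_image=post_image,
    )


def encode_session(session: Session, bank: FeatureBank) -> np.ndarray:
    """Session input matrix of shape ``(n_steps, feature_dim)``.

    Row ``t`` is the feature vector of the flashed image at non-omitted
    flash steps and the zero vector during gray or omitted steps.
    """
    vectors = bank.vectors
    if session.image_ids.size and session.image_ids.max() >= vectors.shape[0]:
        raise ValueError(
            f"session references image {int(session.image_ids.max())} but the "
            f"bank has only {vectors.shape[0]} rows"
        )
    M = np.zeros((session.n_steps, vectors.shape[1]))
    shown = ~session.omitted
    M[session.flash_steps[shown]] = vectors[session.image_ids[shown]]
    return M


@dataclass(frozen=True)
class TrialBatch:
    """Stack of encoded sessions with labels and decision steps."""

    inputs: np.ndarray  # (B, T, feature_dim), nonnegative
    labels: np.ndarray  # (B,), values in {+1, -1}
    readout_steps: np.ndarray  # (B,)
    sessions: List[Session] = field(default_factory=list)

    def __post_init__(self) -> None:
        B = self.inputs.shape[0]
        if not (len(self.labels) == len(self.readout_steps) == B):
            raise ValueError("one label and one readout step per session")
        if np.any(self.inputs < 0):
            raise ValueError("inputs must be nonnegative")

    def __len__(self) -> int:
        return self.inputs.shape[0]


def make_batch(
    config: TaskConfig,
    n_go: int,
    n_catch: int,
    bank: FeatureBank,
    rng: np.random.Generator,
) -> TrialBatch:
    """Generate and encode ``n_go`` Go plus ``n_catch`` Catch sessions."""
    if n_go < 0 or n_catch < 0:
        raise ValueError("counts must be nonnegative")
    if n_go + n_catch == 0:
        raise ValueError("batch must contain at least one session")
    labels = [+1] * n_go + [-1] * n_catch
    sessions = [generate_session(config, lab, rng) for lab in labels]
    inputs = np.stack([encode_session(s, bank) for s in sessions])
    return TrialBatch(
        inputs=inputs,
        labels=np.asarray(labels, dtype=int),
        readout_steps=np.asarray([s.event_step for s in sessions], dtype=int),
        sessions=sessions,
    )
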