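"""Behavioral evaluation statistics.

The detection pipeline maps raw model outputs through a logistic squash to
response probabilities, samples binary responses from per-trial Bernoulli
distributions, and summarizes them as hit / false-alarm rates and a
d-prime detectability index (rate difference divided by a variability
term). Stimulus-transition structure is summarized by an
``n_images x n_images`` response-probability matrix and its
symmetric/antisymmetric decomposition, from which a normalized asymmetry
index in ``[-1, 1]`` is derived.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "DetectionOutcome",
    "DPrimeResult",
    "ResponseMatrix",
    "AsymmetryResult",
    "squash",
    "sample_responses",
    "hit_false_rates",
    "dprime",
    "dprime_from_block_rates",
    "response_matrix",
    "sym_antisym",
    "asymmetry_index",
]

SIGMA_FLOOR = 1e-6


def squash(omega: np.ndarray) -> np.ndarray:
    """Elementwise logistic map to (0, 1)."""
    return expit(np.asarray(omega, dtype=float))


def sample_responses(
    probabilities: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Independent Bernoulli draws, one per probability.

    Raises
    ------
    ValueError
        If any probability falls outside [0, 1].
    """
    p = np.asarray(probabilities, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return (rng.random(p.shape) < p).astype(int)


@dataclass(frozen=True)
class DetectionOutcome:
    """Per-trial responses with labels and optional trial annotations.

    ``labels`` are +1 (Go, image changed) or -1 (Catch, sham change);
    ``predictions`` are sampled binary responses. ``s_omega`` keeps the
    underlying response probabilities for analytic (sampling-free) rates;
    ``block_ids`` group trials for block-wise variance estimation;
    ``pre_images``/``post_images`` carry the stimulus transition of each
    trial for response-matrix bookkeeping.
    """

    predictions: np.ndarray
    labels: np.ndarray
    s_omega: Optional[np.ndarray] = None
    omega: Optional[np.ndarray] = None
    block_ids: Optional[np.ndarray] = None
    pre_images: Optional[np.ndarray] = None
    post_images: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        predictions = np.asarray(self.predictions, dtype=int)
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "predictions", predictions)
        object.__setattr__(self, "labels", labels)
        if predictions.shape != labels.shape:
            raise ValueError("predictions and labels must have equal length")
        if not np.all(np.isin(predictions, (0, 1))):
            raise ValueError("predictions must be binary")
        if not np.all(np.isin(labels, (-1, 1))):
            raise ValueError("labels must be +1 or -1")
        for name in ("s_omega", "omega", "block_ids", "pre_images", "post_images"):
            value = getattr(self, name)
            if value is not None:
                value = np.asarray(value)
                object.__setattr__(self, name, value)
                if value.shape[0] != predictions.shape[0]:
                    raise ValueError(f"{name} must have one entry per trial")
        if self.s_omega is not None and (
            np.any(self.s_omega <= 0) or np.any(self.s_omega >= 1)
        ):
            raise ValueError("s_omega must lie strictly in (0, 1)")

    def __len__(self) -> int:
        return len(self.predictions)


def hit_false_rates(
    outcome: DetectionOutcome, analytic: bool = False
) -> tuple:
    """Mean response on Go trials (hit rate) and Catch trials (false rate).

    With ``analytic=True`` the expected rates are computed from the stored
    response probabilities instead of the sampled binary responses.
    """
    go = outcome.labels == 1
    catch = outcome.labels == -1
    if not go.any() or not catch.any():
        raise ValueError("need at least one Go and one Catch trial")
    if analytic:
        if outcome.s_omega is None:
            raise ValueError("analytic rates require s_omega")
        values = outcome.s_omega
    else:
        values = outcome.predictions
    return float(np.mean(values[go])), float(np.mean(values[catch]))


@dataclass(frozen=True)
class DPrimeResult:
    """Detectability index with its ingredients."""

    hit_rate: float
    false_rate: float
    sigma: float
    dprime: float
    n_go: int
    n_catch: int
    sigma_mode: str


def _pooled_sigma(outcome: DetectionOutcome, analytic: bool) -> float:
    values = outcome.s_omega if analytic else outcome.predictions
    return float(np.std(np.asarray(values, dtype=float)))


def dprime(
    outcome: DetectionOutcome,
    sigma_mode: str = "pooled",
    sigma: Optional[float] = None,
    analytic: bool = False,
    eps: float = SIGMA_FLOOR,
) -> DPrimeResult:
    """Detectability index ``(hit_rate - false_rate) / sigma``.

    ``sigma_mode`` selects the variability term:

    ``"pooled"`` (default)
        Standard deviation of the pooled per-trial responses (Go and Catch
        together). For balanced classes this bounds the index by 2.
    ``"blocks"``
        Per-block hit/false rates are computed over ``outcome.block_ids``
        (at least two blocks required); sigma is the sample standard
        deviation (ddof=1) of the per-block rate differences and the
        numerator is the mean block difference.
    ``"fixed"``
        Caller-supplied ``sigma``.

    Sigma is floored at ``eps`` so a perfect detector stays finite.
    """
    hit, false = hit_false_rates(outcome, analytic=analytic)
    n_go = int(np.sum(outcome.labels == 1))
    n_catch = int(np.sum(outcome.labels == -1))
    if sigma_mode == "pooled":
        sig = _pooled_sigma(outcome, analytic)
        numerator = hit - false
    elif sigma_mode == "blocks":
        if outcome.block_ids is None:
            raise ValueError("blocks mode requires block_ids")
        blocks = np.unique(outcome.block_ids)
        if len(blocks) < 2:
            raise ValueError("blocks mode requires at least two blocks")
        diffs = []
        for b in blocks:
            sel = outcome.block_ids == b
            sub = DetectionOutcome(
                predictions=outcome.predictions[sel],
                labels=outcome.labels[sel],
                s_omega=None if outcome.s_omega is None else outcome.s_omega[sel],
            )
            h, f = hit_false_rates(sub, analytic=analytic)
            diffs.append(h - f)
        diffs = np.asarray(diffs)
        sig = float(np.std(diffs, ddof=1))
        numerator = float(np.mean(diffs))
    elif sigma_mode == "fixed":
        if sigma is None:
            raise ValueError("fixed mode requires sigma")
        sig = float(sigma)
        numerator = hit - false
    else:
        raise ValueError(f"unknown sigma_mode {sigma_mode!r}")
    sig_floored = max(sig, eps)
    return DPrimeResult(
        hit_rate=hit,
        false_rate=false,
        sigma=sig_floored,
        dprime=numerator / sig_floored,
        n_go=n_go,
        n_catch=n_catch,
        sigma_mode=sigma_mode,
    )


def dprime_from_block_rates(
    hit_rates: Sequence[float],
    false_rates: Sequence[float],
    eps: float = SIGMA_FLOOR,
) -> float:
    """Block-mode d-prime straight from per-block (hit, false) rate pairs."""
    hit_rates = np.asarray(hit_rates, dtype=float)
    false_rates = np.asarray(false_rates, dtype=float)
    if hit_rates.shape != false_rates.shape or hit_rates.ndim != 1:
        raise ValueError("need matching 1-D rate sequences")
    if len(hit_rates) < 2:
        raise ValueError("need at least two blocks")
    diffs = hit_rates - false_rates
    sig = max(float(np.std(diffs, ddof=1)), eps)
    return float(np.mean(diffs)) / sig


@dataclass(frozen=True)
class ResponseMatrix:
    """Mean response probability per ordered image transition.

    ``probs[i, j]`` is the mean sampled response over trials whose image
    transition was ``i -> j`` (diagonal cells come only from Catch trials);
    cells with no trials hold NaN and a zero count.
    """

    probs: np.ndarray
    counts: np.ndarray

    @property
    def n_images(self) -> int:
        return self.probs.shape[0]

    @property
    def empty_cells(self) -> np.ndarray:
        return self.counts == 0

    def to_csv(self, path) -> None:
        np.savetxt(path, self.probs, delimiter=",")


def response_matrix(
    outcome: DetectionOutcome, n_images: Optional[int] = None
) -> ResponseMatrix:
    """Aggregate sampled responses by (previous image, current image) pair."""
    if outcome.pre_images is None or outcome.post_images is None:
        raise ValueError("response_matrix requires pre/post image annotations")
    pre = np.asarray(outcome.pre_images, dtype=int)
    post = np.asarray(outcome.post_images, dtype=int)
    if n_images is None:
        n_images = int(max(pre.max(), post.max())) + 1
    sums = np.zeros((n_images, n_images))
    counts = np.zeros((n_images, n_images), dtype=int)
    np.add.at(sums, (pre, post), outcome.predictions)
    np.add.at(counts, (pre, post), 1)
    with np.errstate(invalid="ignore"):
        probs = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return ResponseMatrix(probs=probs, counts=counts)


def sym_antisym(matrix: np.ndarray) -> tuple:
    """Decompose ``M`` into ``(M + M.T)/2`` and ``(M - M.T)/2``."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    return (matrix + matrix.T) / 2.0, (matrix - matrix.T) / 2.0


@dataclass(frozen=True)
class AsymmetryResult:
    """Symmetric/antisymmetric split and the normalized asymmetry index."""

    m_sym: np.ndarray
    m_antisym: np.ndarray
    q: float
    convention: str
    defined: bool = True


def asymmetry_index(
    matrix: np.ndarray, convention: str = "centered-norm-diff"
) -> AsymmetryResult:
    """Normalized asymmetry of a square matrix, in ``[-1, 1]``.

    Conventions
    -----------
    ``"centered-norm-diff"`` (default)
        The matrix is first centered by its grand mean (the antisymmetric
        part is unaffected), then
        ``q = (||A||_F - ||S||_F) / (||S||_F + ||A||_F)`` where ``S``/``A``
        are the symmetric/antisymmetric parts. A purely symmetric centered
        matrix gives -1, a purely antisymmetric one +1.
    ``"norm-diff"``
        Same ratio without centering.

    A matrix whose both parts have zero norm yields ``q = nan`` with
    ``defined=False``.
    """
    matrix = np.asarray(matrix, dtype=float)
    if convention == "centered-norm-diff":
        work = matrix - matrix.mean()
    elif convention == "norm-diff":
        work = matrix
    else:
        raise ValueError(f"unknown convention {convention!r}")
    m_sym, m_antisym = sym_antisym(work)
    ns = float(np.linalg.norm(m_sym))
    na = float(np.linalg.norm(m_antisym))
    if ns + na == 0.0:
        return AsymmetryResult(
            m_sym=m_sym, m_antisym=m_antisym, q=float("nan"),
            convention=convention, defined=False,
        )
    q = (na - ns) / (ns + na)
    return AsymmetryResult(
        m_sym=m_sym, m_antisym=m_antisym, q=q, convention=convention
    )
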