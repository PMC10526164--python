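"""Mean-field model of a depressing synapse with astrocytic feedback.

The per-unit state is the triple ``(x, y, u)``:

* ``x`` — fraction of available synaptic resources, depleted by presynaptic
  drive with rate ``u * x * a(t)`` and recovering with time constant
  ``tau_d``;
* ``y`` — gliotransmitter concentration, produced at rate
  ``beta * Hy(x)`` (a steep sigmoid of the resource level) and relaxing with
  time constant ``tau_y``;
* ``u`` — release probability, a static sigmoid map of ``y`` bounded in
  ``(u0, u0 + delta_u0)``.

Time is measured in conventional units where one unit equals one image
flash (250 ms); integration uses the explicit Euler method with ``dt = 1``
by default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

ArrayLike = Union[float, np.ndarray]

__all__ = [
    "SynapseParams",
    "SynapseState",
    "DriveTrace",
    "SynapseTrajectory",
    "hy_activation",
    "release_probability",
    "euler_step",
    "advance",
    "simulate_trace",
    "steady_state",
]


@dataclass(frozen=True)
class SynapseParams:
    """Constants of the depressing-synapse / astrocyte dynamics.

    Defaults are the published parameter set: ``tau_d=6``, ``u0=0.23``,
    ``delta_u0=0.305``, ``tau_y=1.8``, ``beta=0.4375``, ``x_thr=0.5``,
    ``y_thr=0.573``, with sigmoid slopes 20 (resource gate) and 50
    (release-probability gate).
    """

    tau_d: float = 6.0
    u0: float = 0.23
    delta_u0: float = 0.305
    tau_y: float = 1.8
    beta: float = 0.4375
    x_thr: float = 0.5
    y_thr: float = 0.573
    slope_x: float = 20.0
    slope_y: float = 50.0

    def __post_init__(self) -> None:
        if not self.tau_d > 0:
            raise ValueError(f"tau_d must be positive, got {self.tau_d}")
        if not self.tau_y > 0:
            raise ValueError(f"tau_y must be positive, got {self.tau_y}")
        if self.beta < 0:
            raise ValueError(f"beta must be nonnegative, got {self.beta}")
        if not 0 < self.u0:
            raise ValueError(f"u0 must be positive, got {self.u0}")
        if self.delta_u0 < 0:
            raise ValueError(f"delta_u0 must be nonnegative, got {self.delta_u0}")
        if self.u0 + self.delta_u0 > 1:
            raise ValueError(
                f"u0 + delta_u0 must not exceed 1, got {self.u0 + self.delta_u0}"
            )

    def without_astrocyte(self) -> "SynapseParams":
        """Parameter set with gliotransmitter feedback disabled.

        Setting ``delta_u0 = 0`` and ``beta = 0`` pins the release
        probability to ``u0`` and freezes ``y`` at zero, reducing the model
        to pure short-term depression.
        """
        return dataclasses.replace(self, delta_u0=0.0, beta=0.0)


@dataclass(frozen=True)
class SynapseState:
    """Dynamical variables of one (or a vector of) synapse unit(s)."""

    x: ArrayLike
    y: ArrayLike
    u: ArrayLike

    def validate(self, params: Optional[SynapseParams] = None) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        u = np.asarray(self.u, dtype=float)
        if np.any(x < 0) or np.any(x > 1):
            raise ValueError("x must lie in [0, 1]")
        if np.any(y < 0):
            raise ValueError("y must be nonnegative")
        if params is not None:
            lo, hi = params.u0, params.u0 + params.delta_u0
            if np.any(u < lo - 1e-12) or np.any(u > hi + 1e-12):
                raise ValueError(f"u must lie in [{lo}, {hi}]")


def rested_state(params: SynapseParams, shape: tuple = ()) -> SynapseState:
    """Fully recovered state: ``x=1``, ``y=0``, ``u = u(y=0)``."""
    x = np.ones(shape) if shape else 1.0
    y = np.zeros(shape) if shape else 0.0
    u = release_probability(y, params)
    return SynapseState(x=x, y=y, u=u)


@dataclass(frozen=True)
class DriveTrace:
    """Presynaptic activity over time for one unit (or a unit vector).

    ``values`` has shape ``(T,)`` or ``(T, n_units)``; entries are
    nonnegative mean activities, one per Euler step of size ``dt``.
    """

    values: np.ndarray
    dt: float = 1.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim not in (1, 2):
            raise ValueError("drive values must be 1-D or 2-D (time x units)")
        if values.size == 0:
            raise ValueError("drive must be nonempty")
        if np.any(values < 0):
            raise ValueError("drive values must be nonnegative")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class SynapseTrajectory:
    """Per-step record of an Euler integration.

    ``x_series[t]``, ``y_series[t]``, ``u_series[t]`` are the state at
    *entry* of step ``t`` (so the state at step t depends only on drives at
    steps < t); ``effective_series[t] = u[t] * x[t] * drive[t]`` is the
    transmitted activity.
    """

    times: np.ndarray
    x_series: np.ndarray
    y_series: np.ndarray
    u_series: np.ndarray
    effective_series: np.ndarray
    drive: np.ndarray

    def __len__(self) -> int:
        return len(self.times)

    @property
    def final_state(self) -> SynapseState:
        return SynapseState(
            x=self.x_series[-1], y=self.y_series[-1], u=self.u_series[-1]
        )

    def to_frame(self):
        """Long-format table (step, unit, x, y, u, drive, effective)."""
        import pandas as pd

        x = np.atleast_2d(self.x_series.T).T
        y = np.atleast_2d(self.y_series.T).T
        u = np.atleast_2d(self.u_series.T).T
        d = np.atleast_2d(self.drive.T).T
        e = np.atleast_2d(self.effective_series.T).T
        n_units = x.shape[1] if x.ndim == 2 else 1
        rows = []
        for j in range(n_units):
            rows.append(
                pd.DataFrame(
                    {
                        "step": self.times,
                        "unit": j,
                        "x": x[:, j],
                        "y": y[:, j],
                        "u": u[:, j],
                        "drive": d[:, j],
                        "effective": e[:, j],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def hy_activation(x: ArrayLike, params: SynapseParams) -> ArrayLike:
    """Sigmoid gate on the resource level driving gliotransmitter release.

    ``Hy(x) = 1 / (1 + exp(-slope_x * (x - x_thr)))``; strictly increasing,
    bounded in (0, 1).
    """
    from scipy.special import expit

    return expit(params.slope_x * (np.asarray(x, dtype=float) - params.x_thr))


def release_probability(y: ArrayLike, params: SynapseParams) -> ArrayLike:
    """Release probability as a static sigmoid map of gliotransmitter level.

    ``u(y) = u0 + delta_u0 / (1 + exp(-slope_y * (y - y_thr)))``; bounded in
    ``(u0, u0 + delta_u0)`` and nondecreasing in ``y``.
    """
    from scipy.special import expit

    return params.u0 + params.delta_u0 * expit(
        params.slope_y * (np.asarray(y, dtype=float) - params.y_thr)
    )


def advance(
    x: ArrayLike,
    y: ArrayLike,
    u: ArrayLike,
    drive: ArrayLike,
    params: SynapseParams,
    dt: float = 1.0,
    astro: bool = True,
) -> tuple:
    """One explicit-Euler update of the raw state arrays.

    Update order (fixed for bit-reproducibility): ``x`` advances using the
    current ``(x, u)``; ``y`` advances using the *current* ``x``; ``u`` is
    then recomputed from the new ``y``. ``x`` is clamped to [0, 1] after the
    step — a large drive at ``dt = 1`` can overshoot and clamping preserves
    the resource-fraction semantics.

    With ``astro=False`` the gliotransmitter pathway is skipped entirely:
    ``y`` stays put and ``u`` is pinned to ``u0``.
    """
    x = np.asarray(x, dtype=float)
    x_new = x + dt * ((1.0 - x) / params.tau_d - np.asarray(u) * x * np.asarray(drive))
    x_new = np.clip(x_new, 0.0, 1.0)
    if astro:
        y = np.asarray(y, dtype=float)
        y_new = y + dt * (-y / params.tau_y + params.beta * hy_activation(x, params))
        u_new = release_probability(y_new, params)
    else:
        y_new = np.asarray(y, dtype=float)
        u_new = np.broadcast_to(params.u0, x_new.shape).copy() if x_new.ndim else params.u0
    return x_new, y_new, u_new


def euler_step(
    state: SynapseState,
    drive: ArrayLike,
    params: SynapseParams,
    dt: float = 1.0,
    astro: bool = True,
) -> SynapseState:
    """Advance the synapse state by one Euler step of size ``dt``.

    Raises
    ------
    ValueError
        If ``drive`` is negative or ``dt`` is not positive.
    """
    if np.any(np.asarray(drive) < 0):
        raise ValueError("drive must be nonnegative")
    if not dt > 0:
        raise ValueError("dt must be positive")
    x, y, u = advance(state.x, state.y, state.u, drive, params, dt=dt, astro=astro)
    return SynapseState(x=x, y=y, u=u)


def simulate_trace(
    drive: DriveTrace,
    params: SynapseParams,
    initial: Optional[SynapseState] = None,
    astro: bool = True,
) -> SynapseTrajectory:
    """Integrate the synapse dynamics along a drive trace.

    Parameters
    ----------
    drive
        Presynaptic activity, shape ``(T,)`` or ``(T, n_units)``.
    params
        Dynamics constants.
    initial
        Starting state; defaults to the rested state (x=1, y=0, u=u(0)).
    astro
        If False, run depression-only dynamics (u pinned to u0).

    Returns
    -------
    SynapseTrajectory
        Series of length ``T`` recording the state at entry of each step
        and the transmitted activity ``u*x*drive``.
    """
    values = drive.values
    n_units = values.shape[1] if values.ndim == 2 else None
    shape = (n_units,) if n_units else ()
    if initial is None:
        initial = rested_state(params, shape)
    T = values.shape[0]
    x = np.broadcast_to(np.asarray(initial.x, dtype=float), shape).copy()
    y = np.broadcast_to(np.asarray(initial.y, dtype=float), shape).copy()
    u = np.broadcast_to(np.asarray(initial.u, dtype=float), shape).copy()
    xs = np.empty_like(values)
    ys = np.empty_like(values)
    us = np.empty_like(values)
    for t in range(T):
        xs[t], ys[t], us[t] = x, y, u
        x, y, u = advance(x, y, u, values[t], params, dt=drive.dt, astro=astro)
    return SynapseTrajectory(
        times=np.arange(T),
        x_series=xs,
        y_series=ys,
        u_series=us,
        effective_series=us * xs * values,
        drive=values,
    )


def steady_state(
    drive_const: float,
    params: SynapseParams,
    fixed_u: Optional[float] = None,
    tol: float = 1e-12,
) -> SynapseState:
    """Self-consistent equilibrium of the dynamics under constant drive.

    Solves ``(1 - x*) / tau_d = u* x* a``, ``y* = tau_y * beta * Hy(x*)``
    and ``u* = u(y*)``. Eliminating ``x`` and ``y`` leaves a scalar
    self-consistency equation ``u = g(u)`` with ``g`` monotone decreasing,
    so the (unique) root is bracketed on ``[u0, u0 + delta_u0]`` and found
    by Brent's method. With ``fixed_u`` supplied the release probability is
    held constant, which makes the depression equilibrium available in
    closed form ``x* = 1 / (1 + tau_d * u * a)``.

    Raises
    ------
    RuntimeError
        If the root solver fails to bracket or converge.
    """
    if drive_const < 0:
        raise ValueError("drive_const must be nonnegative")
    a = float(drive_const)

    def x_of(u: float) -> float:
        return 1.0 / (1.0 + params.tau_d * u * a)

    def y_of(x: float) -> float:
        return params.tau_y * params.beta * float(hy_activation(x, params))

    if fixed_u is not None:
        u_star = float(fixed_u)
    elif params.delta_u0 == 0.0:
        u_star = params.u0
    else:
        from scipy.optimize import brentq

        def residual(u: float) -> float:
            return u - float(release_probability(y_of(x_of(u)), params))

        lo, hi = params.u0, params.u0 + params.delta_u0
        r_lo, r_hi = residual(lo), residual(hi)
        if r_lo == 0.0:
            u_star = lo
        elif r_hi == 0.0:
            u_star = hi
        elif r_lo > 0 or r_hi < 0:
            raise RuntimeError(
                f"steady_state could not bracket the equilibrium (drive={a})"
            )
        else:
            u_star = float(brentq(residual, lo, hi, xtol=tol, rtol=8.9e-16))
    x_star = x_of(u_star)
    y_star = y_of(x_star)
    u_out = u_star if fixed_u is not None else float(
        release_probability(y_star, params)
    )
    return SynapseState(x=x_star, y=y_star, u=u_out)
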