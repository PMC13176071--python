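"""Balanced implicit one-step maps and path simulation.

The balanced implicit method (BIM) adds a state-dependent damping term
``c(Y_n) (Y_n - Y_{n+1})`` to the Euler-Maruyama step, with a scalar diagonal
weight ``c(Y_n) = A_n * Id``.  Solving the implicit relation gives the closed
form used here:

    Y_{n+1} = Y_n + (f(Y_n) dt + g(Y_n) dW_n) / (1 + A_n)

with the weight (SIR; the SIS weight replaces K/R_n by K/S_n)

    A_n = (alpha+gamma+mu+beta*I_n) dt + K |F1(Y_n) dW1| + (K/R_n) |F2(Y_n) dW2|.

With this particular weight the update is invariant with respect to the
admissible domain (prism/triangle) for *every* step size and *every*
realization of the increments: no clipping, projection or truncation is
applied anywhere — boundedness and positivity emerge from the scheme alone.
The forward Euler-Maruyama map (``A_n = 0``) is provided as the comparator
that does not have this property.

All step maps broadcast over leading axes: a state of shape ``(M, d)`` with
increment arrays of shape ``(M,)`` advances M paths at once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .models import (
    SIR,
    SIS,
    DomainViolationError,
    EpidemicParams,
    InvalidInputError,
    RatePair,
    drift,
    in_domain,
)

__all__ = [
    "StepInputs",
    "WeightValue",
    "Trajectory",
    "StepSizeWarning",
    "bim_weight_sir",
    "bim_weight_sis",
    "bim_step_sir",
    "bim_step_sis",
    "bim_step",
    "em_step",
    "simulate_path",
    "implicit_residual_sir",
    "implicit_residual_sis",
]


class StepSizeWarning(UserWarning):
    """Emitted for dt > 1: invariance still holds but the V-stability and
    consistency estimates assume step sizes of at most one year."""


@dataclass(frozen=True)
class StepInputs:
    """One integration step: step size ``dt`` (years) and Wiener increments.

    ``dW1``/``dW2`` are the increments of the two noise channels over the
    step (scale sqrt(years)); any real values are admissible.  Scalars or
    broadcastable arrays.
    """

    dt: float
    dW1: float
    dW2: float

    def __post_init__(self) -> None:
        dt = np.asarray(self.dt, dtype=float)
        if not np.all(np.isfinite(dt)) or not np.all(dt > 0):
            raise InvalidInputError("dt must be strictly positive and finite")
        if np.any(dt > 1.0):
            warnings.warn(
                "dt > 1 year: domain invariance holds for any step size, but the "
                "V-stability and consistency estimates assume dt <= 1",
                StepSizeWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class WeightValue:
    """Scalar diagonal balanced weight ``a_n >= 0`` and damping ``1/(1+a_n)``."""

    a_n: np.ndarray
    damping: np.ndarray


@dataclass(frozen=True)
class Trajectory:
    """A single simulated path on a uniform time grid.

    ``states`` has shape ``(n_steps + 1, d)`` with ``states[0]`` the initial
    condition.  For BIM schemes every state is in the admissible domain; for
    the Euler comparator, ``exited[n]`` flags grid points outside it.
    """

    times: np.ndarray
    states: np.ndarray
    scheme: str
    model: str
    exited: np.ndarray = field(default=None)  # type: ignore[assignment]
    path_id: Optional[int] = None


def _weight(model: str, state: np.ndarray, params: EpidemicParams, rates: RatePair,
            step: StepInputs, *, validate: bool = True) -> WeightValue:
    x = np.asarray(state, dtype=float)
    S, I = x[..., 0], x[..., 1]
    divisor = x[..., 2] if model == SIR else S
    if validate and not np.all(divisor > 0):
        which = "R" if model == SIR else "S"
        raise DomainViolationError(f"balanced weight requires {which} > 0")
    f1v, f2v = rates.evaluate(x)
    a_n = (
        (params.loss_rate + params.beta * I) * step.dt
        + params.K * np.abs(f1v * step.dW1)
        + (params.K / divisor) * np.abs(f2v * step.dW2)
    )
    a_n = np.asarray(a_n, dtype=float)
    return WeightValue(a_n=a_n, damping=1.0 / (1.0 + a_n))


def bim_weight_sir(state, params: EpidemicParams, rates: RatePair, step: StepInputs) -> WeightValue:
    """Balanced weight A_n for the SIR scheme; requires ``R > 0``.

    ``A_n >= (alpha+gamma+mu)*dt > 0`` and is invariant under sign flips of
    the increments; larger ``|dW|`` never increases the damping ``1/(1+A_n)``.
    """
    return _weight(SIR, state, params, rates, step)


def bim_weight_sis(state, params: EpidemicParams, rates: RatePair, step: StepInputs) -> WeightValue:
    """Balanced weight A_n for the SIS scheme; requires ``S > 0``."""
    return _weight(SIS, state, params, rates, step)


def _check_in_domain(state, model, K, where):
    chk = in_domain(state, model, K)
    if not chk:
        raise DomainViolationError(f"{where}: state outside domain, violated {chk.violations}")


def bim_step_sir(state, params: EpidemicParams, rates: RatePair, step: StepInputs,
                 *, validate: bool = True) -> np.ndarray:
    """One balanced implicit step of the SIR model (closed explicit form).

    The three coordinates share a single weight ``A_n``.  The output lies in
    the prism for every ``dt`` and every increment pair; ``I = 0`` is
    absorbing for I (every I-increment carries a factor ``I_n``).
    """
    x = np.asarray(state, dtype=float)
    if validate:
        _check_in_domain(x, SIR, params.K, "bim_step_sir")
    w = _weight(SIR, x, params, rates, step, validate=validate)
    S, I, R = x[..., 0], x[..., 1], x[..., 2]
    p = params
    f1v, f2v = rates.evaluate(x)
    n1 = S * I * f1v * step.dW1  # transmission-noise mass moved S -> I
    n2 = I * f2v * step.dW2      # recovery-noise mass moved I -> R
    dt = step.dt
    dS = ((-p.beta * S * I + p.mu * (p.K - S)) * dt - n1) * w.damping
    dI = ((p.beta * S * I - p.loss_rate * I) * dt + n1 - n2) * w.damping
    dR = ((p.alpha * I - p.mu * R) * dt + n2) * w.damping
    return np.stack([S + dS, I + dI, R + dR], axis=-1)


def bim_step_sis(state, params: EpidemicParams, rates: RatePair, step: StepInputs,
                 *, validate: bool = True) -> np.ndarray:
    """One balanced implicit step of the SIS model (closed explicit form)."""
    x = np.asarray(state, dtype=float)
    if validate:
        _check_in_domain(x, SIS, params.K, "bim_step_sis")
    w = _weight(SIS, x, params, rates, step, validate=validate)
    S, I = x[..., 0], x[..., 1]
    p = params
    f1v, f2v = rates.evaluate(x)
    n1 = S * I * f1v * step.dW1
    n2 = I * f2v * step.dW2
    dt = step.dt
    dS = ((-p.beta * S * I + p.mu * (p.K - S) + p.alpha * I) * dt - n1 + n2) * w.damping
    dI = ((p.beta * S * I - p.loss_rate * I) * dt + n1 - n2) * w.damping
    return np.stack([S + dS, I + dI], axis=-1)


def bim_step(model: str, state, params, rates, step: StepInputs, *, validate: bool = True) -> np.ndarray:
    """Dispatch the balanced step on ``model`` ('sir' or 'sis')."""
    if model == SIR:
        return bim_step_sir(state, params, rates, step, validate=validate)
    return bim_step_sis(state, params, rates, step, validate=validate)


def em_step(state, params: EpidemicParams, rates: RatePair, step: StepInputs, model: str) -> np.ndarray:
    """Forward Euler-Maruyama step ``x + f(x) dt + g(x) dW``.

    Comparator only: it carries *no* domain guarantee and may produce
    negative populations or totals above K by design.
    """
    x = np.asarray(state, dtype=float)
    f = drift(model, x, params)
    f1v, f2v = rates.evaluate(x)
    S, I = x[..., 0], x[..., 1]
    n1 = S * I * f1v * step.dW1
    n2 = I * f2v * step.dW2
    if model == SIR:
        noise = np.stack([-n1, n1 - n2, n2], axis=-1)
    else:
        noise = np.stack([-n1 + n2, n1 - n2], axis=-1)
    return x + f * step.dt + noise


def simulate_path(
    model: str,
    params: EpidemicParams,
    rates: RatePair,
    scheme: str,
    initial_state,
    dt: float,
    increments: np.ndarray,
    *,
    path_id: Optional[int] = None,
) -> Trajectory:
    """Iterate a one-step map along a uniform grid, recording every state.

    ``increments`` has shape ``(n_steps, 2)``: the Wiener increments per step
    and channel.  Deterministic given the increments — replaying the same
    array yields a bit-identical trajectory.  BIM paths are checked against
    the domain at every step (a violation raises, falsifying the invariance
    guarantee); Euler paths that exit are flagged, not rejected.
    """
    if scheme not in ("bim", "em"):
        raise InvalidInputError(f"unknown scheme {scheme!r}")
    inc = np.asarray(increments, dtype=float)
    if inc.ndim != 2 or inc.shape[1] != 2:
        raise InvalidInputError("increments must have shape (n_steps, 2)")
    x = np.asarray(initial_state, dtype=float)
    _check_in_domain(x, model, params.K, "simulate_path initial state")
    n = inc.shape[0]
    d = x.shape[-1]
    states = np.empty((n + 1, d))
    states[0] = x
    exited = np.zeros(n + 1, dtype=bool)
    for k in range(n):
        step = StepInputs(dt=dt, dW1=inc[k, 0], dW2=inc[k, 1])
        if scheme == "bim":
            x = bim_step(model, x, params, rates, step)
            _check_in_domain(x, model, params.K, f"simulate_path step {k}")
        else:
            x = em_step(x, params, rates, step, model)
            exited[k + 1] = not in_domain(x, model, params.K).ok
        states[k + 1] = x
    times = np.arange(n + 1) * dt
    return Trajectory(times=times, states=states, scheme=scheme, model=model,
                      exited=exited, path_id=path_id)


# ---------------------------------------------------------------------------
# implicit-form residuals (verification oracles, not solvers)
# ---------------------------------------------------------------------------


def implicit_residual_sir(state, new_state, params: EpidemicParams, rates: RatePair,
                          step: StepInputs) -> np.ndarray:
    """Residual of the implicit SIR relation at a proposed update.

    Returns ``Y_{n+1} - (Y_n + f dt + g dW + A_n (Y_n - Y_{n+1}))``, which is
    zero (to roundoff) iff ``new_state`` solves the balanced implicit
    relation.  Used to certify that the closed-form step is the exact
    solution of the implicit scheme.
    """
    x = np.asarray(state, dtype=float)
    y = np.asarray(new_state, dtype=float)
    w = _weight(SIR, x, params, rates, step)
    S, I, R = x[..., 0], x[..., 1], x[..., 2]
    p = params
    f1v, f2v = rates.evaluate(x)
    n1 = S * I * f1v * step.dW1
    n2 = I * f2v * step.dW2
    rhs_S = S + (-p.beta * S * I + p.mu * (p.K - S)) * step.dt - n1
    rhs_I = I + (p.beta * S * I - p.loss_rate * I) * step.dt + n1 - n2
    rhs_R = R + (p.alpha * I - p.mu * R) * step.dt + n2
    rhs = np.stack([rhs_S, rhs_I, rhs_R], axis=-1) + w.a_n[..., None] * (x - y)
    return y - rhs


def implicit_residual_sis(state, new_state, params: EpidemicParams, rates: RatePair,
                          step: StepInputs) -> np.ndarray:
    """Residual of the implicit SIS relation at a proposed update (see SIR)."""
    x = np.asarray(state, dtype=float)
    y = np.asarray(new_state, dtype=float)
    w = _weight(SIS, x, params, rates, step)
    S, I = x[..., 0], x[..., 1]
    p = params
    f1v, f2v = rates.evaluate(x)
    n1 = S * I * f1v * step.dW1
    n2 = I * f2v * step.dW2
    rhs_S = S + (-p.beta * S * I + p.mu * (p.K - S) + p.alpha * I) * step.dt - n1 + n2
    rhs_I = I + (p.beta * S * I - p.loss_rate * I) * step.dt + n1 - n2
    rhs = np.stack([rhs_S, rhs_I], axis=-1) + w.a_n[..., None] * (x - y)
    return y - rhs
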