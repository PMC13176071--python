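"""Stochastic SIR and SIS epidemic models with variable contact diffusion rates.

The two models describe an epidemic in a population with births and deaths,
bounded by a carrying capacity ``K``.  Susceptibles S are infected at rate
``beta*S*I``; infectives I recover at rate ``alpha``, die of the disease at
rate ``gamma`` and of natural causes at rate ``mu``; births enter the
susceptible class at rate ``mu*K``.  Environmental noise is injected through
two independent Wiener channels whose intensities are the state-dependent
*diffusion rate functions* F1 (transmission channel, multiplying ``S*I``) and
F2 (recovery channel, multiplying ``I``).  The noise is internal to the
population: it moves mass between compartments, never in or out, so the total
population N obeys the ordinary differential equation
``N' = mu*(K - N) - gamma*I``.

States live on biologically admissible bounded domains:

* SIR: the prism ``{S > 0, I >= 0, R > 0, S + I + R <= K}`` in R^3,
* SIS: the triangle ``{S > 0, I >= 0, S + I <= K}`` in R^2.

This module defines the drift and diffusion fields of both models, the domain
membership tests, a library of diffusion-rate-function fixtures used in the
simulation studies, and the analytic quantities attached to the models: the
basic reproduction number ``R0 = beta*K/(alpha+gamma+mu)``, the disease-free
and endemic equilibria, and the Lipschitz/growth/stability constants that
govern the stability and consistency of the balanced implicit discretization.

All rates are per year; populations are numbers of individuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple

import numpy as np

__all__ = [
    "SIR",
    "SIS",
    "EpidemicParams",
    "RatePair",
    "EquilibriumSet",
    "StabilityConstants",
    "DomainCheck",
    "InvalidInputError",
    "InvalidRateError",
    "DomainViolationError",
    "drift_sir",
    "diffusion_sir",
    "drift_sis",
    "diffusion_sis",
    "reproduction_number",
    "equilibria_sir",
    "equilibria_sis",
    "sis_reference_point",
    "sir_reference_point",
    "stability_constants_sir",
    "in_domain",
    "domain_violation_counts",
    "builtin_rates",
    "BUILTIN_RATE_NAMES",
    "BOUNDARY_RTOL",
]

SIR = "sir"
SIS = "sis"

#: Relative tolerance on the total-population constraint ``N <= K``.  The
#: algebra guaranteeing N_{n+1} <= K is exact in real arithmetic only;
#: roundoff may produce N = K + delta with delta of order eps*K.  Strict
#: positivity constraints use exact comparison.
BOUNDARY_RTOL = 1e-12


class InvalidInputError(ValueError):
    """Raised for non-finite or otherwise inadmissible inputs."""


class InvalidRateError(InvalidInputError):
    """Raised when a diffusion rate function evaluates to a non-finite value."""


class DomainViolationError(RuntimeError):
    """Raised when a state that must lie in the admissible domain does not."""


# ---------------------------------------------------------------------------
# parameter and rate containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EpidemicParams:
    """Positive rate constants shared by the SIR and SIS models.

    Parameters
    ----------
    alpha : float
        Recovery rate (1/year); ``1/alpha`` is the mean infective period.
    beta : float
        Contact (infection) rate (1/(individual*year)); ``beta*S*I`` is the
        number of new infections per year.
    gamma : float
        Disease-related death rate (1/year).
    mu : float
        Natural birth = death rate (1/year); ``mu*K`` births enter per year.
    K : float
        Carrying capacity (individuals); upper bound on the total population.
    """

    alpha: float
    beta: float
    gamma: float
    mu: float
    K: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "mu", "K"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise InvalidInputError(
                    f"EpidemicParams.{name} must be strictly positive and finite, got {v!r}"
                )

    @property
    def loss_rate(self) -> float:
        """Total per-capita outflow rate ``alpha + gamma + mu`` of infectives."""
        return self.alpha + self.gamma + self.mu


@dataclass(frozen=True)
class RatePair:
    """A pair of diffusion rate functions F1, F2 with boundedness metadata.

    ``f1`` and ``f2`` map a state array (last axis of size 2 or 3) to a real
    scalar per state; they must broadcast over leading axes.  ``sup_f1``
    bounds ``|F1|`` over the closed domain, and ``sup_f2_ratio`` bounds
    ``|F2|/R`` over the SIR prism (``|F2|/S`` over the SIS triangle).  Finite
    bounds are the hypothesis under which consistency and convergence of the
    balanced scheme hold; they are supplied analytically per fixture, never
    numerically maximized.
    """

    f1: Callable[[np.ndarray], np.ndarray]
    f2: Callable[[np.ndarray], np.ndarray]
    sup_f1: float
    sup_f2_ratio: float
    name: str = ""

    def __post_init__(self) -> None:
        for nm in ("sup_f1", "sup_f2_ratio"):
            v = getattr(self, nm)
            if not (math.isfinite(v) and v >= 0):
                raise InvalidInputError(f"RatePair.{nm} must be finite and nonnegative, got {v!r}")

    def evaluate(self, state: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Evaluate (F1, F2) at ``state``, checking finiteness."""
        f1v = np.asarray(self.f1(state), dtype=float)
        f2v = np.asarray(self.f2(state), dtype=float)
        if not (np.all(np.isfinite(f1v)) and np.all(np.isfinite(f2v))):
            raise InvalidRateError(f"rate pair {self.name!r} returned non-finite values")
        return f1v, f2v


@dataclass(frozen=True)
class EquilibriumSet:
    """Basic reproduction number and equilibria of a model.

    ``endemic`` is present iff ``r0 > 1``; for ``r0 <= 1`` only the
    disease-free equilibrium (K, 0[, 0]) is biologically admissible.
    """

    r0: float
    disease_free: Tuple[float, ...]
    endemic: Optional[Tuple[float, ...]] = None


@dataclass(frozen=True)
class StabilityConstants:
    """Lipschitz/growth constants of the SIR fields and derived stability constants.

    ``L1``/``L2`` are Lipschitz constants of drift/diffusion on the prism,
    ``L3``/``L4`` linear-growth constants.  ``K1 = L3 + (L3^2+L4^2)/2`` is the
    V-stability constant for ``V(y) = 1 + ||y||^2``; ``K2 = 2|L1| + L2^2`` is
    the mean-square contractivity constant (stored in the theorem form — the
    Gronwall exponent in the underlying estimate uses ``2 L1^2 + L2^2``
    instead, a discrepancy we record but do not resolve).  ``a``/``b`` bound
    the balanced weight, ``c3`` is the mean-square Hoelder constant of the
    exact solution, ``K4`` the mean-square consistency constant and ``K5``
    the martingale Hoelder constant.  ``c3``, ``K4`` and ``K5`` involve
    ``exp(3*(L3^2+L4^2))`` and relatives, which overflow to ``inf`` for
    realistic epidemic magnitudes although mathematically finite.
    """

    L1: float
    L2: float
    L3: float
    L4: float
    K1: float
    K2: float
    a: float
    b: float
    c3: float
    K4: float
    K5: float


# ---------------------------------------------------------------------------
# drift and diffusion fields
# ---------------------------------------------------------------------------


def _as_state(state: np.ndarray, d: int) -> np.ndarray:
    x = np.asarray(state, dtype=float)
    if x.shape[-1:] != (d,):
        raise InvalidInputError(f"state must have last axis of size {d}, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("state contains non-finite entries")
    return x


def drift_sir(state: np.ndarray, params: EpidemicParams) -> np.ndarray:
    """Drift field of the stochastic SIR model.

    Returns ``(-beta*S*I + mu*(K-S), beta*S*I - (alpha+gamma+mu)*I,
    alpha*I - mu*R)``; the components sum to ``mu*(K-N) - gamma*I``.
    Broadcasts over leading axes of ``state``.
    """
    x = _as_state(state, 3)
    S, I, R = x[..., 0], x[..., 1], x[..., 2]
    p = params
    return np.stack(
        [
            -p.beta * S * I + p.mu * (p.K - S),
            p.beta * S * I - p.loss_rate * I,
            p.alpha * I - p.mu * R,
        ],
        axis=-1,
    )


def diffusion_sir(state: np.ndarray, params: EpidemicParams, rates: RatePair) -> np.ndarray:
    """Diffusion matrix of the SIR model, shape ``(..., 3, 2)``.

    Column 1 moves ``S*I*F1`` worth of noise mass from S to I; column 2 moves
    ``I*F2`` from I to R.  Each column sums to zero (the noise cancels in the
    total population) and the whole matrix vanishes when ``I = 0``.
    """
    x = _as_state(state, 3)
    S, I = x[..., 0], x[..., 1]
    f1v, f2v = rates.evaluate(x)
    n1 = S * I * f1v
    n2 = I * f2v
    zero = np.zeros_like(n1)
    g = np.stack(
        [
            np.stack([-n1, zero], axis=-1),
            np.stack([n1, -n2], axis=-1),
            np.stack([zero, n2], axis=-1),
        ],
        axis=-2,
    )
    return g


def drift_sis(state: np.ndarray, params: EpidemicParams) -> np.ndarray:
    """Drift field of the stochastic SIS model (recovered return to S)."""
    x = _as_state(state, 2)
    S, I = x[..., 0], x[..., 1]
    p = params
    return np.stack(
        [
            -p.beta * S * I + p.mu * (p.K - S) + p.alpha * I,
            p.beta * S * I - p.loss_rate * I,
        ],
        axis=-1,
    )


def diffusion_sis(state: np.ndarray, params: EpidemicParams, rates: RatePair) -> np.ndarray:
    """Diffusion matrix of the SIS model, shape ``(..., 2, 2)``; rows sum to 0."""
    x = _as_state(state, 2)
    S, I = x[..., 0], x[..., 1]
    f1v, f2v = rates.evaluate(x)
    n1 = S * I * f1v
    n2 = I * f2v
    return np.stack(
        [
            np.stack([-n1, n2], axis=-1),
            np.stack([n1, -n2], axis=-1),
        ],
        axis=-2,
    )


def drift(model: str, state: np.ndarray, params: EpidemicParams) -> np.ndarray:
    """Dispatch ``drift_sir``/``drift_sis`` on ``model``."""
    return drift_sir(state, params) if model == SIR else drift_sis(state, params)


def diffusion(model: str, state: np.ndarray, params: EpidemicParams, rates: RatePair) -> np.ndarray:
    """Dispatch ``diffusion_sir``/``diffusion_sis`` on ``model``."""
    if model == SIR:
        return diffusion_sir(state, params, rates)
    return diffusion_sis(state, params, rates)


# ---------------------------------------------------------------------------
# reproduction number and equilibria
# ---------------------------------------------------------------------------


def reproduction_number(params: EpidemicParams) -> float:
    """Basic reproduction number ``R0 = beta*K / (alpha + gamma + mu)``.

    ``R0 < 1`` implies stochastic asymptotic stability of the disease-free
    equilibrium; ``R0 > 1`` admits an endemic equilibrium.  Invariant under
    the rescaling ``beta -> beta/c, K -> c*K``.
    """
    return params.beta * params.K / params.loss_rate


def sis_reference_point(params: EpidemicParams) -> Tuple[float, float]:
    """The SIS equilibrium formulas ``(K/R0, mu*K/(gamma+mu)*(1 - 1/R0))``.

    Evaluated unconditionally: for ``R0 < 1`` the point is not biologically
    admissible (I2 < 0) but is still used to center the equilibrium-seeking
    diffusion rate fixtures, exactly as in the simulation studies.
    """
    r0 = reproduction_number(params)
    s2 = params.K / r0
    i2 = params.mu * params.K / (params.gamma + params.mu) * (1.0 - 1.0 / r0)
    return s2, i2


def sir_reference_point(params: EpidemicParams) -> Tuple[float, float, float]:
    """The SIR equilibrium formulas ``(K/R0, mu/beta*(R0-1), alpha/beta*(R0-1))``."""
    r0 = reproduction_number(params)
    return (
        params.K / r0,
        params.mu / params.beta * (r0 - 1.0),
        params.alpha / params.beta * (r0 - 1.0),
    )


def equilibria_sis(params: EpidemicParams) -> EquilibriumSet:
    """Disease-free equilibrium (K, 0) and, iff R0 > 1, the endemic equilibrium."""
    r0 = reproduction_number(params)
    endemic = sis_reference_point(params) if r0 > 1.0 else None
    return EquilibriumSet(r0=r0, disease_free=(params.K, 0.0), endemic=endemic)


def equilibria_sir(params: EpidemicParams) -> EquilibriumSet:
    """Disease-free equilibrium (K, 0, 0) and, iff R0 > 1, the endemic equilibrium."""
    r0 = reproduction_number(params)
    endemic = sir_reference_point(params) if r0 > 1.0 else None
    return EquilibriumSet(r0=r0, disease_free=(params.K, 0.0, 0.0), endemic=endemic)


def equilibria(model: str, params: EpidemicParams) -> EquilibriumSet:
    """Dispatch ``equilibria_sir``/``equilibria_sis`` on ``model``."""
    return equilibria_sir(params) if model == SIR else equilibria_sis(params)


# ---------------------------------------------------------------------------
# domain membership
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DomainCheck:
    """Result of a domain membership test with per-constraint diagnostics."""

    ok: bool
    violations: Tuple[str, ...] = ()

    def __bool__(self) -> bool:
        return self.ok


def _constraints(model: str, x: np.ndarray, K: float):
    """Yield (name, satisfied-boolean-array) pairs for the model's domain."""
    cap = K * (1.0 + BOUNDARY_RTOL)
    if model == SIR:
        S, I, R = x[..., 0], x[..., 1], x[..., 2]
        yield "S>0", S >= 0
        yield "I>=0", I >= 0
        yield "R>0", R >= 0
        yield "S+I+R<=K", S + I + R <= cap
    elif model == SIS:
        S, I = x[..., 0], x[..., 1]
        yield "S>0", S >= 0
        yield "I>=0", I >= 0
        yield "S+I<=K", S + I <= cap
    else:  # pragma: no cover - guarded by callers
        raise InvalidInputError(f"unknown model kind {model!r}")


def in_domain(state: np.ndarray, model: str, K: float) -> DomainCheck:
    """Test membership of ``state`` (or a batch of states) in the model domain.

    The domain requires ``S > 0`` (and ``R > 0`` for SIR) strictly, but the
    membership test accepts the closed boundary (S, R >= 0): the disease-free
    state (K, 0[, 0]) is a member.  Stepping from a state with a vanishing
    divisor coordinate is rejected separately by the balanced weight, which
    divides by R (SIR) or S (SIS).  The cap ``N <= K`` is applied with a
    relative roundoff tolerance of ``BOUNDARY_RTOL``; the other constraints
    are exact comparisons.  Violation labels carry the domain's defining
    (strict) inequalities.
    """
    d = 3 if model == SIR else 2
    x = np.asarray(state, dtype=float)
    if x.shape[-1:] != (d,):
        raise InvalidInputError(f"state must have last axis of size {d} for {model!r}")
    violated = tuple(name for name, ok in _constraints(model, x, K) if not np.all(ok))
    return DomainCheck(ok=not violated, violations=violated)


def domain_violation_counts(states: np.ndarray, model: str, K: float) -> dict:
    """Count per-constraint violations over an array of states (vectorized)."""
    x = np.asarray(states, dtype=float)
    return {name: int(np.size(ok) - np.count_nonzero(ok)) for name, ok in _constraints(model, x, K)}


# ---------------------------------------------------------------------------
# stability constants
# ---------------------------------------------------------------------------


def _expm1_sup(c: float) -> float:
    """max over |z|<=1 of (exp(c*z)-1)/z for c >= 0, i.e. expm1(c) (inf on overflow)."""
    with np.errstate(over="ignore"):
        return float(np.expm1(c))


def stability_constants_sir(
    params: EpidemicParams,
    rates: RatePair,
    lip_f1: float,
    lip_f2: float,
) -> StabilityConstants:
    """Lipschitz/growth and stability constants of the SIR model on the prism.

    ``lip_f1``/``lip_f2`` are the caller-supplied local Lipschitz constants of
    the diffusion rate functions on the prism.  The constants:

    * ``L1^2 = 8 beta^2 K^2 + 2 (alpha+gamma+mu)^2 + 2 alpha^2``
    * ``L2^2 = 4 lip_f1 K^4 + 4 lip_f2 K^2 + 8 K^2 sup|F1|^2 + 4 sup|F2|^2``
    * ``L3^2 = max(4 beta^2 K^4 + 4 mu^2 K^2, 4 mu^2, 2 (alpha+gamma+mu)^2 + 2 alpha^2)``
    * ``L4^2 = max(2 K^2 sup|F1|^2, 2 sup|F2|^2)``

    ``sup|F2|`` is bounded by ``K * sup_f2_ratio`` (since ``R <= K`` on the
    prism).  Every output is monotone nondecreasing in each supplied bound.
    """
    if not (lip_f1 >= 0 and lip_f2 >= 0):
        raise InvalidInputError("local Lipschitz constants must be nonnegative")
    p = params
    loss = p.loss_rate
    sup1 = rates.sup_f1
    sup2 = rates.sup_f2_ratio * p.K  # |F2| <= (|F2|/R) * K on the prism

    L1 = math.sqrt(8 * p.beta**2 * p.K**2 + 2 * loss**2 + 2 * p.alpha**2)
    L2 = math.sqrt(4 * lip_f1 * p.K**4 + 4 * lip_f2 * p.K**2 + 8 * p.K**2 * sup1**2 + 4 * sup2**2)
    L3 = math.sqrt(
        max(4 * p.beta**2 * p.K**4 + 4 * p.mu**2 * p.K**2, 4 * p.mu**2, 2 * loss**2 + 2 * p.alpha**2)
    )
    L4 = math.sqrt(max(2 * p.K**2 * sup1**2, 2 * sup2**2))

    K1 = L3 + (L3**2 + L4**2) / 2.0
    K2 = 2 * abs(L1) + L2**2
    a = loss + p.beta * p.K
    b = p.K * (sup1 + rates.sup_f2_ratio)
    c3 = math.sqrt(2.0 * _expm1_sup(3.0 * (L3**2 + L4**2)))
    with np.errstate(over="ignore"):
        K4 = float(np.sqrt(2 * c3**2 * (L1**2 + L2**2) + 4 * L3**2 + 8 * (a**2 + 3 * b**2) * L4**2))
    denom = L1**2 + L2**2
    K5 = (L2**2 / denom) * _expm1_sup(3.0 * denom) if denom > 0 else 0.0
    return StabilityConstants(L1=L1, L2=L2, L3=L3, L4=L4, K1=K1, K2=K2, a=a, b=b, c3=c3, K4=K4, K5=K5)


# ---------------------------------------------------------------------------
# built-in diffusion rate fixtures
# ---------------------------------------------------------------------------


def _sis_linear(params: EpidemicParams) -> RatePair:
    # Equilibrium-seeking pair F1 = (S - S2)/K^2, F2 = S*(I - I2)/K centered
    # at the SIS equilibrium formulas (admissible or not).
    K = params.K
    s2, i2 = sis_reference_point(params)

    def f1(x):
        return (np.asarray(x, float)[..., 0] - s2) / K**2

    def f2(x):
        x = np.asarray(x, float)
        return x[..., 0] * (x[..., 1] - i2) / K

    sup_f1 = max(abs(s2), abs(K - s2)) / K**2
    sup_f2_ratio = max(abs(i2), abs(K - i2)) / K  # |F2|/S = |I - I2|/K
    return RatePair(f1, f2, sup_f1, sup_f2_ratio, name="sis-linear")


def _sis_sin_indicator(params: EpidemicParams, threshold_on_s: bool) -> RatePair:
    # F1 = sin(S+I); F2 = (I^2/K) * indicator.  Main variant gates on S > I,
    # the caption variant on S > 0.01.  The discontinuity set has 2-D Lebesgue
    # measure zero; the indicator is evaluated exactly, never smoothed.
    K = params.K

    def f1(x):
        x = np.asarray(x, float)
        return np.sin(x[..., 0] + x[..., 1])

    if threshold_on_s:
        def f2(x):
            x = np.asarray(x, float)
            return np.where(x[..., 0] > 0.01, x[..., 1] ** 2 / K, 0.0)

        sup_ratio = K / 0.01  # |F2|/S <= (K^2/K)/0.01 on {S > 0.01}
        name = "sis-sin-indicator-caption"
    else:
        def f2(x):
            x = np.asarray(x, float)
            return np.where(x[..., 0] > x[..., 1], x[..., 1] ** 2 / K, 0.0)

        sup_ratio = 1.0  # on {S > I}: I^2/(K*S) < I/K <= 1
        name = "sis-sin-indicator"
    return RatePair(f1, f2, 1.0, sup_ratio, name=name)


def _sir_linear_indicator(params: EpidemicParams) -> RatePair:
    # F1 = (S - S*)/K^3 and F2 = ((I - I*)/K^2) * 1{R > 0.01}, centered at the
    # SIR equilibrium formulas.  F2 vanishes whenever R <= 0.01, which keeps
    # |F2|/R bounded on the whole prism.
    K = params.K
    s_star, i_star, _ = sir_reference_point(params)

    def f1(x):
        return (np.asarray(x, float)[..., 0] - s_star) / K**3

    def f2(x):
        x = np.asarray(x, float)
        return np.where(x[..., 2] > 0.01, (x[..., 1] - i_star) / K**2, 0.0)

    sup_f1 = max(abs(s_star), abs(K - s_star)) / K**3
    sup_f2_ratio = max(abs(i_star), abs(K - i_star)) / (K**2 * 0.01)
    return RatePair(f1, f2, sup_f1, sup_f2_ratio, name="sir-linear-indicator")


def _constant(params: EpidemicParams, c1: float, c2: float, r_floor: float) -> RatePair:
    # Constant intensities for unit tests.  |F2|/R is unbounded as R -> 0 on
    # the open prism, so the stored ratio bound |c2|/r_floor is only valid on
    # {R >= r_floor}; tests using this fixture do not rely on its suprema.
    def f1(x):
        return np.full(np.asarray(x, float).shape[:-1], float(c1))

    def f2(x):
        return np.full(np.asarray(x, float).shape[:-1], float(c2))

    return RatePair(f1, f2, abs(c1), abs(c2) / r_floor, name="constant")


BUILTIN_RATE_NAMES = (
    "sis-linear",
    "sis-sin-indicator",
    "sis-sin-indicator-caption",
    "sir-linear-indicator",
    "constant",
)


def builtin_rates(
    name: str,
    params: EpidemicParams,
    *,
    c1: float = 0.01,
    c2: float = 0.01,
    r_floor: float = 1.0,
) -> RatePair:
    """Return a registered diffusion-rate fixture, parameterized by ``params``.

    Registered names (see :data:`BUILTIN_RATE_NAMES`):

    * ``"sis-linear"`` — F1=(S-S2)/K^2, F2=S(I-I2)/K, centered at the SIS
      equilibrium formulas.
    * ``"sis-sin-indicator"`` — F1=sin(S+I), F2=(I^2/K)*1{S>I}.
    * ``"sis-sin-indicator-caption"`` — same F1, F2 gated on S>0.01 instead.
    * ``"sir-linear-indicator"`` — F1=(S-S*)/K^3, F2=((I-I*)/K^2)*1{R>0.01}.
    * ``"constant"`` — F1=c1, F2=c2 (for unit tests; ratio bound valid on
      R >= ``r_floor`` only).
    """
    if name == "sis-linear":
        return _sis_linear(params)
    if name == "sis-sin-indicator":
        return _sis_sin_indicator(params, threshold_on_s=False)
    if name == "sis-sin-indicator-caption":
        return _sis_sin_indicator(params, threshold_on_s=True)
    if name == "sir-linear-indicator":
        return _sir_linear_indicator(params)
    if name == "constant":
        return _constant(params, c1, c2, r_floor)
    raise KeyError(f"unknown rate fixture {name!r}; known: {BUILTIN_RATE_NAMES}")
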