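"""Wiener increment generation and Monte Carlo ensemble statistics.

Increments are generated once on the finest grid and coarser grids are
obtained by exact summation of consecutive fine increments, so simulations at
different step sizes share the same Brownian paths ("coupled" grids).  Each
path draws from its own counter-derived substream, so path i's increments do
not depend on how many paths are requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .models import (
    SIR,
    DomainViolationError,
    EpidemicParams,
    InvalidInputError,
    RatePair,
    in_domain,
)
from .integrators import StepInputs, bim_step, em_step

__all__ = [
    "IncrementSet",
    "EnsembleSummary",
    "generate_increments",
    "run_ensemble",
    "summary_to_table",
    "write_table",
    "read_table",
]


@dataclass(frozen=True)
class IncrementSet:
    """Wiener increments for ``n_paths`` paths on a uniform grid over [0, T].

    ``values`` has shape ``(n_paths, n_steps, 2)``; each entry is an
    independent N(0, dt) draw at the stored grid resolution.  ``coarsen(k)``
    returns the increments of the grid with step ``k * dt`` by exact pairwise
    (k-wise) summation, preserving the underlying Brownian paths.
    """

    values: np.ndarray
    dt: float
    T: float
    seed: Optional[int] = None

    @property
    def n_paths(self) -> int:
        return self.values.shape[0]

    @property
    def n_steps(self) -> int:
        return self.values.shape[1]

    def path(self, i: int) -> np.ndarray:
        """Increments of path ``i``, shape ``(n_steps, 2)``."""
        return self.values[i]

    def coarsen(self, factor: int) -> "IncrementSet":
        """Exactly sum consecutive groups of ``factor`` increments."""
        if factor < 1 or self.n_steps % factor:
            raise InvalidInputError(
                f"coarsening factor {factor} must divide n_steps={self.n_steps}"
            )
        if factor == 1:
            return self
        v = self.values.reshape(self.n_paths, self.n_steps // factor, factor, 2).sum(axis=2)
        return IncrementSet(values=v, dt=self.dt * factor, T=self.T, seed=self.seed)


def generate_increments(T: float, n_steps_fine: int, n_paths: int, seed: int) -> IncrementSet:
    """Draw N(0, dt) increments for ``n_paths`` independent paths.

    Path ``i`` uses the substream ``SeedSequence(seed, spawn_key=(i,))``:
    reproducible given ``seed`` and independent of ``n_paths``.
    """
    if not (T > 0 and n_steps_fine >= 1 and n_paths >= 1):
        raise InvalidInputError("require T > 0, n_steps_fine >= 1, n_paths >= 1")
    dt = T / n_steps_fine
    sd = np.sqrt(dt)
    values = np.empty((n_paths, n_steps_fine, 2))
    for i in range(n_paths):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        values[i] = rng.normal(0.0, sd, size=(n_steps_fine, 2))
    return IncrementSet(values=values, dt=dt, T=float(T), seed=seed)


@dataclass(frozen=True)
class EnsembleSummary:
    """Per-time mean and (unbiased, M-1 denominator) variance over M paths."""

    times: np.ndarray
    mean: np.ndarray       # (n_times, d)
    variance: np.ndarray   # (n_times, d)
    M: int
    scheme: str
    model: str
    params: EpidemicParams
    rates_name: str
    seed: Optional[int] = None
    n_exited: int = 0      # Euler paths that left the domain at least once


def simulate_paths_vectorized(
    model: str,
    params: EpidemicParams,
    rates: RatePair,
    scheme: str,
    initial_state,
    increments: IncrementSet,
    *,
    check_domain: bool = True,
) -> np.ndarray:
    """Advance all paths of ``increments`` at once; returns (n_steps+1, M, d).

    For BIM schemes any domain violation is a hard failure — it would falsify
    the invariance guarantee of the scheme.
    """
    x0 = np.asarray(initial_state, dtype=float)
    M, n = increments.n_paths, increments.n_steps
    d = x0.shape[-1]
    states = np.empty((n + 1, M, d))
    x = np.broadcast_to(x0, (M, d)).copy()
    states[0] = x
    ever_out = np.zeros(M, dtype=bool)
    for k in range(n):
        step = StepInputs(dt=increments.dt, dW1=increments.values[:, k, 0],
                          dW2=increments.values[:, k, 1])
        if scheme == "bim":
            x = bim_step(model, x, params, rates, step, validate=False)
            if check_domain:
                chk = in_domain(x, model, params.K)
                if not chk:
                    raise DomainViolationError(
                        f"BIM ensemble left the domain at step {k}: {chk.violations}"
                    )
        elif scheme == "em":
            x = em_step(x, params, rates, step, model)
        else:
            raise InvalidInputError(f"unknown scheme {scheme!r}")
        states[k + 1] = x
    return states


def run_ensemble(
    model: str,
    params: EpidemicParams,
    rates: RatePair,
    scheme: str,
    initial_state,
    dt: float,
    T: float,
    M: int,
    seed: int,
) -> EnsembleSummary:
    """Simulate M independent paths and reduce to mean/variance time series.

    Deterministic given ``seed``.  The number of steps is ``round(T/dt)``,
    which must recover ``T`` exactly up to roundoff.
    """
    n = int(round(T / dt))
    if n < 1 or abs(n * dt - T) > 1e-9 * max(T, 1.0):
        raise InvalidInputError(f"T={T} is not an integer multiple of dt={dt}")
    incs = generate_increments(T, n, M, seed)
    states = simulate_paths_vectorized(model, params, rates, scheme, initial_state, incs)
    mean = states.mean(axis=1)
    variance = (
        states.var(axis=1, ddof=1) if M > 1 else np.zeros_like(mean)
    )
    n_exited = 0
    if scheme == "em":
        flat = states.transpose(1, 0, 2)  # (M, n+1, d)
        ok = np.ones(M, dtype=bool)
        for i in range(M):
            ok[i] = in_domain(flat[i], model, params.K).ok
        n_exited = int(M - ok.sum())
    times = np.arange(n + 1) * dt
    return EnsembleSummary(
        times=times, mean=mean, variance=variance, M=M, scheme=scheme, model=model,
        params=params, rates_name=rates.name, seed=seed, n_exited=n_exited,
    )


_COORDS = {2: ("S", "I"), 3: ("S", "I", "R")}


def summary_to_table(summary: EnsembleSummary) -> pd.DataFrame:
    """Lossless flattening to (t, coord, mean, var) rows.

    Row count is n_times * n_coordinates; round-trips through the CSV
    writer/reader at full double precision.
    """
    n_times, d = summary.mean.shape
    coords = _COORDS[d]
    return pd.DataFrame(
        {
            "t": np.repeat(summary.times, d),
            "coord": np.tile(coords, n_times),
            "mean": summary.mean.ravel(),
            "var": summary.variance.ravel(),
        }
    )


def write_table(df: pd.DataFrame, path) -> None:
    """Write a tabular result as RFC-4180 CSV with a header row.

    Floats are written with 17 significant digits so they round-trip in
    double precision.
    """
    df.to_csv(path, index=False, float_format="%.17g")


def read_table(path) -> pd.DataFrame:
    """Read back a CSV written by :func:`write_table` (exact float parsing)."""
    return pd.read_csv(path, float_precision="round_trip")
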