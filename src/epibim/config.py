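"""Run configuration: flat YAML keys, validation, round-trip serialization."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional

import yaml

from .models import (
    SIR,
    SIS,
    BUILTIN_RATE_NAMES,
    EpidemicParams,
    InvalidInputError,
    RatePair,
    builtin_rates,
    in_domain,
)

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Raised for missing or inconsistent configuration keys."""


@dataclass
class RunConfig:
    """Flat configuration for a simulation run.

    ``R0`` is the initial removed population (SIR only) — not to be confused
    with the basic reproduction number, which is always derived from the
    rate parameters.
    """

    model: str = SIS
    scheme: str = "bim"
    alpha: float = 13.0
    beta: float = 0.02
    gamma: float = 13.0
    mu: float = 0.013
    K: float = 200.0
    rates: str = "sis-linear"
    S0: float = 190.0
    I0: float = 10.0
    R0: Optional[float] = None
    dt: float = 0.01
    T: float = 2.0
    M: int = 1
    seed: Optional[int] = None
    out: Optional[str] = None

    def validate(self) -> "RunConfig":
        if self.model not in (SIR, SIS):
            raise ConfigError(f"model must be 'sir' or 'sis', got {self.model!r}")
        if self.scheme not in ("bim", "em"):
            raise ConfigError(f"scheme must be 'bim' or 'em', got {self.scheme!r}")
        if self.rates not in BUILTIN_RATE_NAMES:
            raise ConfigError(f"unknown rates fixture {self.rates!r}")
        try:
            params = self.params
        except InvalidInputError as e:
            raise ConfigError(str(e)) from e
        if self.model == SIR and self.R0 is None:
            raise ConfigError("SIR runs require the initial removed population R0")
        chk = in_domain(self.initial_state, self.model, params.K)
        if not chk:
            raise ConfigError(f"initial state outside domain: violated {chk.violations}")
        if not (self.dt > 0 and self.T > 0 and self.M >= 1):
            raise ConfigError("require dt > 0, T > 0, M >= 1")
        return self

    @property
    def params(self) -> EpidemicParams:
        return EpidemicParams(alpha=self.alpha, beta=self.beta, gamma=self.gamma,
                              mu=self.mu, K=self.K)

    @property
    def initial_state(self):
        if self.model == SIR:
            return (self.S0, self.I0, self.R0)
        return (self.S0, self.I0)

    @property
    def rate_pair(self) -> RatePair:
        return builtin_rates(self.rates, self.params)

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path) -> RunConfig:
    """Parse a YAML config file into a validated :class:`RunConfig`."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping of flat keys")
    return RunConfig.from_dict(data).validate()


def save_config(config: RunConfig, path) -> None:
    """Serialize a config as flat YAML keys; ``load_config`` inverts this."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
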