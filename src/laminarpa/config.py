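"""Analysis configuration.

A single flat key-value structure mirrors the tunable parameters of the
whole pipeline: band-splitting filter, CSD estimator, penalty weight, the
differential-evolution optimizer budget, and the search bounds for the
trapezoid spatial profiles and the postsynaptic kernels. Configurations can
be read from / written to YAML (or JSON, which YAML subsumes); command-line
flags override file values.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from enum import Enum
from pathlib import Path

import yaml

__all__ = ["CsdMethod", "AnalysisConfig"]


class CsdMethod(str, Enum):
    DELTA_ICSD = "delta_icsd"
    TRADITIONAL = "traditional"


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunable parameters of an LPA run.

    Attributes
    ----------
    n_populations
        Number of laminar populations assumed a priori (N_pop >= 1).
    cutoff_hz, filter_order
        Butterworth cutoff and order for the LFP/MUA band split.
    csd_method
        ``delta_icsd`` (disc model, radius ``disc_radius_um``) or
        ``traditional`` (second spatial derivative).
    lambda_penalty
        Weight of the zero-channel-sum penalty in the CSD cost (>= 0).
    de_popsize, de_maxiter, de_tol
        Differential-evolution population-size multiplier, iteration cap,
        and convergence tolerance (both the spatial-profile and the kernel
        fits use the same seeded global optimizer).
    rng_seed
        Seed for every stochastic step; identical seeds give bit-identical
        results.
    tau_bounds_ms, delta_bounds_ms
        Search bounds for the kernel time constant and delay.
    trapezoid_a_bounds_um, trapezoid_b_bounds_um
        Search bounds for the plateau width a and ramp width b of the
        trapezoid spatial profiles; an upper bound of None is resolved
        against the probe span at fit time.
    """

    n_populations: int = 5
    cutoff_hz: float = 300.0
    filter_order: int = 5
    csd_method: CsdMethod = CsdMethod.DELTA_ICSD
    disc_radius_um: float = 400.0
    conductivity_s_per_m: float = 0.3
    lambda_penalty: float = 0.0
    de_popsize: int = 15
    de_maxiter: int = 400
    de_tol: float = 1e-6
    rng_seed: int = 0
    tau_bounds_ms: tuple[float, float] = (1.0, 100.0)
    delta_bounds_ms: tuple[float, float] = (0.0, 50.0)
    trapezoid_a_bounds_um: tuple[float, float | None] = (0.0, None)
    trapezoid_b_bounds_um: tuple[float, float | None] = (2.0, None)
    mua_smooth_ms: float = 2.0

    def __post_init__(self) -> None:
        if self.n_populations < 1:
            raise ValueError("n_populations must be >= 1")
        if self.lambda_penalty < 0:
            raise ValueError("lambda_penalty must be >= 0")
        if self.cutoff_hz <= 0 or self.filter_order < 1:
            raise ValueError("invalid filter settings")
        if self.de_popsize < 5 or self.de_maxiter < 1 or self.de_tol <= 0:
            raise ValueError("invalid optimizer settings")
        for name in ("tau_bounds_ms", "delta_bounds_ms"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must satisfy min < max, got {(lo, hi)}")
        if self.tau_bounds_ms[0] <= 0:
            raise ValueError("tau lower bound must be positive")
        if self.delta_bounds_ms[0] < 0:
            raise ValueError("delta lower bound must be >= 0 (causality)")
        for name in ("trapezoid_a_bounds_um", "trapezoid_b_bounds_um"):
            lo, hi = getattr(self, name)
            if hi is not None and not lo < hi:
                raise ValueError(f"{name} must satisfy min < max, got {(lo, hi)}")
        if self.trapezoid_b_bounds_um[0] <= 0:
            raise ValueError("trapezoid ramp width b must have a positive lower bound")
        object.__setattr__(self, "csd_method", CsdMethod(self.csd_method))

    def override(self, **kwargs) -> "AnalysisConfig":
        """Return a copy with the given fields replaced (None values ignored)."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **updates)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["csd_method"] = self.csd_method.value
        for key, value in d.items():
            if isinstance(value, tuple):
                d[key] = list(value)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        for key, value in kwargs.items():
            if isinstance(value, list):
                kwargs[key] = tuple(value)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)
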