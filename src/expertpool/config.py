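"""Run configuration: documented defaults, YAML override, CLI override."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import yaml


@dataclass(frozen=True)
class RunConfig:
    """All tunable parameters with their documented defaults.

    Precedence: CLI flags > config file > these defaults.
    """

    eps: float = 0.01            # floor added to unnormalised proxy weights
    clip_eps: float = 0.01       # probability clamp before logit transforms
    beta_alpha: float = 7.0      # symmetric Beta(a, a) extremisation parameter
    shift_bound_factor: float = 0.25  # weight of bound shifts vs best-estimate shifts
    log_base: str = "natural"    # informativeness unit: natural | base2
    brier_variant: str = "single_term"  # single_term | two_term
    # three-variance model
    prior_sd: float = 1.0
    sigma_bounds: tuple[float, float] = (0.0, 2.0)
    bound_coverage_z: float = 1.645
    # MCMC
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls().override(**raw)

    def override(self, **kwargs) -> "RunConfig":
        known = {f.name for f in fields(self)}
        unknown = set(kwargs) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        clean = {k: v for k, v in kwargs.items() if v is not None}
        if "sigma_bounds" in clean:
            clean["sigma_bounds"] = tuple(clean["sigma_bounds"])
        return replace(self, **clean)
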