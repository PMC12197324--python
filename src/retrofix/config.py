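"""Run configuration: defaults, file loading, validation, output provenance."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from retrofix.gillespie import StochasticParams
from retrofix.xrv_ode import HostDemography

__all__ = ["RunConfig", "load_config", "write_table"]

_DETERMINISTIC_KEYS = {
    "b0", "v0", "K", "M", "alpha", "delta", "n", "h", "t_max_ode",
    "window", "tol",
}
_STOCHASTIC_KEYS = {
    "b0", "v0", "K", "x", "m", "y", "r", "alpha", "beta", "L", "t_max",
}
_GLOBAL_KEYS = {"seed", "n_repeats", "model"}


@dataclass
class RunConfig:
    """Validated parameter bundle for either model.

    Defaults are the reference configuration: ``b0=1``, ``v0=0.2``,
    ``alpha=1``, ``K=1000`` (stochastic; the deterministic model is
    scale-free in K), ``L=10`` loci.
    """

    model: str = "stochastic"
    seed: int = 0
    n_repeats: int = 2000
    b0: float = 1.0
    v0: float = 0.2
    K: int = 1000
    alpha: float = 1.0
    # deterministic-model controls
    M: float = 0.0
    delta: float = 0.001
    n: int = 1100
    h: float = 0.01
    t_max_ode: float = 1e5
    window: float = 100.0
    tol: float = 1e-7
    # stochastic-model parameters
    x: float = 1.0
    m: float = 0.0
    y: float = 0.0
    r: float = 0.1
    beta: float = 1.0
    L: int = 10
    t_max: float = 1e5
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in ("deterministic", "stochastic"):
            raise ValueError("model must be 'deterministic' or 'stochastic'")
        # delegate invariant checks to the owning modules
        HostDemography(b0=self.b0, v0=self.v0, K=max(float(self.K), 1.0))
        if self.model == "stochastic":
            self.stochastic_params()

    def stochastic_params(self) -> StochasticParams:
        return StochasticParams(
            K=self.K, b0=self.b0, v0=self.v0, x=self.x, m=self.m, y=self.y,
            r=self.r, alpha=self.alpha, beta=self.beta, L=self.L,
            t_max=self.t_max,
        )

    def demography(self, K: float | None = None) -> HostDemography:
        return HostDemography(b0=self.b0, v0=self.v0,
                              K=K if K is not None else float(self.K))

    def provenance_header(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "extra"}
        return "# retrofix config: " + json.dumps(payload, sort_keys=True)


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Load a YAML or JSON config file, apply overrides, and validate.

    Unknown keys raise a descriptive error; an empty (or absent) file yields
    all defaults.
    """
    data: dict = {}
    if path is not None:
        raw = Path(path).read_text()
        data = yaml.safe_load(raw) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config root must be a mapping, got {type(data)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = _GLOBAL_KEYS | _DETERMINISTIC_KEYS | _STOCHASTIC_KEYS
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def write_table(df, path: str | Path, config: RunConfig | None = None) -> None:
    """Write a CSV with a provenance header comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config is not None:
            fh.write(config.provenance_header() + "\n")
        df.to_csv(fh, index=False)
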