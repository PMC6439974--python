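"""Flat key=value run configuration.

One file maps onto the Monte Carlo and driver-loop parameters plus the
input/output paths; command-line flags override file values.  Unknown keys
are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

from .optimize import BarsConfig
from .sampling import MCConfig

__all__ = ["RunConfig", "read_config"]

_INT_KEYS = {
    "max_steps",
    "window",
    "max_fail",
    "paths_per_lp",
    "radius_paths",
    "m_neighbors",
    "max_iterations",
    "max_points",
    "seed",
}
_FLOAT_KEYS = {"temperature", "sigma", "convergence_tau"}
_PATH_KEYS = {"native", "weights", "outdir"}
_ALL_KEYS = _INT_KEYS | _FLOAT_KEYS | _PATH_KEYS


@dataclass
class RunConfig:
    """All tunables of one run in one place, with documented defaults."""

    native: str | None = None
    weights: str | None = None
    outdir: str | None = None
    seed: int = 0
    temperature: float = 2.0
    max_steps: int = 500
    window: int = 3
    sigma: float = 10.0
    max_fail: int = 200
    paths_per_lp: int = 10
    radius_paths: int = 50
    m_neighbors: int = 1000
    convergence_tau: float = 0.3
    max_iterations: int = 20
    max_points: int = 60

    def mc_config(self) -> MCConfig:
        return MCConfig(
            temperature=self.temperature,
            max_steps=self.max_steps,
            window=self.window,
            sigma=self.sigma,
            max_fail=self.max_fail,
            seed=self.seed,
        )

    def bars_config(self) -> BarsConfig:
        return BarsConfig(
            paths_per_lp=self.paths_per_lp,
            radius_paths=self.radius_paths,
            m_neighbors=self.m_neighbors,
            convergence_tau=self.convergence_tau,
            max_iterations=self.max_iterations,
            max_points=self.max_points,
            mc=self.mc_config(),
            seed=self.seed,
        )

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def read_config(path: str | Path) -> RunConfig:
    """Parse a flat ``key = value`` file; '#' starts a comment."""
    cfg = RunConfig()
    for lineno, raw in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), 1
    ):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        if key not in _ALL_KEYS:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        if key in _INT_KEYS:
            setattr(cfg, key, int(value))
        elif key in _FLOAT_KEYS:
            setattr(cfg, key, float(value))
        else:
            setattr(cfg, key, value)
    return cfg
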