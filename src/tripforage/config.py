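"""Run configuration: validated parameter blocks loaded from YAML or JSON."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .core import EnvironmentBelief, ForagerParams
from .forager import StrategyConfig

__all__ = [
    "RunConfig",
    "EnvironmentBlock",
    "ForagerBlock",
    "StrategyBlock",
    "NumericsBlock",
    "SweepBlock",
    "load_config",
]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class EnvironmentBlock(_Block):
    p: float = Field(ge=0, description="patch density per unit distance")
    gamma: float = Field(ge=0, description="linear decay of patch quality with distance")
    mu: float = Field(gt=0, description="patch harvest rate at distance 0")
    D: float = Field(gt=0, description="environment size")


class ForagerBlock(_Block):
    R0: float = Field(gt=0, description="harvest rate on the known patch")
    RDelta: float = Field(lt=0, description="energy rate while travelling")
    T: float = Field(gt=0, description="evaluation horizon")
    v: float = Field(default=1.0, description="travel speed (fixed at 1)")


class StrategyBlock(_Block):
    mode: Literal["plan_once", "replan", "local_rule"] = "plan_once"
    M: int = Field(default=1, ge=1, description="planning horizon in trips")
    n_episodes: int = Field(default=0, ge=0)
    seed: int = 0


class NumericsBlock(_Block):
    grid_n: int = Field(default=400, ge=2, description="planner grid resolution")
    circuit_n: int = Field(default=200, ge=2, description="circuit grid resolution")
    refine: bool = True


class SweepBlock(_Block):
    p_values: list[float]
    gamma_values: list[float]
    M: int = Field(default=4, ge=1)
    grid_n: int = Field(default=150, ge=2)


class RunConfig(_Block):
    environment: EnvironmentBlock
    forager: ForagerBlock
    strategy: StrategyBlock = StrategyBlock()
    numerics: NumericsBlock = NumericsBlock()
    sweep: Optional[SweepBlock] = None

    def belief(self) -> EnvironmentBelief:
        e = self.environment
        return EnvironmentBelief(p=e.p, gamma=e.gamma, mu=e.mu, D=e.D)

    def params(self) -> ForagerParams:
        f = self.forager
        return ForagerParams(R0=f.R0, RDelta=f.RDelta, T=f.T, v=f.v)

    def strategy_config(self) -> StrategyConfig:
        s = self.strategy
        return StrategyConfig(
            mode=s.mode,
            M=s.M,
            seed=s.seed,
            n_episodes=s.n_episodes,
            grid_n=self.numerics.grid_n,
        )

    def validate_model(self) -> None:
        """Re-check every core-model constraint (raises on violation, may warn)."""
        belief = self.belief()
        params = self.params()
        belief.require_profitable(params)

    def hash(self) -> str:
        """Stable digest of the resolved configuration (logged with every run)."""
        canon = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and fully validate a YAML or JSON run configuration.

    Unknown keys are rejected; the error names the offending key.  The
    core-model constraints (sign conditions, mu > R0, the gamma*D warning)
    are re-validated on load, not just at use.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text())  # YAML is a JSON superset
    if not isinstance(raw, dict):
        raise ValueError(f"{path} does not contain a mapping")
    try:
        cfg = RunConfig.model_validate(raw)
    except ValidationError as err:
        locs = ", ".join(".".join(str(x) for x in e["loc"]) or "<root>" for e in err.errors())
        raise ValueError(f"invalid configuration {path}: offending key(s): {locs}") from err
    cfg.validate_model()
    return cfg
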