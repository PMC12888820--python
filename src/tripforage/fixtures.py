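"""Named parameter presets used throughout the examples and tests.

Three study regimes:

* ``two_trip`` — a short horizon with moderately dense, slowly decaying
  patches, where splitting one long exploration into a short-then-long
  pair of trips starts to pay off;
* ``multi_trip`` — a long horizon with dense patches and faster quality
  decay, where optimal sequences use several successively longer trips and
  the three strategies (plan-once, re-plan, local rule) can be compared;
* ``circuit_demo`` — a sparse environment with a steep relative-rate
  profile, convenient for watching the winner-take-all circuit make two
  successive trip decisions.  The caption-level quantities here are the
  relative ones (``R(d)/R0 = 40 (1 - 0.0004 d)`` and ``|RDelta|/R0 = 1``);
  the absolute scale is fixed by choosing ``R0 = 1`` and ``T = 8000``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import yaml

from .config import RunConfig

__all__ = ["two_trip", "multi_trip", "circuit_demo", "PRESETS", "write_preset"]


def two_trip() -> RunConfig:
    return RunConfig.model_validate(
        {
            "environment": {"p": 0.24771, "gamma": 0.001, "mu": 10.0, "D": 1000.0},
            "forager": {"R0": 0.1, "RDelta": -0.1, "T": 8000.0},
        }
    )


def multi_trip() -> RunConfig:
    return RunConfig.model_validate(
        {
            "environment": {"p": 0.24771, "gamma": 0.0006, "mu": 10.0, "D": 1000.0},
            "forager": {"R0": 0.25, "RDelta": -0.25, "T": 24000.0},
        }
    )


def circuit_demo() -> RunConfig:
    return RunConfig.model_validate(
        {
            "environment": {"p": 0.0061359, "gamma": 0.0004, "mu": 40.0, "D": 1000.0},
            "forager": {"R0": 1.0, "RDelta": -1.0, "T": 8000.0},
        }
    )


PRESETS = {
    "two_trip": two_trip,
    "multi_trip": multi_trip,
    "circuit_demo": circuit_demo,
}


def write_preset(name: str, path: Union[str, Path]) -> Path:
    """Emit a preset as a YAML config file (the CLI's fixture generator)."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    cfg = PRESETS[name]()
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
    return path
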