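"""JSON run configuration: schema validation and dispatch metadata.

A run configuration names one subcommand and supplies its parameter block;
unknown keys are rejected by name so that typos fail loudly.  Stochastic
subcommands require a seed, making every run reproducible from its manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["RunConfig", "load_config", "SCHEMAS"]

# allowed keys and defaults per subcommand; None marks "required"
SCHEMAS: dict[str, dict[str, object]] = {
    "simulate": {
        "panel": "", "mu": 0.03, "F": 1.0, "H": 1.0, "w": 0.0,
        "p0": 0.01, "generations": 1000,
    },
    "equilibria": {
        "mu": 0.03, "F": 1.0, "H": 1.0, "w": 0.0,
        "w_sweep": [],
    },
    "abm": {
        "n_hosts": 10_000, "visit_prob": 0.3, "infect_prob": 0.938,
        "survive_prob": 0.302, "infectious_visits": 1, "kill_hosts": False,
        "mu": 0.03, "F": 1.0, "H": 1.0, "p0": 0.01,
        "generations": 50, "replicates": 10,
    },
    "synth": {
        "experiment": None,  # transmission | persistence | decay | fitness
    },
    "analyze": {
        "experiment": None, "input": None,
    },
}

_STOCHASTIC = {"abm", "synth"}


@dataclass(frozen=True)
class RunConfig:
    subcommand: str
    params: dict = field(default_factory=dict)
    out_dir: str = "."
    seed: int | None = None
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "subcommand": self.subcommand, "params": dict(self.params),
            "out_dir": self.out_dir, "seed": self.seed,
            "log_level": self.log_level,
        }


def _validate(subcommand: str, params: dict, seed: int | None) -> dict:
    if subcommand not in SCHEMAS:
        raise ValueError(
            f"unknown subcommand {subcommand!r}; expected one of {sorted(SCHEMAS)}"
        )
    schema = SCHEMAS[subcommand]
    unknown = sorted(set(params) - set(schema))
    if unknown:
        raise ValueError(
            f"unknown keys for {subcommand!r}: {', '.join(unknown)}"
        )
    merged = {**schema, **params}
    missing = [k for k, v in merged.items() if v is None]
    if missing:
        raise ValueError(
            f"missing required keys for {subcommand!r}: {', '.join(sorted(missing))}"
        )
    if subcommand in _STOCHASTIC and seed is None:
        raise ValueError(f"subcommand {subcommand!r} requires a seed")
    return merged


def make_config(subcommand: str, params: dict | None = None, out_dir: str = ".",
                seed: int | None = None, log_level: str = "INFO") -> RunConfig:
    merged = _validate(subcommand, params or {}, seed)
    return RunConfig(subcommand=subcommand, params=merged, out_dir=out_dir,
                     seed=seed, log_level=log_level)


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a JSON run configuration file."""
    raw = json.loads(Path(path).read_text())
    allowed_top = {"subcommand", "params", "out_dir", "seed", "log_level"}
    unknown = sorted(set(raw) - allowed_top)
    if unknown:
        raise ValueError(f"unknown top-level keys: {', '.join(unknown)}")
    if "subcommand" not in raw:
        raise ValueError("missing required field 'subcommand'")
    return make_config(
        subcommand=raw["subcommand"], params=raw.get("params", {}),
        out_dir=raw.get("out_dir", "."), seed=raw.get("seed"),
        log_level=raw.get("log_level", "INFO"),
    )


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config.to_dict(), indent=2) + "\n")
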