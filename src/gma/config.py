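"""Run configuration: TOML/JSON files mapped onto the parameter
dataclasses, with unknown keys rejected."""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field, asdict, fields
from pathlib import Path
from typing import Any

from .aggregation import AggregationParams
from .errors import ParameterError
from .synthdb import DbConfig


def _build(cls, data: dict[str, Any], section: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ParameterError(
            f"unknown key(s) in [{section}]: {', '.join(sorted(unknown))}"
        )
    return cls(**data)


@dataclass
class RunConfig:
    """Top-level configuration: [aggregation] and [db] sections plus a
    global seed and log level."""

    aggregation: AggregationParams = field(default_factory=AggregationParams)
    db: DbConfig = field(default_factory=DbConfig)
    seed: int = 0
    log_level: str = "WARNING"

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        data = dict(data)
        agg = _build(AggregationParams, data.pop("aggregation", {}), "aggregation")
        db = _build(DbConfig, data.pop("db", {}), "db")
        unknown = set(data) - {"seed", "log_level"}
        if unknown:
            raise ParameterError(f"unknown top-level key(s): {', '.join(sorted(unknown))}")
        return cls(
            aggregation=agg,
            db=db,
            seed=int(data.get("seed", 0)),
            log_level=str(data.get("log_level", "WARNING")),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = tomllib.loads(text)
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["aggregation"]["functional"] = str(
            self.aggregation.functional.value
            if hasattr(self.aggregation.functional, "value")
            else self.aggregation.functional
        )
        return d
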