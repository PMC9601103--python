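"""Run configuration: defaults, YAML file values, and flag overrides.

Precedence is flags > config file > defaults.  The effective configuration
is written beside the outputs for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from fractions import Fraction
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "DEFAULTS"]


@dataclass
class RunConfig:
    modules: str | None = None
    annotations: str | None = None
    bins: str | None = None
    metadata: str | None = None
    suites: str | None = None
    groups: str | None = None
    threshold: float = float(Fraction(2, 3))
    count_mode: str = "steps"
    evalue_thresholds: dict = field(default_factory=dict)
    nif_emax: float = 1e-100
    out_dir: str = "."
    seed: int = 0
    log_level: str = "INFO"

    def validate(self, check_paths: bool = True) -> None:
        if not 0 < self.threshold <= 1:
            raise ValueError(f"threshold must lie in (0, 1], got {self.threshold}")
        if self.count_mode not in ("steps", "genes"):
            raise ValueError("count_mode must be 'steps' or 'genes'")
        if check_paths:
            for key in ("modules", "annotations", "bins", "metadata", "suites", "groups"):
                value = getattr(self, key)
                if value is not None and not Path(value).exists():
                    raise FileNotFoundError(f"{key} path does not exist: {value}")

    def write_provenance(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(asdict(self), sort_keys=True), encoding="utf-8"
        )


DEFAULTS = RunConfig()
_VALID_KEYS = tuple(f.name for f in fields(RunConfig))


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Build the effective config: overrides > file values > defaults.

    Overrides with value ``None`` are ignored (unset flags).  Unknown keys
    in the file raise, listing the valid keys.
    """
    values: dict = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a key-value mapping")
        for key in raw:
            if key not in _VALID_KEYS:
                raise ValueError(
                    f"{path}: unknown config key {key!r}; valid keys: "
                    + ", ".join(_VALID_KEYS)
                )
        values.update(raw)
    for key, value in overrides.items():
        if key not in _VALID_KEYS:
            raise ValueError(f"unknown config key {key!r}")
        if value is not None:
            values[key] = value
    cfg = RunConfig(**values)
    cfg.validate(check_paths=False)
    return cfg
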