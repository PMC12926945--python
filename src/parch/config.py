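"""Run configuration: one structured YAML document covering every stage.

Every field is optional with a stated default; unknown keys are rejected so a
typo cannot silently fall back to a default. The loaded configuration is
echoed verbatim into the log, and its hash goes into every run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .parch_scoring import AnnealingSchedule, ContactParams
from .ptm_compare import CompareParams
from .shell_builder import ShellParams

logger = logging.getLogger("parch")

__all__ = ["RunConfig", "load_config", "setup_logging", "ConfigError"]


class ConfigError(ValueError):
    """Raised for unknown keys or invalid values in a config document."""


@dataclass
class RunConfig:
    shell: ShellParams = field(default_factory=ShellParams)
    schedule: AnnealingSchedule = field(default_factory=AnnealingSchedule)
    contact: ContactParams = field(default_factory=ContactParams)
    compare: CompareParams = field(default_factory=CompareParams)
    w_init: float = 0.05       # initial scoring-window fraction
    w_final: float = 0.05      # final scoring-window fraction
    time_offset: float = 0.0   # ps of pre-ramp frames to discard
    replicates: int = 5
    seed: int = 1

    def to_dict(self) -> dict:
        return {
            "shell": dataclasses.asdict(self.shell),
            "schedule": dataclasses.asdict(self.schedule),
            "contact": dataclasses.asdict(self.contact),
            "compare": dataclasses.asdict(self.compare),
            "w_init": self.w_init, "w_final": self.w_final,
            "time_offset": self.time_offset,
            "replicates": self.replicates, "seed": self.seed,
        }

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def log_thresholds(self) -> None:
        """Echo every threshold actually applied, so reports are self-describing."""
        logger.info("d_shell = %g nm", self.shell.d_shell)
        logger.info("d_water = %g nm", self.contact.d_water)
        logger.info("neighbor_cutoff = %g nm", self.compare.neighbor_cutoff)
        logger.info("delta_threshold = +/-%g PV units", self.compare.delta_threshold)
        logger.info("ramp %g -> %g K at %g K/ps", self.schedule.T_start,
                    self.schedule.T_end, self.schedule.rate)


_SECTION_TYPES = {
    "shell": ShellParams,
    "schedule": AnnealingSchedule,
    "contact": ContactParams,
    "compare": CompareParams,
}
_SCALARS = {"w_init", "w_final", "time_offset", "replicates", "seed"}


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config; missing file/None gives all defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config document must be a mapping")
    kwargs: dict = {}
    for key, value in raw.items():
        if key in _SECTION_TYPES:
            cls = _SECTION_TYPES[key]
            known = {f.name for f in dataclasses.fields(cls)}
            bad = set(value) - known
            if bad:
                raise ConfigError(f"unknown keys in '{key}': {sorted(bad)}")
            try:
                kwargs[key] = cls(**value)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"invalid '{key}' section: {exc}") from exc
        elif key in _SCALARS:
            kwargs[key] = value
        else:
            raise ConfigError(f"unknown config key: {key!r}")
    cfg = RunConfig(**kwargs)
    logger.info("loaded config %s: %s", path, json.dumps(cfg.to_dict(), sort_keys=True))
    return cfg


def setup_logging(level: int = logging.INFO) -> None:
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("parch")
    if not root.handlers:
        root.addHandler(handler)
    root.setLevel(level)
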