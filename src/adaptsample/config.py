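"""Run configuration: YAML schema, validation, defaults, and manifests.

A run is fully determined by (configuration, seed, fixture files); the
:class:`RunManifest` records all three plus output paths so any result can
be regenerated byte-for-byte.
"""

from __future__ import annotations

import datetime as dt
import hashlib
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .covariates import Site, default_sites
from .scheduling import SUPPORTED_FIXED_EFFORTS

__all__ = ["RunConfig", "RunManifest", "load_config", "dump_config", "build_manifest"]

_DEFAULT_EFFORTS = list(SUPPORTED_FIXED_EFFORTS)

_FIXTURES = ("vocalization_models.csv", "monthly_weather.csv", "fixed_schedules.csv")


class ConfigError(ValueError):
    """A configuration file failed validation."""


@dataclass
class RunConfig:
    """Validated configuration for a factorial run.

    ``sites`` is either an integer count (synthetic sites in the default
    study area) or a list of (site_id, latitude, longitude) mappings.
    ``p_star_max`` is the capture threshold applied to every species-site
    (0.95 unless overridden).  ``treatments`` defaults to both.
    """

    seed: int = 0
    year: int = 2016
    sites: int | list = 133
    efforts: list = field(default_factory=lambda: list(_DEFAULT_EFFORTS))
    treatments: list = field(default_factory=lambda: ["fixed", "optimized"])
    durations: list = field(default_factory=lambda: ["full_year", "march_only"])
    p_star_max: float = 0.95
    minute_scaling: bool = True
    expected_captures: bool = False
    models_csv: str | None = None
    weather_csv: str | None = None

    def site_objects(self) -> list[Site]:
        if isinstance(self.sites, int):
            return default_sites(self.sites, seed=self.seed + 1)
        return [
            Site(str(s["site_id"]), float(s["latitude"]), float(s["longitude"]))
            for s in self.sites
        ]


_VALID_DURATIONS = {"full_year", "march_only"}


def _validate(cfg: RunConfig) -> RunConfig:
    if not isinstance(cfg.seed, int):
        raise ConfigError(f"seed must be an integer, got {cfg.seed!r}")
    if isinstance(cfg.sites, int):
        if cfg.sites < 1:
            raise ConfigError("sites: count must be >= 1")
    else:
        ids = [s.get("site_id") for s in cfg.sites]
        if len(set(ids)) != len(ids):
            raise ConfigError("sites: site_id values must be unique")
        cfg.site_objects()  # raises on bad coordinates
    bad = set(cfg.treatments) - {"fixed", "optimized"}
    if bad:
        raise ConfigError(f"treatments: unknown entries {sorted(bad)}")
    bad = set(cfg.durations) - _VALID_DURATIONS
    if bad:
        raise ConfigError(f"durations: unknown entries {sorted(bad)}")
    for s in cfg.efforts:
        if not isinstance(s, int) or s < 1:
            raise ConfigError(f"efforts: {s!r} is not a positive integer")
        if "fixed" in cfg.treatments and s not in SUPPORTED_FIXED_EFFORTS:
            raise ConfigError(
                f"efforts: S={s} has no fixed baseline schedule "
                f"(supported: {list(SUPPORTED_FIXED_EFFORTS)})"
            )
    if cfg.p_star_max <= 0:
        raise ConfigError("p_star_max must be > 0")
    if cfg.p_star_max > 1 and not cfg.expected_captures:
        raise ConfigError(
            "p_star_max above 1 requires expected_captures: true"
        )
    for attr in ("models_csv", "weather_csv"):
        p = getattr(cfg, attr)
        if p is not None and not Path(p).exists():
            raise ConfigError(f"{attr}: file not found: {p}")
    return cfg


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration, filling defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    return _validate(RunConfig(**data))


def dump_config(cfg: RunConfig, path) -> None:
    """Write a configuration back to YAML (round-trips with load_config)."""
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)


def _fixture_hashes() -> dict[str, str]:
    hashes = {}
    for name in _FIXTURES:
        ref = resources.files("adaptsample.data") / name
        hashes[name] = hashlib.sha256(ref.read_bytes()).hexdigest()[:16]
    return hashes


@dataclass
class RunManifest:
    """Everything needed to regenerate a run's outputs byte-for-byte."""

    config: dict
    seed: int
    fixture_hashes: dict
    outputs: list
    created_utc: str

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def build_manifest(cfg: RunConfig, outputs) -> RunManifest:
    return RunManifest(
        config=asdict(cfg),
        seed=cfg.seed,
        fixture_hashes=_fixture_hashes(),
        outputs=[str(p) for p in outputs],
        created_utc=dt.datetime.now(dt.timezone.utc).isoformat(timespec="seconds"),
    )
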