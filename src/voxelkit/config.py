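"""Application configuration: named remotes, workers, cache settings.

The config file is TOML. Example::

    workers = 4
    log_level = "INFO"

    [remotes.local]
    type = "file"               # memory | file | http
    root = "/data/volumes"      # file remotes
    chunk_shape = [512, 512, 16]

    [remotes.lab]
    type = "http"
    url = "http://lab-server:8000"

    [cache]
    capacity_mb = 64
    dir = "/tmp/vk-cache"       # omit for an in-memory cache

Every named remote must resolve to a constructed Remote at startup;
unknown keys raise :class:`~voxelkit.errors.ConfigError` naming the key.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

from .core import Remote
from .errors import ConfigError

__all__ = ["AppConfig", "load_config"]

_TOP_KEYS = {"remotes", "workers", "log_level", "cache"}
_REMOTE_KEYS = {"type", "root", "url", "chunk_shape", "timeout", "retries"}
_CACHE_KEYS = {"capacity_mb", "dir"}


@dataclass
class AppConfig:
    remotes: Dict[str, dict] = field(default_factory=dict)
    workers: int = 4
    log_level: str = "WARNING"
    cache: dict = field(default_factory=dict)

    def build_remote(self, name: str) -> Remote:
        """Construct the named remote, raising ConfigError for unknown
        names or unresolvable definitions."""
        if name not in self.remotes:
            raise ConfigError(f"unknown remote name {name!r}; configured: {sorted(self.remotes)}")
        return _build(name, self.remotes[name])

    def build_all(self) -> Dict[str, Remote]:
        return {name: self.build_remote(name) for name in self.remotes}


def _check_keys(mapping: dict, allowed: set, context: str) -> None:
    for key in mapping:
        if key not in allowed:
            raise ConfigError(f"unknown config key {key!r} in {context}")


def _build(name: str, spec: dict) -> Remote:
    _check_keys(spec, _REMOTE_KEYS, f"remotes.{name}")
    rtype = spec.get("type")
    chunk_shape = tuple(spec.get("chunk_shape", (512, 512, 16)))
    if rtype == "memory":
        from .remotes import InMemoryRemote

        return InMemoryRemote(default_chunk_shape=chunk_shape)
    if rtype == "file":
        if "root" not in spec:
            raise ConfigError(f"remotes.{name}: file remote needs a 'root' path")
        from .remotes import FileChunkRemote

        return FileChunkRemote(spec["root"], default_chunk_shape=chunk_shape)
    if rtype == "http":
        if "url" not in spec:
            raise ConfigError(f"remotes.{name}: http remote needs a 'url'")
        from .remotes import HttpRemote

        return HttpRemote(
            spec["url"],
            timeout=float(spec.get("timeout", 10.0)),
            retries=int(spec.get("retries", 3)),
        )
    raise ConfigError(f"remotes.{name}: unknown remote type {rtype!r}")


def load_config(path) -> AppConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    _check_keys(doc, _TOP_KEYS, "top level")
    cache = doc.get("cache", {})
    _check_keys(cache, _CACHE_KEYS, "cache")
    remotes = doc.get("remotes", {})
    for name, spec in remotes.items():
        _check_keys(spec, _REMOTE_KEYS, f"remotes.{name}")
    return AppConfig(
        remotes=remotes,
        workers=int(doc.get("workers", 4)),
        log_level=str(doc.get("log_level", "WARNING")),
        cache=cache,
    )
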