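"""Run manifests, config files, and deterministic seed derivation.

Every CLI run writes its outputs into a directory together with a JSON
``manifest.json`` recording the exact configuration (and its hash), the
top-level seed, the derived per-stage seeds, the package version, and a
checksum inventory of every output file. Two runs with the same config
and seed produce byte-identical outputs and therefore the same
``run_hash``; timestamps are recorded separately so they never enter the
hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Optional

import yaml

__all__ = [
    "RunManifest",
    "derive_seed",
    "canonical_hash",
    "load_config_file",
    "ConfigError",
]

MAX_SEED = 2**31


class ConfigError(ValueError):
    """A config file failed to parse or validate; message names the file."""


def derive_seed(base: int, index: int) -> int:
    """Deterministic child seed for stage/replicate ``index`` (< 2**31)."""
    if not 0 <= base < MAX_SEED:
        raise ValueError("base seed must be in [0, 2**31)")
    return (base * 1_000_003 + 7919 * (index + 1)) % MAX_SEED


def canonical_hash(obj) -> str:
    """sha256 of the canonical (sorted-key, compact) JSON serialization."""
    payload = json.dumps(obj, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(payload.encode()).hexdigest()


def _file_sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config_file(path) -> dict:
    """Load a YAML or JSON config into a dict; raise ConfigError with the
    file (and, for syntax errors, line) identified."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as e:
        raise ConfigError(f"{path}: cannot read config: {e}") from e
    try:
        if path.suffix == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except json.JSONDecodeError as e:
        raise ConfigError(f"{path}:{e.lineno}: invalid JSON: {e.msg}") from e
    except yaml.YAMLError as e:
        mark = getattr(e, "problem_mark", None)
        where = f":{mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"{path}{where}: invalid YAML: {e}") from e
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping, got {type(data).__name__}")
    return data


@dataclass
class RunManifest:
    """Reproducibility record for one CLI run."""

    stage: str
    config: dict
    seed: int
    stage_seeds: dict = field(default_factory=dict)
    package_version: str = ""
    files: dict = field(default_factory=dict)  # name -> {"sha256", "bytes"}
    created_utc: str = ""

    def __post_init__(self) -> None:
        if not self.package_version:
            from . import __version__

            self.package_version = __version__
        if not self.created_utc:
            self.created_utc = datetime.now(timezone.utc).isoformat()

    @property
    def config_hash(self) -> str:
        return canonical_hash(self.config)

    @property
    def run_hash(self) -> str:
        """Hash of everything except timestamps: stable across re-runs."""
        return canonical_hash(
            {
                "stage": self.stage,
                "config_hash": self.config_hash,
                "seed": self.seed,
                "stage_seeds": self.stage_seeds,
                "package_version": self.package_version,
                "files": self.files,
            }
        )

    def add_file(self, path, root: Optional[Path] = None) -> None:
        path = Path(path)
        name = str(path.relative_to(root)) if root else path.name
        self.files[name] = {"sha256": _file_sha256(path), "bytes": path.stat().st_size}

    def add_directory(self, root) -> None:
        """Inventory every file under ``root`` (excluding the manifest)."""
        root = Path(root)
        for p in sorted(root.rglob("*")):
            if p.is_file() and p.name != "manifest.json":
                self.add_file(p, root=root)

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "config": self.config,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "stage_seeds": self.stage_seeds,
            "package_version": self.package_version,
            "files": self.files,
            "run_hash": self.run_hash,
            "created_utc": self.created_utc,
        }

    def write(self, out_dir) -> Path:
        out_dir = Path(out_dir)
        self.add_directory(out_dir)
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def load(cls, path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return cls(
            stage=d["stage"],
            config=d["config"],
            seed=d["seed"],
            stage_seeds=d.get("stage_seeds", {}),
            package_version=d.get("package_version", ""),
            files=d.get("files", {}),
            created_utc=d.get("created_utc", ""),
        )


def write_yaml(data: Mapping, path) -> None:
    Path(path).write_text(yaml.safe_dump(dict(data), sort_keys=True))
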