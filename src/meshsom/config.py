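"""Run configuration: validated settings shared by the CLI subcommands.

Defaults mirror the full-scale literature map (350x350 grid, 20 epochs,
sigma0 = 175, decay base 1.7, minimum term count 100); toy-scale runs
override them through a YAML file or command-line flags.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "write_provenance"]


@dataclass
class RunConfig:
    rows: int = 350
    cols: int = 350
    epochs: int = 20
    sigma0: float = 175.0
    decay_base: float = 1.7
    kernel: str = "gaussian"
    adjacency: str = "8"
    init: str = "sample"
    train_restarts: int = 1
    min_term_count: int = 100
    k_max: int = 12
    kmeans_restarts: int = 10
    title_threshold: float = 0.90
    journal_threshold: float = 0.80
    seed: int = 0
    domain_prefixes: list[str] = field(default_factory=lambda: ["F"])

    def validate(self) -> "RunConfig":
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be positive")
        if self.decay_base <= 1:
            raise ValueError("decay_base must be > 1")
        if self.kernel not in ("gaussian", "bubble"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.init not in ("sample", "pca", "pca_sample"):
            raise ValueError(f"unknown init {self.init!r}")
        if self.train_restarts < 1:
            raise ValueError("train_restarts must be >= 1")
        if self.adjacency not in ("8", "4"):
            raise ValueError(f"unknown adjacency {self.adjacency!r}")
        if self.min_term_count < 0:
            raise ValueError("min_term_count must be >= 0")
        if self.k_max < 3:
            raise ValueError("k_max must be >= 3")
        if self.kmeans_restarts < 1:
            raise ValueError("kmeans_restarts must be >= 1")
        for name in ("title_threshold", "journal_threshold"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        return self


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """YAML config with CLI overrides; unknown keys are rejected."""
    data: dict = {}
    if path is not None:
        with Path(path).open(encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data).validate()


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(
    out_path: str | Path, config: RunConfig, inputs: list[str | Path]
) -> None:
    """Provenance JSON (config, seeds, input digests, version) next to outputs."""
    from . import __version__

    record = {
        "config": asdict(config),
        "inputs": {
            str(p): _digest(Path(p)) for p in inputs if Path(p).is_file()
        },
        "version": __version__,
    }
    with Path(out_path).open("w", encoding="utf-8") as fh:
        json.dump(record, fh, indent=1, sort_keys=True)
        fh.write("\n")
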