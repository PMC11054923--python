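"""Run configuration: a serialisable description of one end-to-end run."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .classify import ALGORITHMS
from .processing import FilterSpec
from .protocol import RecordingProtocol, build_protocol

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run.

    Round-trips through YAML; ``config_hash`` fingerprints the scientific
    settings (not the output directory or log level) so artifacts can be
    tagged with the configuration that produced them.
    """

    protocol: dict = field(default_factory=dict)
    signatures: dict = field(default_factory=dict)   # per-action overrides
    filter: dict = field(default_factory=dict)
    algorithms: list = field(default_factory=lambda: list(ALGORITHMS))
    k_range: list = field(default_factory=lambda: [1, 12])
    subsets_per_k: int | None = None
    n_folds: int = 5
    n_participants: int = 1
    master_seed: int = 0
    out_dir: str = "semgpipe_out"
    log_level: str = "INFO"

    def build_protocol(self) -> RecordingProtocol:
        return build_protocol(self.protocol)

    def build_filter(self) -> FilterSpec:
        return FilterSpec(**self.filter)

    def k_values(self) -> range:
        lo, hi = self.k_range
        return range(int(lo), int(hi) + 1)

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir")
        d.pop("log_level")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
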