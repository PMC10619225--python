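"""Pipeline configuration, seed fan-out and run manifests."""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

__all__ = ["PipelineConfig", "RunManifest", "derive_seed"]

__version__ = "0.1.0"


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, derived from the global seed."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


def _nested(cls, value):
    if isinstance(value, dict):
        return cls(**value)
    return value


@dataclass
class SyntheticConfig:
    n_batches: int = 3
    cells_per_type_per_batch: int = 50
    n_genes: int = 1200
    program_effect_size: float = 4.0
    batch_effect_sd: float = 1.0
    dropout_rate: float = 0.3
    library_size_range: tuple[float, float] = (1000.0, 5000.0)

    def __post_init__(self) -> None:
        self.library_size_range = tuple(self.library_size_range)


@dataclass
class ReferenceConfig:
    n_top: int = 512
    d: int = 20
    K: int | None = None
    theta: float = 2.0
    sigma: float = 0.1
    max_iter: int = 10
    tol: float = 1e-4
    ridge: float = 1e-3
    correct: bool = True


@dataclass
class BulkConfig:
    n_train: int = 8000
    n_val: int = 1000
    cells_per_sample: int = 500
    mode: str = "dense"


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 64
    patience: int = 20
    max_epochs: int = 500
    dropout_rate: float = 0.0


@dataclass
class PipelineConfig:
    """All tunables of the end-to-end run, with ledger defaults."""

    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    reference: ReferenceConfig = field(default_factory=ReferenceConfig)
    bulk: BulkConfig = field(default_factory=BulkConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        self.synthetic = _nested(SyntheticConfig, self.synthetic)
        self.reference = _nested(ReferenceConfig, self.reference)
        self.bulk = _nested(BulkConfig, self.bulk)
        self.train = _nested(TrainConfig, self.train)

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        def build(target, sub):
            allowed = {f.name for f in fields(target)}
            unknown = set(sub) - allowed
            if unknown:
                raise ValueError(f"unknown config keys for {target.__name__}: {sorted(unknown)}")
            return target(**sub)

        allowed = {f.name for f in fields(cls)}
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for name, target in [
            ("synthetic", SyntheticConfig),
            ("reference", ReferenceConfig),
            ("bulk", BulkConfig),
            ("train", TrainConfig),
        ]:
            if name in kwargs and isinstance(kwargs[name], dict):
                kwargs[name] = build(target, kwargs[name])
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class RunManifest:
    """Snapshot of a CLI run: config, seeds, input checksums, timestamps."""

    config: dict
    seed: int
    version: str = __version__
    inputs: dict = field(default_factory=dict)
    started: float = field(default_factory=time.time)
    finished: float | None = None

    def add_input(self, name: str, path) -> None:
        p = Path(path)
        h = hashlib.sha256()
        if p.is_dir():
            for f in sorted(p.rglob("*")):
                if f.is_file():
                    h.update(f.read_bytes())
        elif p.exists():
            h.update(p.read_bytes())
        self.inputs[name] = {"path": str(p), "sha256": h.hexdigest()}

    def write(self, path) -> None:
        self.finished = time.time()
        Path(path).write_text(json.dumps(asdict(self), indent=2))
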