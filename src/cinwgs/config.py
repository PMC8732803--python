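"""Run configuration: pipeline defaults with YAML round-trip."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import yaml

from .cin import CIN_CONVENTIONS


@dataclass(frozen=True)
class RunConfig:
    bin_size: int = 200_000
    cutoff: float = 4000.0
    tp53_threshold: float = -3.0
    alpha: float = 0.05
    n_permutations: int = 1000
    seed: int = 0
    include_sex_chromosomes: bool = False
    cin_convention: str = "abs_arm"
    min_read_pairs: int = 10_000_000

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.cin_convention not in CIN_CONVENTIONS:
            raise ValueError(
                f"cin_convention must be one of {CIN_CONVENTIONS}, "
                f"got {self.cin_convention!r}"
            )
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
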