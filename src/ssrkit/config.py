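"""Pipeline configuration with defaults matching the documented method."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # read filter / mining
    min_read_length: int = 80
    di_threshold: int = 11
    tri_threshold: int = 7
    tetra_threshold: int = 6
    min_tract: int = 21
    max_interruption: int = 100
    min_flank: int = 20
    strand_collapse: bool = False
    # primer design
    product_min: int = 100
    product_max: int = 250
    design_max_tm_diff: float = 1.0
    primer_len_min: int = 18
    primer_len_max: int = 24
    salt_mM: float = 50.0
    primer_nM: float = 200.0
    # virtual PCR / validation
    kmer: int = 9
    max_product: int = 2000
    ta_window: tuple[float, float] = (30.0, 80.0)
    min_ta: float = 50.0
    validation_max_tm_diff: float = 3.0
    # diversity / AMOVA / structure
    rarefaction_g: int | None = None
    n_permutations: int = 1000
    amova_metric: str = "shared_allele"
    nei_variant: str = "standard_1972"
    k_min: int = 2
    k_max: int = 20
    kmeans_restarts: int = 10
    pc_prefilter: float = 0.95
    # global
    seed: int = 0

    def thresholds(self) -> dict[int, int]:
        return {2: self.di_threshold, 3: self.tri_threshold, 4: self.tetra_threshold}

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        if "ta_window" in data:
            data["ta_window"] = tuple(data["ta_window"])
        return cls(**data)

    def digest(self) -> str:
        """Short config hash stamped into every output file."""
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]
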