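"""Run configuration: one YAML file plus command-line overrides.

All stages share a single master seed.  Per-purpose randomness is derived
from it on disjoint, documented streams (see ``stage_seed``), so each stage
is independently reproducible and running stages one by one equals running
them chained.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: Stage name -> stream constant mixed into the master seed.
STAGE_STREAMS = {
    "simulate": 1,
    "map": 2,
    "enrich": 3,
    "globalnull": 4,
    "network": 5,
    "summarize": 6,
}


@dataclass
class RunConfig:
    outdir: str = "pathassoc_out"
    seed: int = 0
    pvalue_threshold: float = 1e-5
    window: int = 20000
    mapping_mode: str = "coordinate"
    alpha: float = 0.05
    min_dp: int = 2
    min_genes: int = 2
    reps: int = 1000
    outer_reps: int = 200
    network_threshold: int = 1
    sample_size_agg: str = "sum"
    smoothed: bool = False
    per_pathway_null: bool = False
    fresh_inner: bool = False
    skip_bad_rows: bool = False
    split_placeholders: bool = True
    bed_one_based: bool = False
    columns: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # catalog/gmt/bed/categories/synonyms
    synthetic: dict = field(default_factory=dict)  # SyntheticSpec overrides

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.reps < 1 or self.outer_reps < 1:
            raise ValueError("reps and outer_reps must be >= 1")
        if self.window < 0:
            raise ValueError("window must be non-negative")
        if self.min_dp < 0 or self.min_genes < 0:
            raise ValueError("min_dp and min_genes must be non-negative")
        if self.network_threshold < 1:
            raise ValueError("network_threshold must be >= 1")
        if self.mapping_mode not in ("coordinate", "reported"):
            raise ValueError(f"unknown mapping mode {self.mapping_mode!r}")
        if self.seed < 0 or self.seed >= 2**31:
            raise ValueError("seed must fit in a non-negative 31-bit integer")

    @classmethod
    def load(cls, path=None, **overrides) -> "RunConfig":
        data: dict = {}
        if path is not None:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def stage_seed(self, stage: str) -> list[int]:
        """Entropy list for one stage's RNG: ``[master_seed, 7919, stream]``."""
        return [self.seed, 7919, STAGE_STREAMS[stage]]

    def out(self, name: str) -> Path:
        return Path(self.outdir) / name

    def input_path(self, kind: str, default_name: str) -> Path:
        """Path for an input: explicit entry under ``inputs`` wins, else the
        simulate stage's output of that kind in ``outdir``."""
        if kind in self.inputs:
            return Path(self.inputs[kind])
        return self.out(default_name)

    def params(self) -> dict:
        """Flat parameter mapping for provenance headers."""
        d = asdict(self)
        # paths are run bookkeeping, not parameters; identical analyses in
        # different directories must produce identical files
        d.pop("outdir", None)
        d.pop("inputs", None)
        d.pop("columns", None)
        d.pop("synthetic", None)
        return d
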