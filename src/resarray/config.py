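"""Pipeline configuration: one structured object covering every stage.

A run is fully determined by its config (including the global seed); the
pipeline writes the resolved config next to its outputs so any run can
be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .caller import CallParams
from .filters import FilterParams
from .simulate import SimParams


@dataclass(frozen=True)
class DesignConfig:
    reference_fasta: str | None = None   # generate a synthetic design when None
    regions_bed: str | None = None
    total_bases: int = 26292
    n_fragments: int = 180
    gc: float = 0.40
    probe_length: int = 25
    chrom: str = "synthetic_ref"


@dataclass(frozen=True)
class TruthConfig:
    n_common_sites: int = 30
    common_freq_min: float = 0.05
    common_freq_max: float = 0.5
    rare_rate: float = 1.5


@dataclass(frozen=True)
class SprofilerConfig:
    enabled: bool = True
    q: float = 0.05
    alpha: float = 1.0
    mode: str = "wildtype_only"
    min_run: int = 5


@dataclass(frozen=True)
class IndelScanConfig:
    min_len: int = 8
    window: int = 15
    drop_frac: float = 0.5


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    n_arrays: int = 24
    design: DesignConfig = field(default_factory=DesignConfig)
    truth: TruthConfig = field(default_factory=TruthConfig)
    sim: SimParams = field(default_factory=SimParams)
    caller: CallParams = field(default_factory=CallParams)
    sprofiler: SprofilerConfig = field(default_factory=SprofilerConfig)
    filters: FilterParams = field(default_factory=FilterParams)
    indel_scan: IndelScanConfig = field(default_factory=IndelScanConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw or {})
        sections = {
            "design": DesignConfig,
            "truth": TruthConfig,
            "sim": SimParams,
            "caller": CallParams,
            "sprofiler": SprofilerConfig,
            "filters": FilterParams,
            "indel_scan": IndelScanConfig,
        }
        kwargs: dict = {}
        for key, typ in sections.items():
            block = raw.pop(key, {}) or {}
            names = {f.name for f in dataclasses.fields(typ)}
            unknown = set(block) - names
            if unknown:
                raise ValueError(f"unknown keys in config section {key!r}: {sorted(unknown)}")
            kwargs[key] = typ(**block)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        kwargs.update(raw)
        return cls(**kwargs)

    def with_seed(self, seed: int) -> "PipelineConfig":
        return dataclasses.replace(
            self, seed=seed, sim=dataclasses.replace(self.sim, seed=seed)
        )
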