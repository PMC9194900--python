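"""Structured pipeline configuration (YAML on disk, dataclasses in memory)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class GenomeEntry:
    name: str
    gff3: str = ""
    cds: str = ""
    lineage: str = ""
    depth: int = 1  # expected colinear depth vs the reference

    def __post_init__(self):
        if not self.lineage:
            self.lineage = self.name


@dataclass
class HitsEntry:
    a: str
    b: str
    path: str


@dataclass
class StageParams:
    """Stage parameters with the conventional defaults.

    max_gap: maximum intervening genes between consecutive anchors.
    min_anchors: minimum anchor pairs per colinear block.
    evalue: homolog hit E-value cutoff (hits must be strictly below).
    window/step: sliding retention window size and step, in genes.
    delta_low/delta_high: P-index inclusion thresholds on d_i.
    bs_threshold: bootstrap percentage required at a gene tree's key node.
    p_index_threshold: allopolyploidy call threshold.
    """

    max_gap: int = 50
    min_anchors: int = 4
    evalue: float = 1e-5
    best_n: int = 10
    window: int = 100
    step: int = 1
    delta_low: float = 0.1
    delta_high: float = 3.0
    bs_threshold: int = 50
    p_index_threshold: float = 0.3


@dataclass
class CalibrationEntry:
    event: str = "gamma"
    ks_peak: float = 1.0
    age_lo: float = 115.0
    age_hi: float = 130.0


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "wgdkit_out"
    reference: str = ""
    genomes: list[GenomeEntry] = field(default_factory=list)
    hits: list[HitsEntry] = field(default_factory=list)
    params: StageParams = field(default_factory=StageParams)
    calibration: CalibrationEntry = field(default_factory=CalibrationEntry)
    scenario: dict = field(default_factory=dict)  # simulator scenario, optional

    def genome(self, name: str) -> GenomeEntry:
        for g in self.genomes:
            if g.name == name:
                return g
        raise KeyError(f"genome {name!r} not configured")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["genomes"] = [GenomeEntry(**g) for g in d.get("genomes", [])]
        d["hits"] = [HitsEntry(**h) for h in d.get("hits", [])]
        d["params"] = StageParams(**d.get("params", {}))
        d["calibration"] = CalibrationEntry(**d.get("calibration", {}))
        return cls(**d)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
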