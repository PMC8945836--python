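"""Plain-text (YAML) pipeline configuration with strict key checking."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # population / bulks
    n_f2: int = 400
    bulk_size: int = 25
    coverage_g: float = 39.82
    coverage_y: float = 33.75
    # genome / panel: long genetic map so flanks decouple from the causal
    # locus and the called region is bounded
    chrom: str = "A03"
    chrom_len: int = 30_000_000
    site_spacing: int = 20_000
    cm_per_mb: float = 10.0
    causal_bp: int = 15_000_000
    # phenotype model
    mu_wt: float = 30.0
    mu_het: float = 15.0
    mu_mut: float = 5.0
    sigma: float = 2.0
    # scan
    window_bp: int = 1_000_000
    step_bp: int = 10_000
    alpha: float = 0.05
    min_depth: int = 7
    n_null_reps: int = 10_000
    # fine mapping / triage
    n_markers: int = 13
    finemap_rounds: int = 2
    gene_span: int = 20_000
    # bookkeeping
    seed: int = 1
    outdir: str = "bulkmap_out"

    def __post_init__(self) -> None:
        if self.causal_bp > self.chrom_len or self.causal_bp < 1:
            raise ValueError("causal_bp outside the chromosome")
        if self.n_markers < 3:
            raise ValueError("need at least 3 markers for narrowing")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
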