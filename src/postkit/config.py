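"""Pipeline configuration: every numeric threshold used downstream.

Defaults follow the standard 454 EST post-assembly protocol: strict e-value
cutoffs per annotation source, the 95%-identity / 5-bp-edge / MAF>0.20 /
three-read SNP filters, the 97.5% random-probe quantile with the 3-of-6
replication rule, and the GS-FLX Titanium substitution-error rate.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from pathlib import Path


@dataclass
class PipelineConfig:
    # e-value cutoffs (strict '<' everywhere)
    annotation_evalue: float = 1e-5
    go_evalue: float = 1e-15
    ortho_evalue: float = 1e-10
    kegg_evalue: float = 1e-5
    completeness_evalue: float = 1e-5
    snp_evalue: float = 1e-5

    # SNP filters
    snp_min_identity: float = 95.0     # percent
    snp_edge_slack: int = 5            # bp of unaligned overhang allowed per read end
    snp_trim: int = 5                  # bp trimmed from each read end before pileup
    snp_min_maf: float = 0.20          # exclusive lower bound on minor-allele frequency
    snp_min_support: int = 3           # reads supporting the minor allele

    # expression calling
    expr_null_quantile: float = 0.975
    expr_min_individuals: int = 3
    expr_group_size: int = 6

    # probe design
    probes_per_contig: int = 3
    probe_length: int = 60             # bp

    # sequencing model
    seq_error_rate: float = 0.00022    # substitutions per base (GS-FLX Titanium)
    min_read_length_after_clean: int = 31  # reads shorter than this are dropped

    rng_seed: int = 0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if f.name == "rng_seed":
                continue
            v = getattr(self, f.name)
            if v <= 0 and f.name != "seq_error_rate":
                raise ValueError(f"{f.name} must be strictly positive, got {v!r}")
        if not (0 <= self.seq_error_rate <= 1):
            raise ValueError("seq_error_rate must lie in [0, 1]")
        if self.expr_min_individuals > self.expr_group_size:
            raise ValueError("expr_min_individuals must not exceed expr_group_size")
        if not (0 < self.snp_min_maf <= 0.5):
            raise ValueError("snp_min_maf must lie in (0, 0.5]")
        if not (0 < self.expr_null_quantile < 1):
            raise ValueError("expr_null_quantile must lie in (0, 1)")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
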