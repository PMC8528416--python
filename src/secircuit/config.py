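"""Pipeline configuration.

Defaults are the canonical parameters of the analysis: 50-bp bins, 200-bp
read extension, ROSE stitching -s 12500 -t 1000, promoter windows of
TSS +/- 500 bp with a top-two-thirds expression rule, a base-mean TPM > 10
expression filter, and the amplified-locus exclusion region around MYCN
(given 1-based inclusive, as in genome-browser coordinates).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .intervals import GenomicInterval, parse_region_string

__all__ = ["PipelineConfig", "load_config"]

MYCN_AMPLICON = "chr2:14817188-17228298"


@dataclass
class PipelineConfig:
    bin_width: int = 50
    read_extension_bp: int = 200
    stitch_distance_bp: int = 12500
    tss_exclusion_bp: int = 1000
    promoter_half_width_bp: int = 500
    peak_p_strict: float = 1e-9
    peak_p_lenient: float = 1e-4
    peak_min_len_bp: int = 100
    fold_threshold: float = 2.0
    differential_pseudocount: float = 1.0
    enrichment_min_fold: float = 3.0
    enrichment_floor: float = 0.5
    expression_pseudocount: float = 0.5
    tpm_filter: float = 10.0
    exclusion_regions: list[str] = field(default_factory=lambda: [MYCN_AMPLICON])
    candidate_tfs: list[str] = field(default_factory=list)
    seed: int = 0

    def exclusion_intervals(self) -> list[GenomicInterval]:
        return [parse_region_string(s) for s in self.exclusion_regions]

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def load_config(path=None, **overrides) -> PipelineConfig:
    """Config file with flag overrides; unknown keys are rejected."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    valid = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    return PipelineConfig(**data)
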