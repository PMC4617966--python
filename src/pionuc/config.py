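"""Run configuration: the analysis constants and synthetic-data overrides.

Defaults reproduce the pipeline's canonical constants (summit windows
100/125/250/400 bp, FDR 0.1, background Z cutoff 1.6445, bin size 500,
hotness cutoff 8, nucleosome anchoring distance 75 bp).  The config is
serialized verbatim into every output directory so runs are self-describing.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from pionuc.simulate import SyntheticConfig


@dataclass
class RunConfig:
    seed: int = 0
    excluded_chroms: tuple[str, ...] = ()

    # analysis constants
    fdr_cutoff: float = 0.1
    z_cutoff: float = 1.6445
    enrich_filter_window: int = 100  # ChIP-vs-input check around summits
    count_window: int = 125          # differential counting half-window
    delta_window: int = 250          # delta-MNase half-window
    motif_density_window: int = 250
    central_motif_window: int = 125
    flank_motif_window: int = 400
    tss_distance: int = 1000
    bin_size: int = 500
    hotness_cutoff: int = 8
    nucleosome_max_dist: int = 75
    peak_p_cutoff: float = 1e-5
    low_pass_fraction: float = 0.02
    nucleosome_min_score: float = 0.2

    # synthetic-data overrides (field name -> value)
    synthetic: dict = field(default_factory=dict)

    def synthetic_config(self) -> SyntheticConfig:
        cfg = SyntheticConfig(seed=self.derive_seed("simulate"))
        for key, value in self.synthetic.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown synthetic-config field {key!r}")
            if key == "chrom_lengths":
                value = {str(k): int(v) for k, v in value.items()}
            setattr(cfg, key, value)
        return cfg

    def derive_seed(self, stage: str) -> int:
        """Counter-free per-stage seed: stable, independent substreams."""
        return (self.seed * 0x9E3779B1 + zlib.crc32(stage.encode())) & 0x7FFFFFFF

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["excluded_chroms"] = list(self.excluded_chroms)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "excluded_chroms" in raw:
            raw = dict(raw, excluded_chroms=tuple(raw["excluded_chroms"]))
        return cls(**raw)


def write_manifest(path: Path, stage: str, config: RunConfig, **extra) -> None:
    from pionuc import __version__

    payload = {
        "stage": stage,
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        **extra,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
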