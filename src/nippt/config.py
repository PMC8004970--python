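"""Pipeline configuration: every calling threshold surfaces as a named key.

Defaults follow the MPS genotype-calling rules the pipeline implements:
nonplasma locus depth minima of 15x (SNP) and 10x (STR) with heterozygote
ratios 0.2 / 0.35; plasma minima of 50x (SNP), 30x (A-/X-STR) and 10x
(Y-STR); a 2% plasma SNP background-noise threshold; a 1% STR low-count
filter; and the stutter tests (mean + 3 SD at N-1/N+1, half the
corresponding parental count elsewhere).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml


@dataclass
class CallingConfig:
    # nonplasma calling
    snp_min_depth: int = 15
    str_min_depth: int = 10
    snp_het_ratio: float = 0.2
    str_het_ratio: float = 0.35
    # plasma SNP
    plasma_snp_min_depth: int = 50
    snp_noise_threshold: float = 0.02
    snp_noise_inclusive: bool = True  # ">= 2%" if True, "> 2%" if False
    # plasma STR
    plasma_str_min_depth: int = 30
    plasma_ystr_min_depth: int = 10
    str_low_count_fraction: float = 0.01  # sequences < 1% of locus depth excluded
    stutter_sd_multiplier: float = 3.0    # mean + 3*SD rule at N-1 / N+1
    other_position_factor: float = 0.5    # > half the corresponding parental count

    def to_yaml(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CallingConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


DEFAULT_CONFIG = CallingConfig()
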