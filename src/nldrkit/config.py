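"""Plain-text (YAML) run configuration.

One file collects everything a reproducible run needs: the source-column
alias map, the workload threshold, the complication-grade rank mapping,
and the validation settings (bootstrap replicates, seed, minimum per-class
resample count, the CV survivor band, covariance mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import COVARIANCE_MODES
from .registry import CLAVIEN_RANKS
from .validate import Boot632Config


@dataclass
class RunConfig:
    threshold_min: float = 210.0
    covariance_mode: str = "pooled"
    cv_band_pp: float = 1.6
    n_boot: int = 200
    seed: int = 0
    min_group: int = 2
    aliases: dict[str, str] = field(default_factory=dict)
    clavien_ranks: dict[str, int] = field(default_factory=lambda: dict(CLAVIEN_RANKS))

    def boot_config(self) -> Boot632Config:
        return Boot632Config(n_boot=self.n_boot, seed=self.seed,
                             min_group=self.min_group)

    def validate(self) -> None:
        if self.covariance_mode not in COVARIANCE_MODES:
            raise ValueError(f"covariance_mode must be one of {COVARIANCE_MODES}")
        if self.threshold_min <= 0:
            raise ValueError("threshold_min must be positive")
        if self.cv_band_pp < 0:
            raise ValueError("cv_band_pp must be >= 0")


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = RunConfig.__dataclass_fields__
    unknown = sorted(set(raw) - set(known))
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    data = {
        "threshold_min": cfg.threshold_min,
        "covariance_mode": cfg.covariance_mode,
        "cv_band_pp": cfg.cv_band_pp,
        "n_boot": cfg.n_boot,
        "seed": cfg.seed,
        "min_group": cfg.min_group,
        "aliases": cfg.aliases,
        "clavien_ranks": cfg.clavien_ranks,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
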