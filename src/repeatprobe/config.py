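"""Validated pipeline configuration and named parameter presets.

Every tunable of the pipeline lives here under its conventional name.  A
configuration file is a flat YAML mapping of these names to values; unknown
keys are rejected.  Two presets are shipped: ``conservative`` (prioritizes
large, extremely robust targets: aggregate on-target >= 500 sites) and
``permissive`` (exhaustive discovery of targets probeable with >= 25
sites).  Their exact values are repository defaults chosen to satisfy those
intents.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    # repeat discovery
    window: int = 3000
    threshold: float = 10.0
    composition: float = 0.5
    file_start: int = 0
    # k-mer engine
    k: int = 18
    # probe mining
    min_length: int = 25
    max_length: int = 50
    min_temp: float = 42.0
    max_temp: float = 52.0
    min_gc: float = 20.0
    max_gc: float = 80.0
    # ranking
    c1_val: float = 1.0
    c2_val: float = 1.0
    mer_cutoff: float = 0.8
    # alignment
    seed_length: int = 15
    max_alignments: int = 500_000
    # specificity / selection
    genome_windows: int = 1_000_000
    thresh_windows: int = 1_000_000
    align_thresh: float = 1.0
    off_bin_thresh: float = 10.0
    binding_prop: float = 0.8
    max_pdups_binding: float = 0.8
    target_sum: float = 25.0
    min_on_target: float = 5.0
    max_probe_return: int = 25
    # thermodynamic model
    temperature: float = 69.5
    sodium: float = 0.39
    magnesium: float = 0.0
    formamide: float = 50.0
    # fixture generation
    seed: int = 0

    def __post_init__(self):
        checks = [
            (self.window >= 1, "window must be >= 1"),
            (0.0 <= self.composition <= 1.0, "composition must lie in [0, 1]"),
            (self.file_start >= 0, "file_start must be >= 0"),
            (self.k >= 1, "k must be >= 1"),
            (1 <= self.min_length <= self.max_length,
             "need 1 <= min_length <= max_length"),
            (self.min_temp <= self.max_temp, "need min_temp <= max_temp"),
            (0 <= self.min_gc <= self.max_gc <= 100,
             "need 0 <= min_gc <= max_gc <= 100"),
            (self.c1_val > 0 and self.c2_val > 0, "c1_val/c2_val must be > 0"),
            (0.0 <= self.mer_cutoff <= 1.0, "mer_cutoff must lie in [0, 1]"),
            (self.seed_length >= 1, "seed_length must be >= 1"),
            (self.max_alignments >= 1, "max_alignments must be >= 1"),
            (self.genome_windows >= 1, "genome_windows must be >= 1"),
            (self.thresh_windows >= 1, "thresh_windows must be >= 1"),
            (self.off_bin_thresh >= 0, "off_bin_thresh must be >= 0"),
            (0.0 <= self.binding_prop <= 1.0, "binding_prop must lie in [0, 1]"),
            (0.0 <= self.max_pdups_binding <= 1.0,
             "max_pdups_binding must lie in [0, 1]"),
            (self.target_sum >= 0, "target_sum must be >= 0"),
            (self.min_on_target >= 0, "min_on_target must be >= 0"),
            (self.max_probe_return >= 1, "max_probe_return must be >= 1"),
            (self.sodium >= 0 and self.magnesium >= 0,
             "salt concentrations must be >= 0"),
        ]
        for ok, message in checks:
            if not ok:
                raise ConfigError(message)

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


PRESETS: dict[str, dict] = {
    # large, highly repetitive targets; extremely robust probe sets
    "conservative": dict(
        threshold=10.0, composition=0.5,
        target_sum=500.0, min_on_target=50.0, max_probe_return=10,
        binding_prop=0.9, off_bin_thresh=2.0, max_pdups_binding=0.5,
    ),
    # exhaustive discovery of smaller targets (>= 25 predicted sites)
    "permissive": dict(
        threshold=5.0, composition=0.5,
        target_sum=25.0, min_on_target=5.0, max_probe_return=25,
        binding_prop=0.8, off_bin_thresh=10.0, max_pdups_binding=0.8,
    ),
}

_FIELDS = {f.name for f in dataclasses.fields(PipelineConfig)}


def load_config(
    path: str | Path | None = None,
    preset: str | None = None,
    **overrides,
) -> PipelineConfig:
    """Build a config from an optional preset, YAML file, and overrides.

    Precedence, lowest to highest: defaults < preset < file < overrides.
    """
    values: dict = {}
    if preset is not None:
        if preset not in PRESETS:
            raise ConfigError(
                f"unknown preset {preset!r}; choose from {sorted(PRESETS)}"
            )
        values.update(PRESETS[preset])
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must be a flat mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(values) - _FIELDS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**values)
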