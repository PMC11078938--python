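"""Run configuration: every pipeline parameter in one serialisable object.

Defaults are the published analysis constants: nucleus area 1200-12000 px
with circularity >= 0.8 and automatic brightness threshold; spot area
30-500 px with a 0.2 peak threshold; 50 x 50 grid smoothed by a 5 x 5
moving average three times; silhouette panels of 25/50/100 features with
100 repetitions on PCs 2-20; 28-mer primary probes with 45-65 % GC,
>= 24 per gene and word-size-10 complementarity screening; 15-mer readout
probes with 40-60 % GC and A/T at the 5' end.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .detect import NucleusParams, SpotParams
from .synth import SynthConfig

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    seed: int = 0
    max_shift: int = 20
    similarity_floor: float = 0.2
    cytosol_expand: tuple[float, float] = (25.0, 15.0)
    nucleus: NucleusParams = field(default_factory=NucleusParams)
    spots: SpotParams = field(default_factory=SpotParams)
    grid_n: int = 50
    grid_kernel: int = 5
    grid_passes: int = 3
    silhouette_sizes: tuple[int, ...] = (25, 50, 100)
    silhouette_reps: int = 100
    silhouette_pc_range: tuple[int, int] = (2, 20)
    probe_word_size: int = 10
    n_readouts: int = 48
    synth: SynthConfig = field(default_factory=SynthConfig)

    def with_seed(self, seed: int) -> "RunConfig":
        cfg = dataclasses.replace(self, seed=seed)
        cfg.synth = dataclasses.replace(self.synth, seed=seed)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _tupled(mapping: dict, keys: tuple[str, ...]) -> dict:
    out = dict(mapping)
    for k in keys:
        if k in out and isinstance(out[k], list):
            out[k] = tuple(out[k])
    return out


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a YAML file; absent keys keep their defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = _tupled(raw, ("cytosol_expand", "silhouette_sizes", "silhouette_pc_range"))
    if "nucleus" in kwargs:
        kwargs["nucleus"] = NucleusParams(**kwargs["nucleus"])
    if "spots" in kwargs:
        kwargs["spots"] = SpotParams(**kwargs["spots"])
    if "synth" in kwargs:
        synth = _tupled(kwargs["synth"],
                        ("nucleus_axis_range", "intensity_range",
                         "reference_intensity_range"))
        kwargs["synth"] = SynthConfig(**synth)
    return RunConfig(**kwargs)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
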