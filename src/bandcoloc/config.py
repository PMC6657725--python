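"""Run configuration: plain-text (YAML) key-value files checked strictly.

Unknown keys are errors — a silently ignored typo in an analysis parameter
would corrupt results. Defaults are the published analysis parameters:
0.6 μm minimum band distance, 20% background threshold, 0.6 μm matching
tolerance, 100,000 permutations, 4,000 bp coverage windows.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """The configuration file is invalid."""


@dataclass
class RunConfig:
    # stage parameters (defaults = the published analysis values)
    min_distance_um: float = 0.6
    threshold_frac: float = 0.20
    tolerance_um: float = 0.6
    n_permutations: int = 100_000
    window_bp: int = 4000
    pseudocount: float = 1.0
    seed: int = 0
    # data layout
    profiles_dir: str | None = None
    bands_path: str | None = None
    peaks_a: str | None = None
    peaks_b: str | None = None
    tracks: dict | None = None          # label -> bedGraph path
    output_dir: str = "bandcoloc_out"
    control: str | None = None
    conditions: list | None = None

    def validate(self) -> None:
        if self.min_distance_um <= 0:
            raise ConfigError("min_distance_um must be positive")
        if not 0 <= self.threshold_frac < 1:
            raise ConfigError("threshold_frac must lie in [0, 1)")
        if self.tolerance_um <= 0:
            raise ConfigError("tolerance_um must be positive")
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if self.window_bp <= 0 or self.window_bp % 2:
            raise ConfigError("window_bp must be even and positive")
        if self.pseudocount <= 0:
            raise ConfigError("pseudocount must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(
            f"{path}: unknown configuration keys {sorted(unknown)}; "
            f"known keys are {sorted(known)}"
        )
    config = RunConfig(**raw)
    config.validate()
    return config
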