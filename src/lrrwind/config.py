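"""Run configuration shared by the pipeline and the CLI.

All defaults equal the method's published operating point: backbone
smoothing σ = 20 residues, secant lengths 100-250, loss weights C = 1 and
D = 1.5, coil-RMS refit threshold 1.0, sliding window 24, 50 mutual
nearest neighbors.  Config files are flat TOML key-value tables; CLI
flags override file values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class RunConfig:
    # geometry
    sigma: float = 20.0
    kernel_truncation_sigmas: float = 4.0
    # segmentation
    d_min: int = 100
    d_max: int = 250
    c_weight: float = 1.0
    d_weight: float = 1.5
    rms_threshold: float = 1.0
    epsilon: float = 2.0
    max_iter: int = 2000
    # laplacian phase / anomalies
    window: int = 24
    knn: int = 50
    phase_sigma: float = 1.0
    swl2d_window: int = 24
    anomaly_mad_factor: float = 3.0
    # repeat validation
    flag_threshold: float = 0.5
    # misc
    seed: int = 0
    chain: str | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def replace(self, **overrides) -> "RunConfig":
        overrides = {k: v for k, v in overrides.items() if v is not None}
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
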