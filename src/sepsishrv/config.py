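"""Flat pipeline configuration with YAML round-trip.

Every default equals the study-protocol value where one exists: 10 Hz
tachogram, 180 s segments with 50 % overlap, VLF/LF/HF band edges
0.2/0.75/3 Hz, 1 kHz ECG, peak-velocity cutoff 0.93 m/s, aortic diameter
2.6 mm, alpha 0.05, 8 sham / 19 sepsis animals with 8 deaths in 24 h.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "save_config", "config_hash"]


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "results/pipeline"

    # simulation
    duration_s: float = 360.0
    simulate_ecg: bool = True
    ecg_noise_sd: float = 0.05  # mV
    ecg_sampling_rate: float = 1000.0

    # detection / tachogram
    tachogram_fs: float = 10.0
    ectopic_threshold: float = 0.3
    detrend_method: str = "smoothness_priors"
    detrend_strength: float = 500.0

    # spectral
    ar_order: int = 16
    ar_method: str = "burg"
    segment_length_s: float = 180.0
    segment_overlap: float = 0.5
    band_edges: list = field(default_factory=lambda: [0.0, 0.2, 0.75, 3.0])

    # hemodynamics
    pv_cutoff: float = 0.93
    aortic_diameter_mm: float = 2.6

    # statistics
    alpha: float = 0.05
    gate: str = "ks"

    # survival
    n_sham: int = 8
    n_sepsis: int = 19
    sepsis_mortality: float = 8.0 / 19.0
    horizon_h: float = 24.0
    deterministic_deaths: bool = True

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if not 0 <= self.segment_overlap < 1:
            raise ValueError("segment_overlap must be in [0, 1)")
        if len(self.band_edges) != 4 or sorted(self.band_edges) != list(
            self.band_edges
        ):
            raise ValueError("band_edges must be 4 ascending values")
        if self.gate not in ("ks", "always-parametric", "always-nonparametric"):
            raise ValueError(f"unknown gate {self.gate!r}")

    def stage_seed(self, stage: int) -> int:
        """Deterministic per-stage substream seed derived from the run seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def config_hash(cfg: PipelineConfig) -> str:
    payload = yaml.safe_dump(asdict(cfg), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig(**data)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
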