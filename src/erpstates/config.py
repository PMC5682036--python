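"""Pipeline configuration: every numeric default in one place, YAML/JSON-loadable."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # preprocessing
    band_low: float = 0.25  # Hz
    band_high: float = 30.0  # Hz
    filter_order: int = 2  # poles per skirt (−12 dB/octave)
    resample: float = 250.0  # Hz
    artifact_threshold: float = 100.0  # µV
    baseline: tuple[float, float] = (-200.0, 0.0)  # ms
    spline_m: int = 4
    spline_terms: int = 50
    spline_ridge: float = 1e-5
    # waveform statistics
    electrodes: tuple[str, ...] = ("E1", "E2")
    alpha: float = 0.05
    family_size: int = 3
    min_ms: float = 28.0
    # microstates
    k_min: int = 2
    k_max: int = 12
    n_restarts: int = 100
    polarity: str = "sensitive"
    min_frames: int = 7
    fit_window: tuple[float, float] = (295.0, 480.0)  # ms
    segment_window: tuple[float, float] = (0.0, 750.0)  # ms
    # head model / source space
    shell_ratios: tuple[float, float, float] = (0.87, 0.92, 1.0)
    conductivities: tuple[float, float, float] = (0.33, 0.0042, 0.33)  # S/m
    grid_spacing: float = 6.0  # mm
    grid_shell: tuple[float, float] = (0.45, 0.95)
    target_nodes: int = 3005
    leadfield_terms: int = 60
    lambda_rel: float = 0.05
    depth_exponent: float = 1.0
    # source statistics
    node_alpha: float = 0.005
    min_nodes: int = 10
    connection_radius: float = 10.0  # mm
    mc_iterations: int = 10_000
    fwhm: float = 7.0  # mm
    # behavior
    n_behavior_trials: int = 90

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {
            k: tuple(v) if isinstance(v, list) else v for k, v in payload.items()
        }
        return cls(**kwargs)

    def dump(self, path: str | Path) -> None:
        payload = {
            k: list(v) if isinstance(v, tuple) else v for k, v in asdict(self).items()
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
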