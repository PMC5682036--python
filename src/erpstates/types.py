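"""Shared domain containers for the ERP analysis pipeline.

Conventions used throughout the package:

* voltages are microvolts (µV), positions are millimetres (mm);
* the time axis is sample-based with its origin at stimulus onset:
  ``t_ms(i) = (i - t0_index) * 1000 / sfreq``;
* windows given in milliseconds are half-open ``[start, end)`` and a sample
  belongs to a window iff its time stamp falls inside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an on-disk artifact violates its documented format."""


def window_samples(
    n_samples: int, sfreq: float, t0_index: int, start_ms: float, end_ms: float
) -> np.ndarray:
    """Indices of samples whose time stamp lies in the half-open window [start, end) ms."""
    t_ms = (np.arange(n_samples) - t0_index) * 1000.0 / sfreq
    return np.nonzero((t_ms >= start_ms) & (t_ms < end_ms))[0]


@dataclass
class ElectrodeMontage:
    """Electrode labels and 3D positions (head frame, mm).

    ``fitted_sphere`` is ``None`` until :func:`erpstates.forward.fit_sphere`
    has projected the montage onto its best-fitting sphere.
    """

    labels: list[str]
    positions: np.ndarray  # (n_channels, 3), mm
    fitted_sphere: tuple[np.ndarray, float] | None = None  # (center mm, radius mm)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.labels) != len(set(self.labels)):
            raise FormatError("montage labels must be unique")
        if self.positions.shape != (len(self.labels), 3):
            raise FormatError("positions must be (n_channels, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise FormatError("montage positions must be finite")
        if len(self.labels) < 16:
            raise FormatError("montage needs at least 16 channels")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None


@dataclass
class EpochSet:
    """Single-subject, single-condition epoched EEG (trials × channels × samples, µV)."""

    subject_id: str
    group: str
    condition: str
    sfreq: float
    data: np.ndarray
    t0_index: int
    kept_mask: np.ndarray | None = None
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials × channels × samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data must be finite")
        if not 0 <= self.t0_index < self.data.shape[2]:
            raise ValueError("t0_index outside the sample range")
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.data.shape[0], dtype=bool)
        else:
            self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
            if self.kept_mask.shape != (self.data.shape[0],):
                raise ValueError("kept_mask must have one entry per trial")
        if self.labels is not None and len(self.labels) != self.data.shape[1]:
            raise ValueError("labels must match the channel dimension")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample time stamps in ms relative to stimulus onset."""
        return (np.arange(self.n_samples) - self.t0_index) * 1000.0 / self.sfreq


@dataclass
class Evoked:
    """Per-subject, per-condition averaged ERP (channels × samples, µV)."""

    data: np.ndarray
    sfreq: float
    t0_index: int
    n_epochs: int = 1
    baseline_window: tuple[float, float] | None = None  # ms
    average_referenced: bool = False
    baseline_corrected: bool = False
    labels: list[str] | None = None
    subject_id: str = ""
    group: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("evoked data must be channels × samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return (np.arange(self.n_samples) - self.t0_index) * 1000.0 / self.sfreq

    def window(self, start_ms: float, end_ms: float) -> np.ndarray:
        """Sample indices inside the half-open [start, end) ms window."""
        return window_samples(self.n_samples, self.sfreq, self.t0_index, start_ms, end_ms)

    def channel(self, label: str) -> np.ndarray:
        if self.labels is None:
            raise ValueError("evoked carries no channel labels")
        return self.data[self.labels.index(label)]


@dataclass
class StudyDesign:
    """Mixed factorial design: between-subject expertise × within-subject condition."""

    groups: list[str]
    conditions: list[str]
    n_per_group: dict[str, int]

    def __post_init__(self) -> None:
        if len(self.groups) < 2 or len(self.conditions) < 2:
            raise ValueError("need at least 2 levels per factor")
        if set(self.n_per_group) != set(self.groups):
            raise ValueError("n_per_group must cover exactly the group levels")

    @property
    def n_subjects(self) -> int:
        return sum(self.n_per_group.values())

    def subject_ids(self) -> list[tuple[str, str]]:
        """(subject_id, group) pairs; every subject sees every condition."""
        out = []
        for g in self.groups:
            for i in range(self.n_per_group[g]):
                out.append((f"{g}-{i + 1:02d}", g))
        return out


STAT_COLUMNS = ["effect", "statistic", "value", "df1", "df2", "p", "effect_size", "correction"]


class StatTable:
    """Long-format table of test statistics (one record per effect/contrast)."""

    def __init__(self, records: Sequence[dict] | None = None):
        self.records: list[dict] = []
        self.note: str = ""  # e.g. gatekeeping explanations for empty tables
        for rec in records or []:
            self.add(**rec)

    def add(
        self,
        effect: str,
        statistic: str,
        value: float,
        df1: float,
        p: float,
        df2: float = np.nan,
        effect_size: float = np.nan,
        correction: str = "none",
    ) -> None:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p} outside [0, 1]")
        if df1 <= 0:
            raise ValueError("degrees of freedom must be positive")
        self.records.append(
            {
                "effect": effect,
                "statistic": statistic,
                "value": float(value),
                "df1": float(df1),
                "df2": float(df2),
                "p": float(p),
                "effect_size": float(effect_size),
                "correction": correction,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=STAT_COLUMNS)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __repr__(self) -> str:
        return f"StatTable({len(self.records)} records)"
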