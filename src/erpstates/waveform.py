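"""Pointwise waveform statistics: between-group t-tests over time at selected
electrodes, Bonferroni-corrected, with a minimum-run-length criterion.

A sample counts as significant when the pooled-variance independent-samples t
beats alpha divided by the family size (default 3: the pairwise group
contrasts); only maximal runs of at least ``min_frames`` consecutive
significant samples are reported.  28 ms at 250 Hz is 7 frames, the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import Evoked

logger = logging.getLogger("erpstates")


@dataclass
class SignificantRun:
    electrode: str
    contrast: str
    condition: str
    start_ms: float
    end_ms: float  # half-open on the sample grid
    mean_t: float

    @property
    def length_ms(self) -> float:
        return self.end_ms - self.start_ms


def pointwise_runs(
    evokeds_a: list[Evoked],
    evokeds_b: list[Evoked],
    electrode: str,
    alpha: float = 0.05,
    n_family: int = 3,
    min_frames: int = 7,
    contrast: str = "",
    condition: str = "",
) -> list[SignificantRun]:
    """Runs of consecutive samples where two groups differ at one electrode.

    Two-sided pooled-variance t at every sample; a sample is significant iff
    p < alpha / n_family; runs shorter than ``min_frames`` are suppressed.
    """
    if len(evokeds_a) < 2 or len(evokeds_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    xa = np.stack([ev.channel(electrode) for ev in evokeds_a])
    xb = np.stack([ev.channel(electrode) for ev in evokeds_b])
    ref = evokeds_a[0]
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t_vals, p_vals = stats.ttest_ind(xa, xb, axis=0, equal_var=True)
    degenerate = (xa.var(axis=0, ddof=1) + xb.var(axis=0, ddof=1)) == 0
    bad = degenerate | ~np.isfinite(p_vals)
    if np.any(bad):
        logger.warning(
            "%s: %d samples with degenerate variance marked non-significant",
            electrode,
            int(bad.sum()),
        )
        p_vals = np.where(bad, 1.0, p_vals)
        t_vals = np.where(bad, 0.0, t_vals)
    sig = p_vals < alpha / n_family

    runs: list[SignificantRun] = []
    times = ref.times
    frame_ms = 1000.0 / ref.sfreq
    start = None
    for i in range(len(sig) + 1):
        if i < len(sig) and sig[i]:
            if start is None:
                start = i
        elif start is not None:
            if i - start >= min_frames:
                runs.append(
                    SignificantRun(
                        electrode=electrode,
                        contrast=contrast,
                        condition=condition,
                        start_ms=float(times[start]),
                        end_ms=float(times[i - 1] + frame_ms),
                        mean_t=float(t_vals[start:i].mean()),
                    )
                )
            start = None
    return runs


def min_frames_for(min_ms: float, sfreq: float) -> int:
    """Number of frames spanned by a minimum duration (28 ms at 250 Hz → 7)."""
    return int(round(min_ms * sfreq / 1000.0))
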