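"""ERP preprocessing chain.

Fixed stage order: average reference → band-pass filter → downsample →
spherical-spline interpolation of bad channels → threshold artifact rejection
→ averaging with pre-stimulus baseline correction.  All stages operate on µV
arrays whose channel axis is the second-to-last.

Filtering is zero-phase (forward–backward), so the effective magnitude
response is the square of the single-pass Butterworth response; ERP latency
measures require the zero-phase property.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .types import ElectrodeMontage, EpochSet, Evoked, window_samples


@dataclass
class PreprocessConfig:
    band: tuple[float, float] = (0.25, 30.0)  # Hz
    order: int = 2  # poles per skirt → −6·order dB/octave asymptotic roll-off
    resample: float = 250.0  # Hz
    threshold: float = 100.0  # µV, strict inequality
    baseline: tuple[float, float] = (-200.0, 0.0)  # ms, half-open
    spline_m: int = 4
    spline_terms: int = 50
    spline_ridge: float = 1e-5

    def __post_init__(self) -> None:
        low, high = self.band
        if not 0 < low < high:
            raise ValueError("band must satisfy 0 < low < high")
        if high >= self.resample / 2:
            raise ValueError("band upper edge must lie below the target Nyquist")
        if self.threshold <= 0:
            raise ValueError("artifact threshold must be positive")


def average_reference(data: np.ndarray) -> np.ndarray:
    """Re-reference to the instantaneous channel mean (channel axis = -2)."""
    data = np.asarray(data, float)
    if data.shape[-2] < 2:
        raise ValueError("average reference needs at least 2 channels")
    return data - data.mean(axis=-2, keepdims=True)


def bandpass_sos(low: float, high: float, order: int, sfreq: float) -> np.ndarray:
    """Second-order sections of the single-pass Butterworth band-pass."""
    if not 0 < low < high < sfreq / 2:
        raise ValueError("band edges must lie inside (0, Nyquist)")
    return signal.butter(order, [low, high], btype="bandpass", fs=sfreq, output="sos")


def bandpass_response(
    low: float, high: float, order: int, sfreq: float, freqs: np.ndarray,
    analog: bool = True,
) -> np.ndarray:
    """Complex single-pass frequency response at ``freqs`` (Hz).

    By default the analog Butterworth design response is returned — the
    asymptotic −6·order dB/octave roll-off is a property of the design, while
    the digital (bilinear) realisation warps frequencies near Nyquist.  Pass
    ``analog=False`` for the realised digital response.
    """
    freqs = np.asarray(freqs, float)
    if analog:
        b, a = signal.butter(
            order, [2 * np.pi * low, 2 * np.pi * high], btype="bandpass", analog=True
        )
        _, h = signal.freqs(b, a, worN=2 * np.pi * freqs)
        return h
    sos = bandpass_sos(low, high, order, sfreq)
    _, h = signal.sosfreqz(sos, worN=freqs, fs=sfreq)
    return h


def bandpass(
    data: np.ndarray, sfreq: float, low: float = 0.25, high: float = 30.0, order: int = 2
) -> np.ndarray:
    """Zero-phase (forward–backward) Butterworth band-pass along the last axis."""
    sos = bandpass_sos(low, high, order, sfreq)
    return signal.sosfiltfilt(sos, np.asarray(data, float), axis=-1)


def downsample(
    data: np.ndarray, sfreq_in: float, sfreq_out: float, t0_index: int = 0
) -> tuple[np.ndarray, int]:
    """Decimate by keeping every (sfreq_in/sfreq_out)-th sample from the first.

    No extra anti-alias filter is applied: the band-pass preceding this stage
    already removes content above the target Nyquist.  Returns the decimated
    array and the rescaled stimulus-onset index.
    """
    ratio = sfreq_in / sfreq_out
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValueError(f"sfreq_in/sfreq_out = {ratio} is not a positive integer")
    if t0_index % factor:
        raise ValueError("stimulus onset does not fall on the decimated grid")
    return np.asarray(data, float)[..., ::factor], t0_index // factor


# ---------------------------------------------------------------------------
# spherical-spline interpolation (Perrin-style)

def _legendre_g(x: np.ndarray, m: int, n_terms: int) -> np.ndarray:
    """g(x) = (1/4π) Σ_{n=1}^{N} (2n+1) / (n(n+1))^m · P_n(x)."""
    x = np.asarray(x, float)
    out = np.zeros_like(x)
    p_prev = np.ones_like(x)  # P_0
    p = x.copy()  # P_1
    for n in range(1, n_terms + 1):
        out += (2 * n + 1) / float(n * (n + 1)) ** m * p
        p_next = ((2 * n + 1) * x * p - n * p_prev) / (n + 1)
        p_prev, p = p, p_next
    return out / (4 * np.pi)


def interpolate_bad_channels(
    data: np.ndarray,
    montage: ElectrodeMontage,
    bad_labels: list[str],
    m: int = 4,
    n_terms: int = 50,
    ridge: float = 1e-5,
) -> np.ndarray:
    """Replace bad channels by the spherical-spline prediction from good ones.

    The montage must be sphere-fitted; interpolation uses the unit directions
    of the projected electrodes.  A small ridge stabilises the spline system.
    """
    if not bad_labels:
        return np.asarray(data, float).copy()
    bads = [montage.index(lab) for lab in bad_labels]
    if len(bads) * 2 > montage.n_channels:
        raise ValueError("refusing to interpolate more than 50% of channels")
    if montage.fitted_sphere is None:
        from .forward import fit_sphere  # lazy: avoids a hard module cycle

        fit_sphere(montage)
    center, radius = montage.fitted_sphere
    unit = (montage.positions - center)
    unit /= np.linalg.norm(unit, axis=1, keepdims=True)

    good = np.setdiff1d(np.arange(montage.n_channels), bads)
    cos_gg = np.clip(unit[good] @ unit[good].T, -1.0, 1.0)
    cos_bg = np.clip(unit[bads] @ unit[good].T, -1.0, 1.0)
    g_gg = _legendre_g(cos_gg, m, n_terms) + ridge * np.eye(len(good))
    g_bg = _legendre_g(cos_bg, m, n_terms)

    n_good = len(good)
    system = np.zeros((n_good + 1, n_good + 1))
    system[:n_good, :n_good] = g_gg
    system[:n_good, n_good] = 1.0
    system[n_good, :n_good] = 1.0

    data = np.asarray(data, float)
    flat = data.reshape(-1, data.shape[-2], data.shape[-1]) if data.ndim == 3 else data[None]
    out = flat.copy()
    for ep in range(flat.shape[0]):
        rhs = np.zeros((n_good + 1, flat.shape[-1]))
        rhs[:n_good] = flat[ep][good]
        sol = np.linalg.solve(system, rhs)
        out[ep][bads] = g_bg @ sol[:n_good] + sol[n_good]
    return out.reshape(data.shape)


def reject_artifacts(epochs: EpochSet, threshold: float = 100.0) -> np.ndarray:
    """Boolean keep-mask: an epoch is rejected iff any |sample| exceeds threshold µV."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    peak = np.abs(epochs.data).max(axis=(1, 2))
    return peak <= threshold


def make_evoked(epochs: EpochSet, baseline: tuple[float, float] = (-200.0, 0.0)) -> Evoked:
    """Average the kept epochs and subtract the per-channel pre-stimulus mean."""
    kept = epochs.data[epochs.kept_mask]
    if kept.shape[0] == 0:
        raise ValueError("no kept epochs to average")
    mean = kept.mean(axis=0)
    sel = window_samples(epochs.n_samples, epochs.sfreq, epochs.t0_index, *baseline)
    if sel.size:
        mean = mean - mean[:, sel].mean(axis=1, keepdims=True)
    return Evoked(
        data=mean,
        sfreq=epochs.sfreq,
        t0_index=epochs.t0_index,
        n_epochs=int(kept.shape[0]),
        baseline_window=baseline,
        baseline_corrected=bool(sel.size),
        labels=epochs.labels,
        subject_id=epochs.subject_id,
        group=epochs.group,
        condition=epochs.condition,
    )


def preprocess_epochs(
    epochs: EpochSet,
    montage: ElectrodeMontage | None = None,
    config: PreprocessConfig | None = None,
    bad_labels: list[str] | None = None,
) -> EpochSet:
    """Run reference → filter → downsample → interpolate → reject on one recording."""
    cfg = config or PreprocessConfig()
    data = average_reference(epochs.data)
    data = bandpass(data, epochs.sfreq, *cfg.band, order=cfg.order)
    t0 = epochs.t0_index
    sfreq = epochs.sfreq
    if cfg.resample and cfg.resample != epochs.sfreq:
        data, t0 = downsample(data, epochs.sfreq, cfg.resample, t0)
        sfreq = cfg.resample
    if bad_labels:
        if montage is None:
            raise ValueError("bad-channel interpolation needs the montage")
        data = interpolate_bad_channels(
            data, montage, bad_labels, m=cfg.spline_m, n_terms=cfg.spline_terms, ridge=cfg.spline_ridge
        )
    out = EpochSet(
        subject_id=epochs.subject_id,
        group=epochs.group,
        condition=epochs.condition,
        sfreq=sfreq,
        data=data,
        t0_index=t0,
        labels=epochs.labels,
    )
    out.kept_mask = reject_artifacts(out, cfg.threshold)
    n_rej = int((~out.kept_mask).sum())
    logger_msg = (
        f"{epochs.subject_id}/{epochs.condition}: kept {int(out.kept_mask.sum())}"
        f"/{out.n_trials} epochs ({n_rej} rejected at {cfg.threshold} µV)"
    )
    import logging

    logging.getLogger("erpstates").info(logger_msg)
    return out
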