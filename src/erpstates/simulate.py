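"""Synthetic study generator with known ground truth.

Emulates the study conditions of the expertise × music-syntax design: three
groups (19/20/20 subjects), three closure conditions (regular, subtle and
apparent transgression), ≤90 trials per condition, ~200-channel montage,
epochs −200…750 ms.  Each cell's ERP is a piecewise sequence of template
topographies (microstates) modulated by a smooth amplitude envelope; the
microstate durations inside the 295–480 ms analysis window differ by group
and condition with the qualitative pattern of the study (one "naïve" map
longest in non-musicians, the "expert" maps longest in experts).  Templates
are forward-projected dipole pairs, so the source arm has ground truth too.
Behavioral YES/NO responses follow an equal-variance signal-detection model
with cell-specific sensitivity.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .forward import HeadModel, SourceGrid, dipole_potentials
from .preprocess import average_reference
from .types import ElectrodeMontage, EpochSet, Evoked, StudyDesign

EPOCH_MS = (-200.0, 750.0)
ANALYSIS_WINDOW = (295.0, 480.0)

GROUPS = ["Nonmusician", "Amateur", "Expert"]
CONDITIONS = ["R", "Tsub", "Tapp"]

# per-group frame budget (4 ms frames at 250 Hz) for the four window
# microstates; the "naïve" map (index 3) dominates non-musicians, the
# "expert" maps (4 and 6) dominate experts, map 5 is shared moderate time.
_WINDOW_FRAMES = {
    "Nonmusician": [26, 4, 10, 6],
    "Amateur": [14, 10, 10, 12],
    "Expert": [6, 16, 10, 14],
}
# transgressions shift frames from the naïve to the first expert map
_CONDITION_SHIFT = {"R": 0, "Tsub": 1, "Tapp": 2}

# cell-mean sensitivity (d′); expert values sit near ceiling
DEFAULT_DPRIME = {
    ("Nonmusician", "Tsub"): 0.49,
    ("Nonmusician", "Tapp"): 1.60,
    ("Amateur", "Tsub"): 1.54,
    ("Amateur", "Tapp"): 3.68,
    ("Expert", "Tsub"): 3.80,
    ("Expert", "Tapp"): 4.20,
}


def default_design() -> StudyDesign:
    return StudyDesign(
        groups=list(GROUPS),
        conditions=list(CONDITIONS),
        n_per_group={"Nonmusician": 19, "Amateur": 20, "Expert": 20},
    )


def generate_montage(
    n_channels: int = 204,
    seed: int | np.random.Generator | None = None,
    radius: float = 90.0,
    jitter_deg: float = 1.0,
) -> ElectrodeMontage:
    """Quasi-uniform electrodes on the upper ~2.7π sr of a sphere (mm).

    A golden-angle (Fibonacci) spiral covers the cap down to the cheek/neck
    exclusion line; a small seeded angular jitter individualises montages.
    """
    if n_channels < 16:
        raise ValueError("need at least 16 channels")
    rng = np.random.default_rng(seed)
    # cap area 2.7π sr ⇒ cos(θ_max) = 1 − 2.7/2 = −0.35
    z = np.linspace(1.0, -0.35, n_channels, endpoint=False) - (1.0 + 0.35) / (2 * n_channels)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * np.arange(n_channels)
    sin_t = np.sqrt(1.0 - z**2)
    pts = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), z])
    if jitter_deg > 0:
        jit = rng.normal(scale=np.deg2rad(jitter_deg), size=(n_channels, 3))
        pts = pts + np.cross(jit, pts)
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    labels = [f"E{i + 1}" for i in range(n_channels)]
    return ElectrodeMontage(labels, radius * pts)


def generate_templates(
    k: int,
    montage: ElectrodeMontage,
    grid: SourceGrid,
    head: HeadModel,
    seed: int | np.random.Generator | None = None,
    max_abs_corr: float = 0.8,
    min_eccentricity: float = 0.75,
    max_draws: int = 1000,
) -> tuple[np.ndarray, list[dict]]:
    """k template maps from forward-projected superficial dipole pairs.

    Maps are average-referenced, unit-GFP, and mutually dissimilar
    (pairwise |spatial correlation| below ``max_abs_corr``, which keeps every
    pairwise GMD above √(2(1−max_abs_corr))).  Returns (maps, source records).
    """
    if k < 2:
        raise ValueError("need k ≥ 2 templates")
    rng = np.random.default_rng(seed)
    radii = np.linalg.norm(grid.positions - head.center, axis=1)
    superficial = np.nonzero(radii >= min_eccentricity * radii.max())[0]
    maps: list[np.ndarray] = []
    sources: list[dict] = []
    draws = 0
    while len(maps) < k:
        if draws >= max_draws:
            raise RuntimeError(
                f"could not draw {k} mutually dissimilar maps in {max_draws} attempts"
            )
        draws += 1
        nodes = rng.choice(superficial, size=2, replace=False)
        moments = rng.normal(size=(2, 3))
        moments /= np.linalg.norm(moments, axis=1, keepdims=True)
        pots = dipole_potentials(montage, grid.positions[nodes], head)
        v = np.einsum("cpd,pd->c", pots, moments)
        v = v - v.mean()
        g = np.sqrt((v**2).mean())
        if g == 0:
            continue
        v = v / g
        if any(abs(_corr(v, m)) >= max_abs_corr for m in maps):
            continue
        maps.append(v)
        sources.append({"nodes": nodes.tolist(), "moments": moments.tolist()})
    return np.stack(maps), sources


def _corr(u: np.ndarray, v: np.ndarray) -> float:
    u = u - u.mean()
    v = v - v.mean()
    return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))


def default_timeline(
    design: StudyDesign, sfreq: float = 250.0
) -> dict[tuple[str, str], list[tuple[int, float, float]]]:
    """Per-cell (map index, onset ms, offset ms) segments on the 250 Hz grid.

    Maps 0–2 form a shared early sequence, maps 3–6 split the 295–480 ms
    analysis window with group/condition-specific durations, and map 2
    returns for the late tail.
    """
    frame = 1000.0 / sfreq
    out = {}
    for g in design.groups:
        base = _WINDOW_FRAMES.get(g, _WINDOW_FRAMES["Amateur"])
        for c in design.conditions:
            shift = _CONDITION_SHIFT.get(c, 0)
            frames = list(base)
            frames[0] -= shift
            frames[1] += shift
            segs = [(0, 0.0, 100.0), (1, 100.0, 200.0), (2, 200.0, 296.0)]
            t = 296.0
            for m, nf in zip((3, 4, 5, 6), frames):
                segs.append((m, t, t + nf * frame))
                t += nf * frame
            segs.append((2, t, 750.0))
            out[(g, c)] = segs
    return out


@dataclass
class SimulationSpec:
    """Parameters of the synthetic EEG study."""

    design: StudyDesign = field(default_factory=default_design)
    k_templates: int = 7
    timeline: dict[tuple[str, str], list[tuple[int, float, float]]] | None = None
    cell_amplitudes: dict[tuple[str, str], float] | None = None  # relative scale
    amplitude_uv: float = 3.0  # peak-of-envelope GFP scale, µV
    noise_sd: float | None = None  # µV per channel/sample; None → from target_snr
    target_snr: float = 0.5  # single-trial RMS signal/noise when noise_sd is None
    n_trials: int = 70
    sfreq: float = 250.0
    subject_jitter_sd: float = 0.2  # log-normal amplitude jitter across subjects
    window: tuple[float, float] = ANALYSIS_WINDOW

    def __post_init__(self) -> None:
        if self.timeline is None:
            self.timeline = default_timeline(self.design, min(self.sfreq, 250.0))
        if self.cell_amplitudes is None:
            self.cell_amplitudes = {
                (g, c): 1.0 for g in self.design.groups for c in self.design.conditions
            }
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be ≥ 0")
        for cell, segs in self.timeline.items():
            last = EPOCH_MS[0]
            for m, t0, t1 in sorted(segs, key=lambda s: s[1]):
                if t0 < last or t1 <= t0 or t1 > EPOCH_MS[1]:
                    raise ValueError(f"timeline segments overlap or leave the epoch in {cell}")
                last = t1
            if self.k_templates <= max(s[0] for s in segs):
                raise ValueError("timeline references a template beyond k_templates")

    @property
    def n_samples(self) -> int:
        pre = round(-EPOCH_MS[0] / 1000.0 * self.sfreq)
        post = int(np.floor(EPOCH_MS[1] / 1000.0 * self.sfreq))
        return pre + post + 1

    @property
    def t0_index(self) -> int:
        return round(-EPOCH_MS[0] / 1000.0 * self.sfreq)


@dataclass
class GroundTruth:
    """Everything the recovery oracles need."""

    templates: np.ndarray  # (k, n_channels)
    timeline: dict[tuple[str, str], list[tuple[int, float, float]]]
    durations: dict[tuple[str, str], dict[int, float]]  # ms inside the window
    window: tuple[float, float]
    sources: list[dict]
    dprime_by_cell: dict[tuple[str, str], float] | None = None
    noise_sd: float = np.nan


def _envelope(t_ms: np.ndarray) -> np.ndarray:
    """Smooth positive amplitude envelope over the post-stimulus period."""
    return 1.0 + 0.8 * np.sin(np.pi * np.clip(t_ms, 0.0, 750.0) / 750.0)


def cell_erp(spec: SimulationSpec, templates: np.ndarray, cell: tuple[str, str]) -> np.ndarray:
    """Noise-free ERP (channels × samples) of one design cell."""
    n = spec.n_samples
    t_ms = (np.arange(n) - spec.t0_index) * 1000.0 / spec.sfreq
    out = np.zeros((templates.shape[1], n))
    amp = spec.amplitude_uv * spec.cell_amplitudes[cell]
    for m, t0, t1 in spec.timeline[cell]:
        sel = (t_ms >= t0) & (t_ms < t1)
        out[:, sel] = templates[m][:, None] * (_envelope(t_ms[sel]) * amp)[None, :]
    return out


def true_durations(
    spec: SimulationSpec, cell: tuple[str, str]
) -> dict[int, float]:
    """Ground-truth per-map duration (ms) inside the analysis window."""
    n = spec.n_samples
    t_ms = (np.arange(n) - spec.t0_index) * 1000.0 / spec.sfreq
    lo, hi = spec.window
    frame = 1000.0 / spec.sfreq
    out = {m: 0.0 for m in range(spec.k_templates)}
    for m, t0, t1 in spec.timeline[cell]:
        sel = (t_ms >= max(t0, lo)) & (t_ms < min(t1, hi))
        out[m] += float(sel.sum()) * frame
    return out


def _signal_rms(spec: SimulationSpec, templates: np.ndarray) -> float:
    erps = [cell_erp(spec, templates, cell) for cell in spec.timeline]
    return float(np.sqrt(np.mean([np.mean(e**2) for e in erps])))


def resolve_noise_sd(spec: SimulationSpec, templates: np.ndarray) -> float:
    if spec.noise_sd is not None:
        return float(spec.noise_sd)
    return _signal_rms(spec, templates) / spec.target_snr


def _ground_truth(spec, templates, sources, noise_sd) -> GroundTruth:
    return GroundTruth(
        templates=templates,
        timeline=spec.timeline,
        durations={cell: true_durations(spec, cell) for cell in spec.timeline},
        window=spec.window,
        sources=sources,
        noise_sd=noise_sd,
    )


def simulate_study(
    spec: SimulationSpec,
    templates: np.ndarray,
    montage: ElectrodeMontage | None = None,
    seed: int | np.random.Generator | None = None,
    sources: list[dict] | None = None,
) -> tuple[list[EpochSet], GroundTruth]:
    """Trial-level simulation: every subject × condition gets an EpochSet.

    Each trial is the cell ERP scaled by the subject's log-normal amplitude
    jitter plus independent Gaussian channel noise.
    """
    rng = np.random.default_rng(seed)
    noise_sd = resolve_noise_sd(spec, templates)
    labels = list(montage.labels) if montage is not None else None
    out = []
    for subj, group in spec.design.subject_ids():
        jitter = float(np.exp(rng.normal(0.0, spec.subject_jitter_sd)))
        for cond in spec.design.conditions:
            erp = cell_erp(spec, templates, (group, cond)) * jitter
            noise = rng.normal(0.0, noise_sd, size=(spec.n_trials,) + erp.shape) if noise_sd else 0.0
            out.append(
                EpochSet(
                    subject_id=subj,
                    group=group,
                    condition=cond,
                    sfreq=spec.sfreq,
                    data=erp[None] + noise,
                    t0_index=spec.t0_index,
                    labels=labels,
                )
            )
    return out, _ground_truth(spec, templates, sources or [], noise_sd)


def simulate_study_evoked(
    spec: SimulationSpec,
    templates: np.ndarray,
    montage: ElectrodeMontage | None = None,
    seed: int | np.random.Generator | None = None,
    sources: list[dict] | None = None,
) -> tuple[list[Evoked], GroundTruth]:
    """Evoked-level simulation: subject ERPs with noise sd ``noise_sd/√n_trials``.

    Statistically equivalent to averaging the trial-level output, at a fraction
    of the cost; the returned evokeds are average-referenced and
    baseline-corrected like real pipeline output.
    """
    rng = np.random.default_rng(seed)
    noise_sd = resolve_noise_sd(spec, templates)
    ev_sd = noise_sd / np.sqrt(spec.n_trials)
    labels = list(montage.labels) if montage is not None else None
    t_ms = (np.arange(spec.n_samples) - spec.t0_index) * 1000.0 / spec.sfreq
    base_sel = t_ms < 0
    out = []
    for subj, group in spec.design.subject_ids():
        jitter = float(np.exp(rng.normal(0.0, spec.subject_jitter_sd)))
        for cond in spec.design.conditions:
            data = cell_erp(spec, templates, (group, cond)) * jitter
            if ev_sd:
                data = data + rng.normal(0.0, ev_sd, size=data.shape)
            data = average_reference(data)
            data = data - data[:, base_sel].mean(axis=1, keepdims=True)
            out.append(
                Evoked(
                    data=data,
                    sfreq=spec.sfreq,
                    t0_index=spec.t0_index,
                    n_epochs=spec.n_trials,
                    baseline_window=(EPOCH_MS[0], 0.0),
                    average_referenced=True,
                    baseline_corrected=True,
                    labels=labels,
                    subject_id=subj,
                    group=group,
                    condition=cond,
                )
            )
    return out, _ground_truth(spec, templates, sources or [], noise_sd)


def grand_means(evokeds: list[Evoked]) -> dict[tuple[str, str], Evoked]:
    """Average the subject evokeds of each group × condition cell."""
    cells: dict[tuple[str, str], list[Evoked]] = {}
    for ev in evokeds:
        cells.setdefault((ev.group, ev.condition), []).append(ev)
    out = {}
    for cell, evs in cells.items():
        ref = evs[0]
        out[cell] = Evoked(
            data=np.mean([e.data for e in evs], axis=0),
            sfreq=ref.sfreq,
            t0_index=ref.t0_index,
            n_epochs=len(evs),
            baseline_window=ref.baseline_window,
            average_referenced=ref.average_referenced,
            baseline_corrected=ref.baseline_corrected,
            labels=ref.labels,
            group=cell[0],
            condition=cell[1],
        )
    return out


# ---------------------------------------------------------------------------
# behavior

def simulate_behavior(
    design: StudyDesign,
    dprime_by_cell: dict[tuple[str, str], float] | None = None,
    criterion_c: float = 0.0,
    n_trials_per_condition: int = 90,
    subject_sd: float = 0.45,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Trial-level YES/NO responses under equal-variance signal detection.

    Regular endings are the noise class.  A subject's false-alarm rate is
    Φ(−d̄/2 − c) with d̄ the subject's mean sensitivity over transgressions
    (one shared R response criterion), and each transgression's hit rate is
    chosen so that z(hit) − z(fa) equals that cell's d′ exactly.
    ``subject_sd`` is the between-subject spread of true sensitivity.
    """
    if n_trials_per_condition < 1:
        raise ValueError("need at least 1 trial per condition")
    rng = np.random.default_rng(seed)
    dp = dprime_by_cell or {
        k: v for k, v in DEFAULT_DPRIME.items() if k[0] in design.groups
    }
    transgressions = [c for c in design.conditions if c != "R"]
    rows = []
    for subj, group in design.subject_ids():
        d_subj = {}
        for c in transgressions:
            mean_d = dp[(group, c)]
            if not np.isfinite(mean_d):
                raise ValueError("d′ must be finite")
            d_subj[c] = mean_d + (rng.normal(0.0, subject_sd) if subject_sd else 0.0)
        d_bar = np.mean(list(d_subj.values()))
        fa_rate = float(stats.norm.cdf(-d_bar / 2.0 - criterion_c))
        fa_rate = min(max(fa_rate, 1e-9), 1 - 1e-9)
        for cond in design.conditions:
            if cond == "R":
                p_no = fa_rate
            else:
                hit = float(stats.norm.cdf(d_subj[cond] + stats.norm.ppf(fa_rate)))
                p_no = min(max(hit, 1e-9), 1 - 1e-9)
            nos = rng.random(n_trials_per_condition) < p_no
            for resp_no in nos:
                rows.append(
                    {
                        "subject_id": subj,
                        "group": group,
                        "condition": cond,
                        "response": "NO" if resp_no else "YES",
                    }
                )
    return pd.DataFrame(rows)
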