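"""Topographic microstate analysis of ERPs.

The grand-mean ERPs of every group × condition cell are segmented jointly into
*k* quasi-stable scalp topographies (microstates) with a modified k-means that
clusters time frames by spatial correlation rather than amplitude.  Model
order is chosen by a cross-validation criterion together with a
Krzanowski–Lai-style dispersion ratio.  The winning template maps are then
back-fitted to each individual ERP inside an analysis window, yielding
per-subject microstate durations that are compared nonparametrically.

Clustering is polarity-sensitive by default: evoked components have a fixed
polarity, so a map and its mirror image are treated as different states.  The
polarity-invariant variant (classical spontaneous-EEG convention) is kept as
an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import Evoked, StatTable, StudyDesign


# ---------------------------------------------------------------------------
# elementary topographic measures

def gfp(maps: np.ndarray) -> np.ndarray | float:
    """Global field power: spatial RMS about the channel mean.

    Accepts a single map (channels,) or frames (channels, t).
    """
    maps = np.asarray(maps, float)
    dev = maps - maps.mean(axis=0, keepdims=True)
    out = np.sqrt((dev**2).mean(axis=0))
    return float(out) if out.ndim == 0 else out


def spatial_corr(u: np.ndarray, v: np.ndarray) -> float:
    """Spatial Pearson correlation between two maps."""
    u = np.asarray(u, float) - np.mean(u)
    v = np.asarray(v, float) - np.mean(v)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("spatial correlation undefined for a flat map")
    return float(u @ v / (nu * nv))


def gmd(u: np.ndarray, v: np.ndarray) -> float:
    """Global map dissimilarity: RMS difference of the GFP-normalized maps.

    Satisfies gmd² = 2(1 − r) with r the spatial correlation, so gmd ∈ [0, 2]
    with 0 for identical and 2 for polarity-reversed topographies.
    """
    u = np.asarray(u, float) - np.mean(u)
    v = np.asarray(v, float) - np.mean(v)
    gu, gv = gfp(u), gfp(v)
    if gu == 0 or gv == 0:
        raise ValueError("gmd undefined for a zero-GFP map")
    return float(np.sqrt(np.mean((u / gu - v / gv) ** 2)))


def _normalize_maps(maps: np.ndarray) -> np.ndarray:
    """Average-reference each map and scale to unit GFP."""
    maps = np.asarray(maps, float)
    maps = maps - maps.mean(axis=1, keepdims=True)
    g = np.sqrt((maps**2).mean(axis=1, keepdims=True))
    g[g == 0] = 1.0
    return maps / g


# ---------------------------------------------------------------------------
# containers

@dataclass
class MicrostateModel:
    """k template maps (average-referenced, unit GFP) plus selection metadata."""

    maps: np.ndarray  # (k, n_channels)
    polarity_mode: str = "sensitive"  # or "invariant"
    gev: float = np.nan  # global explained variance of the training segmentation
    selection: pd.DataFrame | None = None  # per-k criteria table from choose_k

    def __post_init__(self) -> None:
        self.maps = _normalize_maps(self.maps)
        if self.maps.shape[0] < 2:
            raise ValueError("a microstate model needs k ≥ 2 maps")

    @property
    def k(self) -> int:
        return self.maps.shape[0]


@dataclass
class LabelSequence:
    """Per-frame map assignment (−1 = unlabeled); sample-grid aligned."""

    labels: np.ndarray  # (n_frames,) int
    sfreq: float
    t0_index: int  # index of stimulus onset relative to labels[0] (may be negative)
    group: str = ""
    condition: str = ""
    subject_id: str = ""

    @property
    def times(self) -> np.ndarray:
        return (np.arange(len(self.labels)) - self.t0_index) * 1000.0 / self.sfreq


# ---------------------------------------------------------------------------
# segmentation

def _assign(frames_n: np.ndarray, maps_n: np.ndarray, polarity: str) -> tuple[np.ndarray, np.ndarray]:
    """Best map per frame by spatial correlation; returns (labels, corr values).

    Ties break toward the lowest map index (argmax convention).
    """
    corr = maps_n @ frames_n  # (k, t); both unit-normalized and centred
    eff = np.abs(corr) if polarity == "invariant" else corr
    labels = np.argmax(eff, axis=0)
    return labels, eff[labels, np.arange(frames_n.shape[1])]

def _unit_frames(frames: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centre frames and scale to unit vector norm; returns (unit frames, frame norms)."""
    centred = frames - frames.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(centred, axis=0)
    safe = np.where(norms == 0, 1.0, norms)
    return centred / safe, norms


def _recompute_maps(
    frames_n: np.ndarray, labels: np.ndarray, k: int, polarity: str, rng: np.random.Generator
) -> np.ndarray:
    maps = np.empty((k, frames_n.shape[0]))
    for j in range(k):
        members = frames_n[:, labels == j]
        if members.shape[1] == 0:
            # empty cluster: reseed from the worst-fit frame
            maps[j] = np.nan
            continue
        if polarity == "invariant":
            # first principal direction of the member frames
            u, s, _ = np.linalg.svd(members, full_matrices=False)
            maps[j] = u[:, 0]
        else:
            maps[j] = members.mean(axis=1)
    return maps


def _seed_maps(frames_n: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Farthest-point seeding in correlation space: start from a random frame,
    then repeatedly add the frame least correlated with all chosen seeds."""
    t = frames_n.shape[1]
    chosen = [int(rng.integers(t))]
    max_abs = np.abs(frames_n[:, chosen[0]] @ frames_n)
    for _ in range(1, k):
        nxt = int(np.argmin(max_abs))
        chosen.append(nxt)
        max_abs = np.maximum(max_abs, np.abs(frames_n[:, nxt] @ frames_n))
    return frames_n[:, chosen].T.copy()


def _kmeans_once(
    frames_n: np.ndarray, k: int, polarity: str, rng: np.random.Generator, max_iter: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    maps = _unit_rows(_seed_maps(frames_n, k, rng))
    labels = np.full(frames_n.shape[1], -1)
    for _ in range(max_iter):
        new_labels, corrs = _assign(frames_n, maps, polarity)
        # reseed empty clusters from the worst-fit frame
        for j in range(k):
            if not np.any(new_labels == j):
                worst = np.argmin(corrs)
                maps[j] = frames_n[:, worst]
                new_labels[worst] = j
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        raw = _recompute_maps(frames_n, labels, k, polarity, rng)
        for j in range(k):
            if np.all(np.isnan(raw[j])):
                raw[j] = maps[j]
        maps = _unit_rows(raw)
    return maps, labels


def _unit_rows(maps: np.ndarray) -> np.ndarray:
    maps = maps - maps.mean(axis=1, keepdims=True)
    n = np.linalg.norm(maps, axis=1, keepdims=True)
    n[n == 0] = 1.0
    return maps / n


def _smooth_labels(
    labels: np.ndarray, frames_n: np.ndarray, maps_n: np.ndarray, min_frames: int, polarity: str
) -> np.ndarray:
    """Reject segments shorter than min_frames, reassigning each frame to the
    neighbouring segment's map with the higher spatial correlation."""
    labels = labels.copy()
    while True:
        runs = _runs(labels)
        if len(runs) == 1:
            return labels
        short = []
        for idx, (start, stop) in enumerate(runs):
            if stop - start >= min_frames or labels[start] < 0:
                continue
            left = labels[runs[idx - 1][0]] if idx > 0 else -1
            right = labels[runs[idx + 1][0]] if idx < len(runs) - 1 else -1
            cand = [c for c in (left, right) if c >= 0]
            if cand:
                short.append((stop - start, start, stop, cand))
        if not short:
            return labels
        _, start, stop, cand = min(short)
        for i in range(start, stop):
            cors = []
            for c in cand:
                v = maps_n[c] @ frames_n[:, i]
                cors.append(abs(v) if polarity == "invariant" else v)
            labels[i] = cand[int(np.argmax(cors))]


def _runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """Maximal constant runs as half-open (start, stop) index pairs."""
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((start, i))
            start = i
    return out


def segment(
    grand_means: dict[tuple[str, str], Evoked],
    k: int,
    n_restarts: int = 100,
    polarity: str = "sensitive",
    min_frames: int = 7,
    window: tuple[float, float] = (0.0, 750.0),
    seed: int | np.random.Generator | None = None,
) -> tuple[MicrostateModel, dict[tuple[str, str], LabelSequence]]:
    """Segment the cell grand-mean ERPs jointly into k microstate maps.

    Modified k-means on topographic similarity: frames are assigned to the map
    with the highest spatial correlation and maps are recomputed from their
    members; the best of ``n_restarts`` random initialisations (by explained
    variance) wins.  Labeled segments shorter than ``min_frames`` are removed
    by the smoothing rule.  Zero-GFP frames stay unlabeled.
    """
    rng = np.random.default_rng(seed)
    cells = list(grand_means)
    first = grand_means[cells[0]]
    sels = {}
    blocks = []
    for cell in cells:
        ev = grand_means[cell]
        if ev.sfreq != first.sfreq or ev.n_channels != first.n_channels:
            raise ValueError("all cells must share channels and sampling rate")
        sel = ev.window(*window)
        sels[cell] = sel
        blocks.append(ev.data[:, sel])
    frames = np.concatenate(blocks, axis=1)
    frames_n, norms = _unit_frames(frames)
    usable = norms > 0
    if k < 2:
        raise ValueError("k must be ≥ 2")

    best = None
    fit_frames = frames_n[:, usable]
    for _ in range(max(1, n_restarts)):
        maps, labels = _kmeans_once(fit_frames, k, polarity, rng)
        gev_val = _gev(frames[:, usable], maps, labels, polarity)
        if best is None or gev_val > best[0]:
            best = (gev_val, maps, labels)
    _, maps, fit_labels = best
    labels = np.full(frames.shape[1], -1)
    labels[usable] = fit_labels

    # smooth per cell (segments never straddle cell boundaries)
    offsets = np.cumsum([0] + [b.shape[1] for b in blocks])
    seqs: dict[tuple[str, str], LabelSequence] = {}
    for ci, cell in enumerate(cells):
        seg_labels = labels[offsets[ci] : offsets[ci + 1]]
        seg_frames = frames_n[:, offsets[ci] : offsets[ci + 1]]
        seg_labels = _smooth_labels(seg_labels, seg_frames, maps, min_frames, polarity)
        labels[offsets[ci] : offsets[ci + 1]] = seg_labels
        ev = grand_means[cell]
        sel = sels[cell]
        t0 = ev.t0_index - sel[0]
        seqs[cell] = LabelSequence(
            labels=seg_labels, sfreq=ev.sfreq, t0_index=t0, group=cell[0], condition=cell[1]
        )
    model = MicrostateModel(
        maps=maps, polarity_mode=polarity, gev=_gev(frames, maps, labels, polarity)
    )
    return model, seqs


def _gev(frames: np.ndarray, maps_n: np.ndarray, labels: np.ndarray, polarity: str) -> float:
    frames_n, norms = _unit_frames(frames)
    g2 = norms**2
    denom = g2.sum()
    if denom == 0:
        return 0.0
    lab = np.asarray(labels)
    ok = lab >= 0
    if not np.any(ok):
        return 0.0
    corr = np.einsum("ct,tc->t", frames_n[:, ok], maps_n[lab[ok]])
    return float((g2[ok] * corr**2).sum() / denom)


def explained_variance(
    model: MicrostateModel, frames: np.ndarray, labels: np.ndarray
) -> float:
    """Global explained variance: GFP²-weighted mean squared spatial correlation
    between each labeled frame and its assigned map (unlabeled frames count 0)."""
    maps_n = model.maps / np.linalg.norm(model.maps, axis=1, keepdims=True)
    return _gev(np.asarray(frames, float), maps_n, np.asarray(labels), model.polarity_mode)


# ---------------------------------------------------------------------------
# model-order selection

def segmentation_criteria(
    grand_means: dict[tuple[str, str], Evoked],
    k_range: range,
    window: tuple[float, float] = (0.0, 750.0),
    n_restarts: int = 50,
    polarity: str = "sensitive",
    min_frames: int = 7,
    seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict[int, tuple[MicrostateModel, dict]]]:
    """Fit a range of k values and tabulate CV and dispersion per k."""
    rng = np.random.default_rng(seed)
    rows = []
    fits = {}
    cells = list(grand_means)
    blocks = [grand_means[c].data[:, grand_means[c].window(*window)] for c in cells]
    frames = np.concatenate(blocks, axis=1)
    frames_n, norms = _unit_frames(frames)
    usable = norms > 0
    n_ch = frames.shape[0]
    for k in k_range:
        model, seqs = segment(
            grand_means,
            k,
            n_restarts=n_restarts,
            polarity=polarity,
            min_frames=min_frames,
            window=window,
            seed=rng,
        )
        # criteria use the raw (pre-smoothing) assignment of every usable frame
        maps_n = model.maps / np.linalg.norm(model.maps, axis=1, keepdims=True)
        raw_labels, corr = _assign(frames_n[:, usable], maps_n, polarity)
        resid = norms[usable] ** 2 * (1 - corr**2)
        w_k = float(resid.sum())
        sigma2 = w_k / (usable.sum() * (n_ch - 1))
        cv = sigma2 * ((n_ch - 1) / (n_ch - 1 - k)) ** 2
        rows.append({"k": k, "cv": cv, "dispersion": w_k, "gev": model.gev})
        fits[k] = (model, seqs)
    table = pd.DataFrame(rows)
    table.attrs["n_channels"] = n_ch
    return table, fits


def choose_k(criteria: pd.DataFrame, cv_slack: float = 0.05, exponent: float | None = None) -> tuple[int, pd.DataFrame]:
    """Pick the model order from the per-k criteria table.

    The Krzanowski–Lai-style index is DIFF(k)/DIFF(k+1) with
    DIFF(k) = W(k−1)^(2/C) − W(k)^(2/C) on the dispersion curve W (the exponent
    2/C uses the channel count C unless overridden); it is 0 by convention at
    the endpoints of the k range.  The winner is the KL argmax among k whose
    cross-validation criterion lies within ``cv_slack`` of the CV minimum.
    """
    tab = criteria.sort_values("k").reset_index(drop=True).copy()
    if len(tab) < 4:
        raise ValueError("need at least 4 consecutive k values")
    ks = tab["k"].to_numpy()
    if not np.all(np.diff(ks) == 1):
        raise ValueError("k values must be consecutive")
    w = tab["dispersion"].to_numpy(float)
    n_ch = tab.attrs.get("n_channels")
    expo = exponent if exponent is not None else 2.0 / (n_ch if n_ch else 204)
    wt = np.power(np.maximum(w, 0.0), expo)
    kl = np.zeros(len(tab))
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in range(1, len(tab) - 1):
            diff_k = wt[i - 1] - wt[i]
            diff_k1 = wt[i] - wt[i + 1]
            if diff_k1 == 0:
                kl[i] = np.inf if diff_k > 0 else 0.0
            else:
                kl[i] = diff_k / diff_k1
    tab["kl"] = kl
    cv = tab["cv"].to_numpy(float)
    admissible = cv <= (1.0 + cv_slack) * cv.min()
    cand = np.where(admissible, kl, -np.inf)
    k_opt = int(ks[int(np.argmax(cand))])
    return k_opt, tab


# ---------------------------------------------------------------------------
# back-fitting and durations

def backfit(
    model: MicrostateModel, evoked: Evoked, window: tuple[float, float] = (295.0, 480.0)
) -> LabelSequence:
    """Assign each frame in the window to the best-correlating template map.

    No smoothing is applied at back-fit, so individual durations may be
    fragmented; zero-GFP frames stay unlabeled.
    """
    sel = evoked.window(*window)
    frames = evoked.data[:, sel]
    frames_n, norms = _unit_frames(frames)
    maps_n = model.maps / np.linalg.norm(model.maps, axis=1, keepdims=True)
    labels, _ = _assign(frames_n, maps_n, model.polarity_mode)
    labels = labels.astype(int)
    labels[norms == 0] = -1
    return LabelSequence(
        labels=labels,
        sfreq=evoked.sfreq,
        t0_index=evoked.t0_index - (sel[0] if sel.size else 0),
        group=evoked.group,
        condition=evoked.condition,
        subject_id=evoked.subject_id,
    )


def durations(seq: LabelSequence, k: int) -> dict[int, float]:
    """Total per-map duration in ms (key −1 collects unlabeled time)."""
    frame_ms = 1000.0 / seq.sfreq
    out = {j: 0.0 for j in range(k)}
    out[-1] = 0.0
    for lab in seq.labels:
        out[int(lab)] += frame_ms
    return out


def duration_table(
    model: MicrostateModel,
    evokeds: list[Evoked],
    window: tuple[float, float] = (295.0, 480.0),
) -> pd.DataFrame:
    """Back-fit every individual ERP and tabulate per-map durations (long format)."""
    rows = []
    for ev in evokeds:
        seq = backfit(model, ev, window=window)
        dur = durations(seq, model.k)
        for map_idx, ms in dur.items():
            rows.append(
                {
                    "subject_id": ev.subject_id,
                    "group": ev.group,
                    "condition": ev.condition,
                    "map": map_idx,
                    "duration_ms": ms,
                }
            )
    return pd.DataFrame(rows)


def duration_tests(
    table: pd.DataFrame,
    design: StudyDesign,
    maps: list[int] | None = None,
    alpha: float = 0.05,
) -> StatTable:
    """Kruskal–Wallis across groups per map × condition, with Bonferroni-corrected
    pairwise Mann–Whitney U tests gated on a significant omnibus."""
    out = StatTable()
    map_ids = maps if maps is not None else sorted(m for m in table["map"].unique() if m >= 0)
    n_pairs = len(design.groups) * (len(design.groups) - 1) // 2
    for cond in design.conditions:
        for map_idx in map_ids:
            sub = table[(table["condition"] == cond) & (table["map"] == map_idx)]
            samples = [
                sub[sub["group"] == g]["duration_ms"].to_numpy(float) for g in design.groups
            ]
            if any(len(s) < 2 for s in samples):
                raise ValueError("need at least 2 subjects per group")
            try:
                with np.errstate(invalid="ignore"):
                    h, p = stats.kruskal(*samples)
            except ValueError:  # all values identical
                h, p = 0.0, 1.0
            if not (np.isfinite(h) and np.isfinite(p)):  # fully tied data
                h, p = 0.0, 1.0
            label = f"map{map_idx}|{cond}"
            out.add(label, "KruskalWallis-H", h, df1=len(samples) - 1, p=p)
            if p < alpha:
                for i in range(len(design.groups)):
                    for j in range(i + 1, len(design.groups)):
                        u, pu = stats.mannwhitneyu(
                            samples[i], samples[j], alternative="two-sided"
                        )
                        out.add(
                            f"{label}|{design.groups[i]} vs {design.groups[j]}",
                            "MannWhitney-U",
                            u,
                            df1=len(samples[i]) + len(samples[j]) - 2,
                            p=min(1.0, pu * n_pairs),
                            correction=f"bonferroni{n_pairs}|gatekept",
                        )
    return out
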