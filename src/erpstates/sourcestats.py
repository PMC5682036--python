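"""Statistical parametric mapping on current-density maps.

Node-wise mixed ANOVA (expertise × condition), cluster-extent thresholding
under a fixed connection radius, AlphaSim-style Monte-Carlo calibration of the
cluster criterion, and gatekept Fisher-LSD post-hocs at peak nodes.

The Monte-Carlo surrogate smooths i.i.d. Gaussian node noise with a Gaussian
kernel over node distances (the assumed spatial smoothness of the real maps),
re-standardizes, thresholds two-sidedly at the node alpha and searches for
clusters; the real CD maps themselves are never smoothed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .anova import MixedAnovaResult, mixed_anova, oneway_anova
from .forward import SourceGrid
from .types import StatTable

logger = logging.getLogger("erpstates")

EFFECTS = ("between", "within", "interaction")


def mixed_anova_map(
    cd: np.ndarray, groups: np.ndarray
) -> MixedAnovaResult:
    """Node-wise mixed ANOVA on CD maps of shape (n_subjects, n_conditions, n_nodes)."""
    cd = np.asarray(cd, float)
    if cd.ndim != 3:
        raise ValueError("cd must be subjects × conditions × nodes")
    return mixed_anova(cd, groups)


def threshold_clusters(
    p_map: np.ndarray,
    f_map: np.ndarray,
    grid: SourceGrid,
    node_alpha: float = 0.005,
    min_nodes: int = 10,
    effect: str = "",
) -> pd.DataFrame:
    """Connected components of supra-threshold nodes, kept if ≥ min_nodes.

    Contiguity is the grid's connection-radius adjacency.  Returns one row per
    surviving cluster with its size, peak F, peak coordinates and member ids.
    """
    p_map = np.asarray(p_map, float)
    f_map = np.asarray(f_map, float)
    mask = p_map < node_alpha
    rows = []
    idx = np.nonzero(mask)[0]
    if idx.size:
        sub = grid.adjacency[np.ix_(idx, idx)]
        n_comp, comp = connected_components(sub, directed=False)
        for c in range(n_comp):
            members = idx[comp == c]
            if members.size < min_nodes:
                continue
            peak = members[np.argmax(f_map[members])]
            rows.append(
                {
                    "effect": effect,
                    "size": int(members.size),
                    "peak_f": float(f_map[peak]),
                    "peak_node": int(peak),
                    "peak_x": float(grid.positions[peak, 0]),
                    "peak_y": float(grid.positions[peak, 1]),
                    "peak_z": float(grid.positions[peak, 2]),
                    "members": members.tolist(),
                }
            )
    rows.sort(key=lambda r: -r["size"])
    return pd.DataFrame(
        rows,
        columns=["effect", "size", "peak_f", "peak_node", "peak_x", "peak_y", "peak_z", "members"],
    )


@dataclass
class MCCalibration:
    n_iterations: int
    fwhm: float
    node_alpha: float
    min_nodes: int
    probability: float  # per-map chance of ≥1 surviving cluster
    n_hits: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability outside [0, 1]")


def smoothing_kernel(grid: SourceGrid, fwhm: float, cutoff_sd: float = 3.5):
    """Sparse Gaussian smoothing kernel over node distances, rows normalized to 1."""
    n = grid.n_nodes
    if fwhm <= 0:
        return sparse.identity(n, format="csr"), np.ones(n)
    sd = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # FWHM → σ
    from scipy.spatial import cKDTree

    tree = cKDTree(grid.positions)
    pairs = tree.sparse_distance_matrix(tree, cutoff_sd * sd, output_type="coo_matrix")
    w = np.exp(-(pairs.data**2) / (2 * sd**2))
    kern = sparse.csr_matrix((w, (pairs.row, pairs.col)), shape=(n, n))
    row_sums = np.asarray(kern.sum(axis=1)).ravel()
    kern = sparse.diags(1.0 / row_sums) @ kern
    # standard deviation of each smoothed node given i.i.d. unit input
    node_sd = np.sqrt(np.asarray(kern.multiply(kern).sum(axis=1)).ravel())
    return kern.tocsr(), node_sd


def montecarlo_cluster_p(
    grid: SourceGrid,
    fwhm: float = 7.0,
    node_alpha: float = 0.005,
    min_nodes: int = 10,
    n_iter: int = 10_000,
    seed: int | np.random.Generator | None = None,
    batch: int = 250,
) -> MCCalibration:
    """Monte-Carlo estimate of the per-map probability that smooth Gaussian
    noise produces at least one cluster of ≥ min_nodes supra-threshold nodes."""
    if n_iter < 1:
        raise ValueError("n_iter must be ≥ 1")
    rng = np.random.default_rng(seed)
    kern, node_sd = smoothing_kernel(grid, fwhm)
    z_crit = stats.norm.isf(node_alpha / 2.0)  # two-sided node threshold
    hits = 0
    done = 0
    adj = grid.adjacency.tocsr()
    while done < n_iter:
        m = min(batch, n_iter - done)
        noise = rng.standard_normal((grid.n_nodes, m))
        smooth = kern @ noise
        smooth /= node_sd[:, None]
        supra = np.abs(smooth) > z_crit
        for col in range(m):
            idx = np.nonzero(supra[:, col])[0]
            if idx.size < min_nodes:
                continue
            sub = adj[np.ix_(idx, idx)]
            n_comp, comp = connected_components(sub, directed=False)
            if np.bincount(comp, minlength=n_comp).max() >= min_nodes:
                hits += 1
        done += m
    return MCCalibration(
        n_iterations=n_iter,
        fwhm=fwhm,
        node_alpha=node_alpha,
        min_nodes=min_nodes,
        probability=hits / n_iter,
        n_hits=hits,
        seed=seed if isinstance(seed, int) else None,
    )


def lsd_posthoc(
    values: np.ndarray,
    groups: np.ndarray,
    effect: str = "between",
    alpha: float = 0.05,
) -> StatTable:
    """Fisher-LSD pairwise contrasts at a peak node, gated on the omnibus test.

    Pairwise t-tests reuse the omnibus error term and its degrees of freedom
    with no further correction; with 3 groups the gatekeeping keeps the
    family-wise error at the nominal alpha.  Called with a non-significant
    omnibus it returns an empty table carrying a gatekeeping note.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    out = StatTable()

    if values.ndim == 1:
        f, p_omni, ms_err, df_err, means, n_g, levels = oneway_anova(values, groups)
        if p_omni >= alpha:
            out.note = f"omnibus p={p_omni:.4g} ≥ {alpha}: post-hocs withheld (gatekeeping)"
            return out
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                se = np.sqrt(ms_err * (1.0 / n_g[i] + 1.0 / n_g[j]))
                t = (means[i] - means[j]) / se if se > 0 else 0.0
                p = 2 * stats.t.sf(abs(t), df_err) if se > 0 else 1.0
                out.add(
                    f"{levels[i]} vs {levels[j]}", "t", t, df1=df_err, p=p,
                    correction="LSD|gatekept",
                )
        return out

    res = mixed_anova(values, groups)
    eff = res.effect(effect)
    p_omni = float(eff["p"])
    if p_omni >= alpha:
        out.note = f"omnibus p={p_omni:.4g} ≥ {alpha}: post-hocs withheld (gatekeeping)"
        return out
    levels = [g for i, g in enumerate(groups) if g not in groups[:i]]
    n_g = np.array([(groups == g).sum() for g in levels])
    b = values.shape[1]
    if effect == "between":
        subj_means = values.mean(axis=1)
        means = np.array([subj_means[groups == g].mean() for g in levels])
        ss_subj = b * sum(
            ((subj_means[groups == g] - subj_means[groups == g].mean()) ** 2).sum()
            for g in levels
        )
        df_err = res.df_between[1]
        ms = ss_subj / df_err / b  # per-observation error on subject means
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                se = np.sqrt(ms * (1.0 / n_g[i] + 1.0 / n_g[j]))
                t = (means[i] - means[j]) / se if se > 0 else 0.0
                p = 2 * stats.t.sf(abs(t), df_err) if se > 0 else 1.0
                out.add(
                    f"{levels[i]} vs {levels[j]}", "t", t, df1=df_err, p=p,
                    correction="LSD|gatekept",
                )
    else:
        cell = np.stack([values[groups == g].mean(axis=0) for g in levels])
        cond_means = cell.mean(axis=0)
        subj_mean = values.mean(axis=1)
        group_of = np.array([levels.index(g) for g in groups])
        subj_group_mean = np.stack([subj_mean[groups == g].mean() for g in levels])
        resid = values - subj_mean[:, None] - cell[group_of] + subj_group_mean[group_of][:, None]
        df_err = res.df_within[1]
        ms_err = (resid**2).sum() / df_err
        n_h = len(levels) / (1.0 / n_g).sum()
        for i in range(b):
            for j in range(i + 1, b):
                se = np.sqrt(2.0 * ms_err / (n_h * len(levels)))
                t = (cond_means[i] - cond_means[j]) / se if se > 0 else 0.0
                p = 2 * stats.t.sf(abs(t), df_err) if se > 0 else 1.0
                out.add(
                    f"cond{i} vs cond{j}", "t", t, df1=df_err, p=p,
                    correction="LSD|gatekept",
                )
    return out
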