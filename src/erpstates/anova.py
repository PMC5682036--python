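"""Mixed-design (split-plot) ANOVA engine shared by the source and behavioral arms.

One between-subject factor (expertise group, a levels) crossed with one
within-subject factor (condition, b levels).  Unequal group sizes are handled
by unweighted-means sums of squares (harmonic-mean cell weight), which
coincides with the classical solution when the design is balanced.  The
between main effect is tested against subjects-within-groups; the within main
effect and the interaction against the subject × condition residual.  No
sphericity correction is applied (the within factor has few levels and the
reference degrees of freedom are uncorrected).

All quantities broadcast over an optional trailing axis, so a whole
node-by-node statistical map is one call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class MixedAnovaResult:
    """F, df, p and partial η² for the three effects; values may be arrays."""

    f_between: np.ndarray
    f_within: np.ndarray
    f_interaction: np.ndarray
    p_between: np.ndarray
    p_within: np.ndarray
    p_interaction: np.ndarray
    df_between: tuple[float, float]
    df_within: tuple[float, float]
    df_interaction: tuple[float, float]
    eta_between: np.ndarray
    eta_within: np.ndarray
    eta_interaction: np.ndarray

    def effect(self, name: str) -> dict:
        f = getattr(self, f"f_{name}")
        p = getattr(self, f"p_{name}")
        df = getattr(self, f"df_{name}")
        eta = getattr(self, f"eta_{name}")
        return {"F": f, "p": p, "df": df, "eta_p2": eta}


def _safe_f(ss_eff: np.ndarray, df_eff: float, ss_err: np.ndarray, df_err: float):
    """F and p with the degenerate-variance convention: zero error and zero
    effect → F = 0, p = 1 (identical data carry no evidence)."""
    ms_eff = ss_eff / df_eff
    ms_err = ss_err / df_err
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(ms_err > 0, ms_eff / np.where(ms_err > 0, ms_err, 1.0), np.where(ms_eff > 0, np.inf, 0.0))
    p = np.where(np.isinf(f), 0.0, stats.f.sf(np.where(np.isinf(f), 0.0, f), df_eff, df_err))
    p = np.where((ms_err == 0) & (ms_eff == 0), 1.0, p)
    with np.errstate(invalid="ignore"):
        eta = np.where(ss_eff + ss_err > 0, ss_eff / np.where(ss_eff + ss_err > 0, ss_eff + ss_err, 1.0), 0.0)
    return f, p, eta


def mixed_anova(values: np.ndarray, groups: np.ndarray) -> MixedAnovaResult:
    """Mixed ANOVA on ``values`` of shape (n_subjects, n_conditions[, ...]).

    ``groups`` assigns each subject to a between-factor level (any hashable
    labels).  Trailing axes (e.g. source nodes) are vectorized.
    """
    y = np.asarray(values, float)
    if y.ndim == 2:
        y = y[..., None]
        squeeze = True
    else:
        squeeze = False
    groups = np.asarray(groups)
    levels = [g for i, g in enumerate(groups) if g not in groups[:i]]
    a = len(levels)
    n_subj, b = y.shape[:2]
    if a < 2 or b < 2:
        raise ValueError("need ≥2 levels on each factor")
    n_g = np.array([(groups == g).sum() for g in levels])
    if np.any(n_g < 2):
        raise ValueError("every group needs at least 2 subjects")
    n_total = int(n_g.sum())
    n_h = a / (1.0 / n_g).sum()  # harmonic mean group size

    tail = y.shape[2:]
    cell = np.stack([y[groups == g].mean(axis=0) for g in levels])  # (a, b, ...)
    subj_mean = y.mean(axis=1)  # (n_subj, ...)
    a_mean = cell.mean(axis=1)  # (a, ...)   unweighted group means
    b_mean = cell.mean(axis=0)  # (b, ...)   unweighted condition means
    grand = cell.mean(axis=(0, 1))

    ss_a = n_h * b * ((a_mean - grand) ** 2).sum(axis=0)
    ss_b = n_h * a * ((b_mean - grand) ** 2).sum(axis=0)
    ss_ab = n_h * (
        (cell - a_mean[:, None] - b_mean[None, :] + grand) ** 2
    ).sum(axis=(0, 1))

    group_of = np.array([levels.index(g) for g in groups])
    subj_group_mean = np.stack([subj_mean[groups == g].mean(axis=0) for g in levels])
    ss_subj = b * ((subj_mean - subj_group_mean[group_of]) ** 2).sum(axis=0)
    resid = (
        y
        - subj_mean[:, None]
        - cell[group_of]
        + subj_group_mean[group_of][:, None]
    )
    ss_err = (resid**2).sum(axis=(0, 1))

    df_a = (a - 1.0, float(n_total - a))
    df_b = (b - 1.0, float((n_total - a) * (b - 1)))
    df_ab = ((a - 1.0) * (b - 1.0), float((n_total - a) * (b - 1)))

    f_a, p_a, e_a = _safe_f(ss_a, df_a[0], ss_subj, df_a[1])
    f_b, p_b, e_b = _safe_f(ss_b, df_b[0], ss_err, df_b[1])
    f_ab, p_ab, e_ab = _safe_f(ss_ab, df_ab[0], ss_err, df_ab[1])

    def fin(x):
        x = np.asarray(x)
        return x[..., 0] if squeeze and x.ndim and x.shape[-1] == 1 else x

    return MixedAnovaResult(
        f_between=fin(f_a),
        f_within=fin(f_b),
        f_interaction=fin(f_ab),
        p_between=fin(p_a),
        p_within=fin(p_b),
        p_interaction=fin(p_ab),
        df_between=df_a,
        df_within=df_b,
        df_interaction=df_ab,
        eta_between=fin(e_a),
        eta_within=fin(e_b),
        eta_interaction=fin(e_ab),
    )


def oneway_anova(values: np.ndarray, groups: np.ndarray):
    """Classical one-way between-subjects ANOVA (used by gatekept post-hocs).

    Returns (F, p, ms_error, df_error, group means, group sizes, levels).
    """
    y = np.asarray(values, float)
    groups = np.asarray(groups)
    levels = [g for i, g in enumerate(groups) if g not in groups[:i]]
    n_g = np.array([(groups == g).sum() for g in levels])
    means = np.array([y[groups == g].mean() for g in levels])
    grand = y.mean()
    ss_between = float((n_g * (means - grand) ** 2).sum())
    ss_within = float(sum(((y[groups == g] - m) ** 2).sum() for g, m in zip(levels, means)))
    df1, df2 = len(levels) - 1, len(y) - len(levels)
    ms_err = ss_within / df2
    if ms_err == 0:
        f, p = (0.0, 1.0) if ss_between == 0 else (np.inf, 0.0)
    else:
        f = ss_between / df1 / ms_err
        p = float(stats.f.sf(f, df1, df2))
    return f, p, ms_err, df2, means, n_g, levels
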