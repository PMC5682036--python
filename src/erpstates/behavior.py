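"""Behavioral arm: YES/NO appraisal scoring, signal-detection d′, and the
expertise × transgression mixed ANOVA with Bonferroni contrasts.

Regular endings (R) are the noise class; transgressed endings are signal.
Detecting a transgression means answering NO, so hits are NO responses to a
transgressed ending and false alarms are NO responses to R.  Extreme rates
(0 or 1) are replaced by the 1/(2N) rule before the z-transform, which keeps
d′ finite at ceiling; a log-linear correction is available as an option.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .anova import mixed_anova
from .types import StatTable, StudyDesign

logger = logging.getLogger("erpstates")

NOISE_CONDITION = "R"


def dprime(
    hits: int,
    n_signal: int,
    fas: int,
    n_noise: int,
    correction: str = "1/2N",
) -> float:
    """Sensitivity d′ = z(hit rate) − z(false-alarm rate), equal-variance model.

    Rates of exactly 0 or 1 are pulled in by 1/(2N) (or, with
    ``correction="loglinear"``, all counts are shifted by 0.5).  Interior rates
    are used exactly as observed.
    """
    if n_signal <= 0 or n_noise <= 0:
        raise ValueError("need at least one signal and one noise trial")
    if correction == "loglinear":
        h = (hits + 0.5) / (n_signal + 1.0)
        f = (fas + 0.5) / (n_noise + 1.0)
    else:
        h = hits / n_signal
        f = fas / n_noise
        if h == 0.0:
            h = 1.0 / (2 * n_signal)
        elif h == 1.0:
            h = 1.0 - 1.0 / (2 * n_signal)
        if f == 0.0:
            f = 1.0 / (2 * n_noise)
        elif f == 1.0:
            f = 1.0 - 1.0 / (2 * n_noise)
    return float(stats.norm.ppf(h) - stats.norm.ppf(f))


def score_responses(trials: pd.DataFrame, design: StudyDesign, correction: str = "1/2N") -> pd.DataFrame:
    """Score trial-level YES/NO responses into a per-subject behavioral table.

    ``trials`` columns: subject_id, group, condition, response ("YES"/"NO").
    Correct answers are YES to R and NO to a transgression.  Returns one row
    per subject with per-condition counts, percent correct, and d′ for each
    transgression (false alarms taken from the shared R trials).
    """
    known = set(design.conditions)
    bad = set(trials["condition"].unique()) - known
    if bad:
        raise ValueError(f"unknown condition label(s): {sorted(bad)}")
    transgressions = [c for c in design.conditions if c != NOISE_CONDITION]
    rows = []
    for (subj, group), sub in trials.groupby(["subject_id", "group"], sort=False):
        row: dict = {"subject_id": subj, "group": group}
        counts = {}
        for cond in design.conditions:
            cond_trials = sub[sub["condition"] == cond]
            n = len(cond_trials)
            n_yes = int((cond_trials["response"] == "YES").sum())
            counts[cond] = (n, n_yes)
            correct = n_yes if cond == NOISE_CONDITION else n - n_yes
            row[f"n_{cond}"] = n
            row[f"yes_{cond}"] = n_yes
            row[f"pc_{cond}"] = correct / n if n else np.nan
        n_noise, yes_noise = counts[NOISE_CONDITION]
        fas = n_noise - yes_noise  # NO responses to R
        row["fa_count"] = fas
        for cond in transgressions:
            n_sig, n_yes = counts[cond]
            hits = n_sig - n_yes  # NO responses to the transgression
            row[f"hits_{cond}"] = hits
            row[f"dprime_{cond}"] = dprime(hits, n_sig, fas, n_noise, correction=correction)
        rows.append(row)
    return pd.DataFrame(rows)


def dprime_anova(table: pd.DataFrame, design: StudyDesign) -> StatTable:
    """Mixed ANOVA on d′: expertise (between) × transgression (within).

    Reports F, df, p and partial η² = SS_effect / (SS_effect + SS_error) for
    both main effects and the interaction.
    """
    transgressions = [c for c in design.conditions if c != NOISE_CONDITION]
    cols = [f"dprime_{c}" for c in transgressions]
    if any(c not in table.columns for c in cols) or table[cols].isna().any().any():
        raise ValueError("every subject needs a d′ for every transgression")
    values = table[cols].to_numpy(float)
    groups = table["group"].to_numpy()
    res = mixed_anova(values, groups)
    out = StatTable()
    for name, label in [("between", "Expertise"), ("within", "Transgression"),
                        ("interaction", "Expertise x Transgression")]:
        eff = res.effect(name)
        out.add(
            label, "F", float(eff["F"]), df1=eff["df"][0], df2=eff["df"][1],
            p=float(eff["p"]), effect_size=float(eff["eta_p2"]),
        )
    return out


def group_contrasts(table: pd.DataFrame, design: StudyDesign) -> StatTable:
    """Bonferroni-corrected contrasts: independent t between groups per
    transgression, and paired t between transgressions per group."""
    transgressions = [c for c in design.conditions if c != NOISE_CONDITION]
    out = StatTable()
    n_pairs = len(design.groups) * (len(design.groups) - 1) // 2
    for cond in transgressions:
        col = f"dprime_{cond}"
        for i in range(len(design.groups)):
            for j in range(i + 1, len(design.groups)):
                gi, gj = design.groups[i], design.groups[j]
                xi = table[table["group"] == gi][col].to_numpy(float)
                xj = table[table["group"] == gj][col].to_numpy(float)
                if len(xi) < 2 or len(xj) < 2:
                    raise ValueError("need at least 2 subjects per group")
                t, p = _safe_t(lambda: stats.ttest_ind(xi, xj, equal_var=True))
                out.add(
                    f"{cond}|{gi} vs {gj}", "t", t,
                    df1=len(xi) + len(xj) - 2, p=min(1.0, p * n_pairs),
                    correction=f"bonferroni{n_pairs}",
                )
    if len(transgressions) == 2:
        c1, c2 = transgressions
        n_groups = len(design.groups)
        for g in design.groups:
            sub = table[table["group"] == g]
            x1 = sub[f"dprime_{c1}"].to_numpy(float)
            x2 = sub[f"dprime_{c2}"].to_numpy(float)
            t, p = _safe_t(lambda: stats.ttest_rel(x2, x1))
            out.add(
                f"{g}|{c2} vs {c1} (paired)", "t", t, df1=len(x1) - 1,
                p=min(1.0, p * n_groups), correction=f"bonferroni{n_groups}",
            )
    return out


def _safe_t(call) -> tuple[float, float]:
    """Run a scipy t-test, mapping degenerate variance to t=0, p=1."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = call()
    if not (np.isfinite(t) and np.isfinite(p)):
        logger.warning("degenerate variance in t-test: reporting p = 1")
        return 0.0, 1.0
    return float(t), float(p)
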