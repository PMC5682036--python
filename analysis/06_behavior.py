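"""Behavioral arm: score the YES/NO appraisals, compute per-subject d′ for
both transgressions, and run the expertise × transgression mixed ANOVA with
Bonferroni contrasts and paired simple effects."""

import pandas as pd

from common import RESULTS, SCRATCH, ensure_dirs
from erpstates.behavior import dprime_anova, group_contrasts, score_responses
from erpstates.io import write_stats
from erpstates.simulate import default_design

ensure_dirs()
design = default_design()
trials = pd.read_csv(SCRATCH / "behavior_trials.tsv", sep="\t")
table = score_responses(trials, design)
table.to_csv(RESULTS / "behavioral_table.tsv", sep="\t", index=False)

anova = dprime_anova(table, design)
write_stats(anova, RESULTS / "behavior_anova.tsv")
contrasts = group_contrasts(table, design)
write_stats(contrasts, RESULTS / "behavior_contrasts.tsv")

means = table.groupby("group")[["dprime_Tsub", "dprime_Tapp"]].agg(["mean", "std"]).round(2)
means.to_csv(RESULTS / "behavior_group_means.tsv", sep="\t")
print(means)
for rec in anova:
    print(f"{rec['effect']}: F({rec['df1']:.0f},{rec['df2']:.0f}) = {rec['value']:.1f}, "
          f"p = {rec['p']:.2e}, partial η² = {rec['effect_size']:.3f}")
n_sig = sum(r["p"] < 0.05 for r in contrasts)
print(f"{n_sig}/{len(contrasts)} Bonferroni-corrected contrasts significant")
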