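"""Pointwise between-group waveform statistics at two midline-proxy
electrodes: pooled-variance t at every frame, Bonferroni 3 (the pairwise group
contrasts), runs of ≥28 ms (7 frames) reported."""

import pandas as pd

from common import RESULTS, ensure_dirs, load_evokeds
from erpstates.simulate import default_design
from erpstates.waveform import min_frames_for, pointwise_runs

ensure_dirs()
design = default_design()
evokeds = load_evokeds()
# the two electrodes closest to the vertex stand in for Fz/Cz
montage_labels = evokeds[0].labels
electrodes = [montage_labels[0], montage_labels[1]]

rows = []
for cond in design.conditions:
    cell = {
        g: [e for e in evokeds if e.group == g and e.condition == cond]
        for g in design.groups
    }
    for electrode in electrodes:
        for i in range(len(design.groups)):
            for j in range(i + 1, len(design.groups)):
                ga, gb = design.groups[i], design.groups[j]
                for run in pointwise_runs(
                    cell[ga], cell[gb], electrode,
                    min_frames=min_frames_for(28.0, 250.0),
                    contrast=f"{ga} vs {gb}", condition=cond,
                ):
                    rows.append(vars(run))

table = pd.DataFrame(
    rows, columns=["electrode", "contrast", "condition", "start_ms", "end_ms", "mean_t"]
)
table.to_csv(RESULTS / "waveform_runs.tsv", sep="\t", index=False)
print(f"{len(table)} significant runs (≥28 ms) across "
      f"{len(electrodes)} electrodes × 3 contrasts × 3 conditions")
if len(table):
    span = table.assign(length=table.end_ms - table.start_ms)
    print(span.groupby("condition")[["start_ms", "end_ms", "length"]].mean().round(0))
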