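"""Microstate analysis: joint segmentation of the 9 grand means over 0–750 ms,
model-order selection (CV + Krzanowski–Lai), back-fitting of the winning maps
to every individual ERP over 295–480 ms, and nonparametric duration tests."""

import numpy as np
import pandas as pd

from common import RESULTS, SCRATCH, SEED, ensure_dirs, load_evokeds
from erpstates.io import write_stats
from erpstates.microstate import (
    choose_k,
    duration_table,
    duration_tests,
    segmentation_criteria,
)
from erpstates.simulate import default_design, grand_means

ensure_dirs()
design = default_design()
evokeds = load_evokeds()
cells = grand_means(evokeds)

criteria, fits = segmentation_criteria(cells, range(2, 13), n_restarts=50, seed=SEED)
k_opt, table = choose_k(criteria)
model, seqs = fits[k_opt]
print(f"selected k = {k_opt}; global explained variance {model.gev * 100:.2f}%")
table.to_csv(RESULTS / "microstate_selection.tsv", sep="\t", index=False)

maps_frame = pd.DataFrame(model.maps.T, columns=[f"map{i + 1}" for i in range(model.k)])
maps_frame.insert(0, "channel", evokeds[0].labels)
maps_frame.to_csv(RESULTS / "microstate_maps.tsv", sep="\t", index=False)

durations = duration_table(model, evokeds, window=(295.0, 480.0))
durations.to_csv(RESULTS / "microstate_durations.tsv", sep="\t", index=False)

stats_table = duration_tests(durations, design)
write_stats(stats_table, RESULTS / "microstate_duration_stats.tsv")
n_sig = sum(r["statistic"] == "MannWhitney-U" for r in stats_table)
print(f"duration tests: {len(stats_table)} records, {n_sig} gatekept pairwise contrasts")

# template recovery against ground truth
truth = np.load(SCRATCH / "templates.npy")
if model.k == truth.shape[0]:
    corr = np.abs(np.corrcoef(np.vstack([model.maps, truth]))[: model.k, model.k:])
    print("per-template recovery |r|:", np.round(corr.max(axis=0), 3))

summary = (
    durations[durations["map"] >= 0]
    .groupby(["group", "condition", "map"])["duration_ms"]
    .mean()
    .unstack("map")
    .round(1)
)
summary.to_csv(RESULTS / "microstate_duration_means.tsv", sep="\t")
print(summary)
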