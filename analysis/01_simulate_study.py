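"""Generate the synthetic cohort: 3 expertise groups (19/20/20) × 3 closure
conditions, 204 channels, 70 trials/condition at single-trial SNR 0.5, with
7 ground-truth microstate templates and behavioral responses at the study's
sensitivity levels.  Subject ERPs are produced at the evoked level (noise
scaled by √n_trials), which is what every later stage consumes."""

import json

import numpy as np

from common import RESULTS, SCRATCH, SEED, ensure_dirs, save_evokeds
from erpstates.forward import HeadModel, build_grid, fit_sphere
from erpstates.io import write_montage
from erpstates.simulate import (
    SimulationSpec,
    generate_montage,
    generate_templates,
    resolve_noise_sd,
    simulate_behavior,
    simulate_study_evoked,
)

ensure_dirs()
rng = np.random.default_rng(SEED)

montage = generate_montage(204, seed=rng)
write_montage(montage, SCRATCH / "montage.sfp")
(SCRATCH / "labels.txt").write_text(" ".join(montage.labels))
fit_sphere(montage)
head = HeadModel.from_montage(montage)
grid = build_grid(head)
templates, sources = generate_templates(7, montage, grid, head, seed=rng)
np.save(SCRATCH / "templates.npy", templates)

spec = SimulationSpec()
evokeds, truth = simulate_study_evoked(spec, templates, montage, seed=rng, sources=sources)
save_evokeds(evokeds)

trials = simulate_behavior(spec.design, seed=rng)
trials.to_csv(SCRATCH / "behavior_trials.tsv", sep="\t", index=False)

payload = {
    "seed": SEED,
    "noise_sd_uV": truth.noise_sd,
    "window_ms": truth.window,
    "durations_ms": {f"{g}|{c}": d for (g, c), d in truth.durations.items()},
    "sources": truth.sources,
}
(SCRATCH / "ground_truth.json").write_text(json.dumps(payload, indent=1))

print(f"cohort: {len(evokeds)} subject-condition ERPs "
      f"({spec.design.n_subjects} subjects × {len(spec.design.conditions)} conditions)")
print(f"single-trial noise sd {resolve_noise_sd(spec, templates):.2f} µV "
      f"(SNR {spec.target_snr}); {grid.n_nodes} source nodes")
print(f"behavior: {len(trials)} trials written")
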