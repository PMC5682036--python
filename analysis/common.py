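"""Shared paths and loaders for the numbered analysis drivers.

Big intermediates (evoked stacks, lead fields, CD maps) live under scratch/;
only text tables go to results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"
SEED = 2026


def ensure_dirs():
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)


def save_evokeds(evokeds):
    data = np.stack([ev.data for ev in evokeds]).astype(np.float32)
    np.save(SCRATCH / "evokeds.npy", data)
    meta = pd.DataFrame(
        {
            "subject_id": [ev.subject_id for ev in evokeds],
            "group": [ev.group for ev in evokeds],
            "condition": [ev.condition for ev in evokeds],
        }
    )
    meta.to_csv(SCRATCH / "evokeds_meta.tsv", sep="\t", index=False)


def load_evokeds():
    from erpstates.types import Evoked

    data = np.load(SCRATCH / "evokeds.npy").astype(float)
    meta = pd.read_csv(SCRATCH / "evokeds_meta.tsv", sep="\t")
    labels = (SCRATCH / "labels.txt").read_text().split()
    return [
        Evoked(
            data=data[i],
            sfreq=250.0,
            t0_index=50,
            labels=labels,
            average_referenced=True,
            baseline_corrected=True,
            subject_id=row.subject_id,
            group=row.group,
            condition=row.condition,
        )
        for i, row in enumerate(meta.itertuples())
    ]


def load_montage():
    from erpstates.forward import fit_sphere
    from erpstates.io import read_montage

    montage = read_montage(SCRATCH / "montage.sfp")
    fit_sphere(montage)
    return montage
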