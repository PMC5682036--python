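"""File I/O: electrode montages (.sfp), epoch fixtures, evoked fixtures, TSV tables.

The native fixture format pairs one matrix file (``.npy``) with a JSON sidecar
holding the metadata (sampling rate, labels, events or epoch annotations), so
recordings can be exchanged without inventing a binary container.  EDF+ import
is available through :mod:`mne` when that package is installed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import STAT_COLUMNS, ElectrodeMontage, EpochSet, Evoked, FormatError, StatTable

logger = logging.getLogger("erpstates")

EPOCH_START_MS = -200.0
EPOCH_END_MS = 750.0


# ---------------------------------------------------------------------------
# montage

def read_montage(path: str | Path) -> ElectrodeMontage:
    """Read electrode positions from an .sfp file (``label x y z`` per line, mm).

    Fiducial rows (labels starting with ``Fid``) are skipped.  A JSON montage
    (``{"labels": [...], "positions": [[x,y,z], ...]}``) is accepted as well.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        return ElectrodeMontage(list(payload["labels"]), np.asarray(payload["positions"], float))
    labels: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise FormatError(f"{path}:{lineno}: expected 'label x y z'")
        label = parts[0]
        if label.startswith("Fid"):
            continue
        if label in labels:
            raise FormatError(f"{path}:{lineno}: duplicate channel label {label!r}")
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric coordinate") from None
        labels.append(label)
    return ElectrodeMontage(labels, np.asarray(rows, float))


def write_montage(montage: ElectrodeMontage, path: str | Path) -> None:
    path = Path(path)
    lines = [
        f"{lab}\t{float(x)!r}\t{float(y)!r}\t{float(z)!r}"
        for lab, (x, y, z) in zip(montage.labels, montage.positions)
    ]
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# epochs

def _sidecar_path(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("") if path.suffix in {".json", ".npy"} else path
    return stem.with_suffix(".npy"), stem.with_suffix(".json")


def write_epochs(epochs: EpochSet, path: str | Path) -> None:
    """Write an epoched recording as matrix + JSON sidecar (round-trip exact)."""
    mat_path, json_path = _sidecar_path(Path(path))
    np.save(mat_path, epochs.data)
    meta = {
        "format": "epoched",
        "subject_id": epochs.subject_id,
        "group": epochs.group,
        "condition": epochs.condition,
        "sfreq": epochs.sfreq,
        "t0_index": int(epochs.t0_index),
        "labels": epochs.labels,
        "kept_mask": [bool(v) for v in epochs.kept_mask],
        "n_trials": int(epochs.n_trials),
        "n_channels": int(epochs.n_channels),
        "n_samples": int(epochs.n_samples),
    }
    json_path.write_text(json.dumps(meta))


def read_epochs(path: str | Path, expect_sfreq: float | None = None) -> EpochSet:
    """Read the fixture format: either an epoched matrix or a continuous one.

    A continuous sidecar carries ``events`` (sample indices of stimulus onsets);
    epochs are cut −200…750 ms around each event.  Events whose window extends
    past the record are dropped with a logged warning.
    """
    mat_path, json_path = _sidecar_path(Path(path))
    meta = json.loads(json_path.read_text())
    data = np.load(mat_path)
    sfreq = float(meta["sfreq"])
    if expect_sfreq is not None and sfreq != expect_sfreq:
        raise FormatError(f"sampling rate mismatch: sidecar {sfreq}, expected {expect_sfreq}")
    common = dict(
        subject_id=meta.get("subject_id", ""),
        group=meta.get("group", ""),
        condition=meta.get("condition", ""),
        sfreq=sfreq,
        labels=meta.get("labels"),
    )
    if meta.get("format", "epoched") == "epoched":
        if data.ndim != 3:
            raise FormatError("epoched fixture matrix must be 3D")
        kept = meta.get("kept_mask")
        return EpochSet(
            data=data,
            t0_index=int(meta["t0_index"]),
            kept_mask=None if kept is None else np.asarray(kept, bool),
            **common,
        )
    if data.ndim != 2:
        raise FormatError("continuous fixture matrix must be channels × samples")
    pre = round(-EPOCH_START_MS / 1000.0 * sfreq)
    post = int(np.floor(EPOCH_END_MS / 1000.0 * sfreq))
    trials = []
    for ev in meta["events"]:
        ev = int(ev)
        if ev - pre < 0 or ev + post >= data.shape[1]:
            logger.warning("event at sample %d: epoch window outside record, dropped", ev)
            continue
        trials.append(data[:, ev - pre : ev + post + 1])
    if not trials:
        raise FormatError("no complete epochs in recording")
    return EpochSet(data=np.stack(trials), t0_index=pre, **common)


def read_epochs_edf(edf_path: str | Path, events: np.ndarray, **meta) -> EpochSet:
    """Cut epochs from an EDF+ recording (requires :mod:`mne`)."""
    import mne  # local import: EDF support is optional

    raw = mne.io.read_raw_edf(str(edf_path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # V → µV
    sfreq = float(raw.info["sfreq"])
    tmp_meta = {
        "format": "continuous",
        "sfreq": sfreq,
        "events": [int(e) for e in np.asarray(events).ravel()],
        "labels": list(raw.ch_names),
        **meta,
    }
    pre = round(-EPOCH_START_MS / 1000.0 * sfreq)
    post = int(np.floor(EPOCH_END_MS / 1000.0 * sfreq))
    trials = []
    for ev in tmp_meta["events"]:
        if ev - pre < 0 or ev + post >= data.shape[1]:
            logger.warning("event at sample %d: epoch window outside record, dropped", ev)
            continue
        trials.append(data[:, ev - pre : ev + post + 1])
    return EpochSet(
        subject_id=str(meta.get("subject_id", "")),
        group=str(meta.get("group", "")),
        condition=str(meta.get("condition", "")),
        sfreq=sfreq,
        data=np.stack(trials),
        t0_index=pre,
        labels=list(raw.ch_names),
    )


# ---------------------------------------------------------------------------
# evoked

def write_evoked(evoked: Evoked, path: str | Path) -> None:
    mat_path, json_path = _sidecar_path(Path(path))
    np.save(mat_path, evoked.data)
    meta = {
        "format": "evoked",
        "subject_id": evoked.subject_id,
        "group": evoked.group,
        "condition": evoked.condition,
        "sfreq": evoked.sfreq,
        "t0_index": int(evoked.t0_index),
        "n_epochs": int(evoked.n_epochs),
        "baseline_window": evoked.baseline_window,
        "average_referenced": evoked.average_referenced,
        "baseline_corrected": evoked.baseline_corrected,
        "labels": evoked.labels,
    }
    json_path.write_text(json.dumps(meta))


def read_evoked(path: str | Path) -> Evoked:
    mat_path, json_path = _sidecar_path(Path(path))
    meta = json.loads(json_path.read_text())
    bw = meta.get("baseline_window")
    return Evoked(
        data=np.load(mat_path),
        sfreq=float(meta["sfreq"]),
        t0_index=int(meta["t0_index"]),
        n_epochs=int(meta.get("n_epochs", 1)),
        baseline_window=None if bw is None else (float(bw[0]), float(bw[1])),
        average_referenced=bool(meta.get("average_referenced", False)),
        baseline_corrected=bool(meta.get("baseline_corrected", False)),
        labels=meta.get("labels"),
        subject_id=meta.get("subject_id", ""),
        group=meta.get("group", ""),
        condition=meta.get("condition", ""),
    )


# ---------------------------------------------------------------------------
# tables

def write_stats(table: StatTable, path: str | Path) -> None:
    """Write a StatTable as TSV with fixed column order, floats at 6 significant digits."""
    frame = table.to_frame()
    with open(path, "w") as fh:
        fh.write("\t".join(STAT_COLUMNS) + "\n")
        for _, row in frame.iterrows():
            cells = []
            for col in STAT_COLUMNS:
                v = row[col]
                cells.append(f"{v:.6g}" if isinstance(v, float) else str(v))
            fh.write("\t".join(cells) + "\n")


def read_stats(path: str | Path) -> StatTable:
    frame = pd.read_csv(path, sep="\t")
    if list(frame.columns) != STAT_COLUMNS:
        raise FormatError(f"unexpected stats columns in {path}")
    table = StatTable()
    for rec in frame.to_dict("records"):
        table.add(**rec)
    return table


def write_maps(maps: np.ndarray, labels: list[str], path: str | Path) -> None:
    """Microstate template maps as channel-by-map TSV."""
    maps = np.asarray(maps, float)
    frame = pd.DataFrame(maps.T, columns=[f"map{i + 1}" for i in range(maps.shape[0])])
    frame.insert(0, "channel", labels)
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_maps(path: str | Path) -> tuple[np.ndarray, list[str]]:
    frame = pd.read_csv(path, sep="\t")
    labels = frame.pop("channel").tolist()
    return frame.to_numpy(float).T, labels


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, default=_json_default))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
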