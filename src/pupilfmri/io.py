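"""File readers and writers: TSV for tabular data, NIfTI-1 for volumes
(TR in the header), JSON for reports and truth sidecars.  Naming is
BIDS-like without claiming BIDS compliance."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .design import LABELS, BoldDataset
from .task import (
    BLOCK_ORDER,
    INSTRUCTION_DURATION,
    TRIALS_PER_BLOCK,
    Block,
    Condition,
    ResponseLog,
    TaskSchedule,
    Trial,
)


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def save_bold(bold: BoldDataset, path) -> None:
    """4-D NIfTI with the TR recorded in the header."""
    img = nib.Nifti1Image(np.asarray(bold.data, np.float32), np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, bold.tr))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def load_bold(path, labels: np.ndarray | None = None, discard: int = 4) -> BoldDataset:
    img = nib.load(str(path))
    tr = float(img.header.get_zooms()[3])
    return BoldDataset(data=np.asarray(img.dataobj, np.float64), tr=tr,
                       labels=labels, discard=discard)


def save_map(arr: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(arr, np.float32), np.eye(4)), str(path))


def load_map(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, np.float64)


def save_labels(labels: np.ndarray, path, sidecar_path=None) -> None:
    nib.save(nib.Nifti1Image(np.asarray(labels, np.int16), np.eye(4)), str(path))
    if sidecar_path is not None:
        write_json({"label_codes": {name: i for i, name in enumerate(LABELS)}}, sidecar_path)


def load_labels(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, np.int64)


def write_events(schedule: TaskSchedule, path) -> None:
    write_tsv(schedule.to_events(), path)


def schedule_from_events(events: pd.DataFrame) -> TaskSchedule:
    """Rebuild a TaskSchedule from its BIDS-style events table."""
    blocks = []
    for b, grp in events.groupby("block_index", sort=True):
        grp = grp.sort_values("onset")
        condition = Condition(grp["trial_type"].iloc[0])
        if len(grp) != TRIALS_PER_BLOCK:
            raise ValueError(f"block {b} has {len(grp)} trials, expected {TRIALS_PER_BLOCK}")
        trials = tuple(
            Trial(onset=float(r.onset), letter=str(r.letter),
                  is_target=bool(r.is_target), condition=condition)
            for r in grp.itertuples()
        )
        blocks.append(Block(condition=condition,
                            instruction_onset=float(grp["onset"].iloc[0]) - INSTRUCTION_DURATION,
                            trials=trials))
    if len(blocks) != len(BLOCK_ORDER):
        raise ValueError(f"expected {len(BLOCK_ORDER)} blocks, got {len(blocks)}")
    return TaskSchedule(blocks=tuple(blocks))


def write_presses(log: ResponseLog, path) -> None:
    write_tsv(log.to_frame(), path)


def read_presses(path) -> ResponseLog:
    df = read_tsv(path)
    return ResponseLog(presses=df["press_time"].to_numpy(float))
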