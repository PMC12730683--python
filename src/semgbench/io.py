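"""Reading and writing recording CSVs and run artifacts.

Two CSV dialects are supported, one row per sample with a header:

* ``myo``: columns ``ch1..ch8, label, repetition``; labels are already the
  study class indices 0..5.
* ``ninapro``: columns ``ch1..ch12, label, repetition``; labels are NinaPro
  stimulus identifiers and are mapped to study classes on read. Rows whose
  identifier is outside the map are dropped (with the drop count logged).

Window tensors are persisted as a compressed ``.npz`` container with a JSON
sidecar for run metadata, so every number in a report traces back to a file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import DatasetProfile, GESTURE_CODES, PROFILES, Recording, WindowSet

logger = logging.getLogger(__name__)

__all__ = [
    "GestureMap",
    "NINAPRO_GESTURE_MAP",
    "read_recording",
    "write_recording",
    "select_gestures",
    "save_window_set",
    "load_window_set",
    "save_json",
]


@dataclass(frozen=True)
class GestureMap:
    """Bijective map from source gesture identifiers to study class indices.

    ``pairs`` is a tuple of (source_id, class_index) with class index 0 =
    rest (RE). Class codes follow the study order RE, AP, PI, PO, MO, AT.
    """

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        sources = [s for s, _ in self.pairs]
        classes = [c for _, c in self.pairs]
        if len(set(sources)) != len(sources) or len(set(classes)) != len(classes):
            raise ValueError("gesture map must be bijective")
        if sorted(classes) != list(range(len(classes))):
            raise ValueError("class indices must be 0..k-1")

    def as_dict(self) -> dict[int, int]:
        return dict(self.pairs)

    def class_code(self, class_index: int) -> str:
        return GESTURE_CODES[class_index]


#: NinaPro DB3 stimulus ids for the six study gestures, in class order
#: RE, AP, PI, PO, MO, AT: ids 0, 6, 13, 14, 5, 2.
NINAPRO_GESTURE_MAP = GestureMap(
    pairs=((0, 0), (6, 1), (13, 2), (14, 3), (5, 4), (2, 5))
)


def _columns(profile: DatasetProfile) -> list[str]:
    return [f"ch{i + 1}" for i in range(profile.n_channels)] + ["label", "repetition"]


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording in its dialect's CSV schema (header + one row/sample)."""
    path = Path(path)
    cols = _columns(rec.profile)
    df = pd.DataFrame(rec.samples.T, columns=cols[:-2])
    df["label"] = rec.labels
    df["repetition"] = rec.repetition
    df.to_csv(path, index=False, float_format="%.6g")
    return path


def read_recording(
    path: str | Path,
    dialect: str,
    profile: DatasetProfile,
    subject_id: str | None = None,
    gesture_map: GestureMap | None = None,
) -> Recording:
    """Read a recording CSV; the ``ninapro`` dialect maps stimulus ids to classes.

    Row order is preserved; the reader never resamples. For the ninapro
    dialect, rows with unmapped stimulus ids are dropped and counted.
    """
    path = Path(path)
    if dialect not in ("myo", "ninapro"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path)
    expected = _columns(profile)
    if "repetition" not in df.columns:
        raise ValueError(
            f"{path.name}: missing 'repetition' column; recordings without a "
            "repetition index cannot be split into train/test repetitions"
        )
    if list(df.columns) != expected:
        raise ValueError(
            f"{path.name}: expected columns {expected} "
            f"({profile.n_channels} channels + label + repetition), "
            f"got {list(df.columns)}"
        )
    labels = df["label"].to_numpy(dtype=np.int64)
    if dialect == "ninapro":
        gmap = (gesture_map or NINAPRO_GESTURE_MAP).as_dict()
        keep = np.isin(labels, list(gmap))
        dropped = int((~keep).sum())
        if dropped:
            logger.info("%s: dropped %d rows with unmapped gesture ids", path.name, dropped)
        df = df.loc[keep]
        labels = np.array([gmap[s] for s in labels[keep]], dtype=np.int64)
    samples = df[expected[:-2]].to_numpy(dtype=np.float64).T
    return Recording(
        subject_id=subject_id or path.stem,
        profile=profile,
        samples=samples,
        labels=labels,
        repetition=df["repetition"].to_numpy(dtype=np.int64),
    )


def select_gestures(rec: Recording, gesture_map: GestureMap) -> Recording:
    """Filter a source-id-labeled recording to the mapped gestures.

    Only samples whose label is a key of the map survive; surviving labels
    are re-coded to study class indices. Raises if nothing survives.
    """
    gmap = gesture_map.as_dict()
    keep = np.isin(rec.labels, list(gmap))
    if not keep.any():
        raise ValueError(
            f"no samples of {rec.subject_id} carry a mapped gesture id "
            f"(map keys: {sorted(gmap)})"
        )
    dropped = int((~keep).sum())
    if dropped:
        logger.info("%s: select_gestures dropped %d samples", rec.subject_id, dropped)
    labels = np.array([gmap[s] for s in rec.labels[keep]], dtype=np.int64)
    return Recording(
        subject_id=rec.subject_id,
        profile=rec.profile,
        samples=rec.samples[:, keep],
        labels=labels,
        repetition=rec.repetition[keep],
    )


def save_window_set(ws: WindowSet, path: str | Path) -> Path:
    """Persist a WindowSet as .npz plus a JSON metadata sidecar."""
    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    np.savez_compressed(
        path, data=ws.data, labels=ws.labels, repetitions=ws.repetitions
    )
    meta = {
        "subject_id": ws.subject_id,
        "profile": ws.profile.name,
        "n_windows": len(ws),
        "class_counts": {str(k): v for k, v in ws.class_counts().items()},
    }
    save_json(meta, path.with_suffix(".json"))
    return path


def load_window_set(path: str | Path) -> WindowSet:
    path = Path(path)
    with np.load(path) as z:
        data, labels, reps = z["data"], z["labels"], z["repetitions"]
    meta = json.loads(path.with_suffix(".json").read_text())
    return WindowSet(
        data=data,
        labels=labels,
        repetitions=reps,
        subject_id=meta["subject_id"],
        profile=PROFILES[meta["profile"]],
    )


def save_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")
    return path


def _jsonify(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")
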