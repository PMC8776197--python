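"""Readers and writers: EDF, BrainVision, event TSVs, feature tables, grids.

Generated recordings are written as 16-bit European Data Format (EDF) with a
companion tab-separated events file (onset_s, duration_s, class_id,
class_name).  Reading goes through MNE for both EDF and BrainVision Core
(.vhdr) files; the events TSV dialect written here is also accepted as the
annotation source.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from eegscape.errors import DataError
from eegscape.features import FeatureTensor
from eegscape.preprocess import Recording
from eegscape.simulate import CLASS_NAMES

# EDF physical range (uV); signals are clipped to it on write.
_PHYS_MIN, _PHYS_MAX = -1000.0, 1000.0
_DIG_MIN, _DIG_MAX = -32768, 32767


def _pad(s: str, n: int) -> bytes:
    b = s.encode("ascii")[:n]
    return b + b" " * (n - len(b))


def write_edf(rec: Recording, path) -> Path:
    """Write a Recording as 16-bit EDF (1-s data records, fixed start stamp).

    The sampling rate must be an integer; the signal is zero-padded to a
    whole number of seconds.  Values are clipped to +/-1000 uV and quantized
    to the 16-bit grid (step ~0.03 uV).
    """
    path = Path(path)
    rate = rec.rate_hz
    if abs(rate - round(rate)) > 1e-9:
        raise DataError("EDF writer requires an integer sampling rate")
    rate = int(round(rate))
    n_ch, n = rec.samples.shape
    n_rec = int(np.ceil(n / rate))
    data = np.zeros((n_ch, n_rec * rate))
    data[:, :n] = np.clip(rec.samples, _PHYS_MIN, _PHYS_MAX)
    scale = (_DIG_MAX - _DIG_MIN) / (_PHYS_MAX - _PHYS_MIN)
    digital = np.round((data - _PHYS_MIN) * scale + _DIG_MIN).astype("<i2")

    header_bytes = 256 * (1 + n_ch)
    with open(path, "wb") as f:
        f.write(_pad("0", 8))
        f.write(_pad("X X X X", 80))                       # patient id (anonymous)
        f.write(_pad("Startdate 01-JAN-2000 X X X", 80))   # recording id
        f.write(_pad("01.01.00", 8))
        f.write(_pad("00.00.00", 8))
        f.write(_pad(str(header_bytes), 8))
        f.write(_pad("", 44))
        f.write(_pad(str(n_rec), 8))
        f.write(_pad("1", 8))
        f.write(_pad(str(n_ch), 4))
        for ch in rec.channel_labels:
            f.write(_pad(ch, 16))
        for _ in rec.channel_labels:
            f.write(_pad("AgAgCl electrode", 80))
        for _ in rec.channel_labels:
            f.write(_pad("uV", 8))
        for _ in rec.channel_labels:
            f.write(_pad(str(_PHYS_MIN), 8))
        for _ in rec.channel_labels:
            f.write(_pad(str(_PHYS_MAX), 8))
        for _ in rec.channel_labels:
            f.write(_pad(str(_DIG_MIN), 8))
        for _ in rec.channel_labels:
            f.write(_pad(str(_DIG_MAX), 8))
        for _ in rec.channel_labels:
            f.write(_pad("", 80))
        for _ in rec.channel_labels:
            f.write(_pad(str(rate), 8))
        for _ in rec.channel_labels:
            f.write(_pad("", 32))
        for r in range(n_rec):
            f.write(digital[:, r * rate:(r + 1) * rate].tobytes())
    return path


def write_events_tsv(rec: Recording, path) -> Path:
    """Companion events file: onset_s, duration_s, class_id, class_name."""
    path = Path(path)
    df = pd.DataFrame(rec.annotations, columns=["onset_s", "duration_s", "class_id"])
    df["class_name"] = df["class_id"].map(CLASS_NAMES)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_events_tsv(path) -> list[tuple[float, float, int]]:
    path = Path(path)
    if not path.exists():
        raise DataError(f"events file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    for col in ("onset_s", "duration_s", "class_id"):
        if col not in df.columns:
            raise DataError(f"events file {path} lacks column {col!r}")
    return [(float(r.onset_s), float(r.duration_s), int(r.class_id)) for r in df.itertuples()]


def read_recording(path, events_path=None, subject_id: int = 0) -> Recording:
    """Read an EDF (.edf) or BrainVision (.vhdr) recording through MNE.

    Annotations come from the events TSV when given (defaulting to the
    sibling ``<stem>_events.tsv`` if present), otherwise from any in-file
    annotations/markers whose description parses as an integer class id.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise DataError(f"recording not found: {path}")
    suffix = path.suffix.lower()
    if suffix == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif suffix == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    else:
        raise DataError(f"unsupported recording format: {path.name}")

    data = raw.get_data() * 1e6  # MNE returns volts
    annotations: list[tuple[float, float, int]] = []
    if events_path is None:
        sibling = path.with_name(path.stem + "_events.tsv")
        events_path = sibling if sibling.exists() else None
    if events_path is not None:
        annotations = read_events_tsv(events_path)
    else:
        for ann in raw.annotations:
            desc = str(ann["description"]).strip().removeprefix("Stimulus/S").strip()
            try:
                cls = int(desc)
            except ValueError:
                continue
            annotations.append((float(ann["onset"]), float(ann["duration"]), cls))
    return Recording(samples=data, rate_hz=float(raw.info["sfreq"]),
                     channel_labels=list(raw.ch_names), annotations=annotations,
                     subject_id=subject_id)


# ---------------------------------------------------------------------------
# feature tensors

_MAX_DIM = 145


def write_feature_tensor(tensor: FeatureTensor, path) -> Path:
    """Long-format TSV (one row per epoch per family per band) plus a metadata sidecar."""
    path = Path(path)
    rows = []
    for (fam, band), X in sorted(tensor.values.items()):
        for i in range(X.shape[0]):
            meta = tensor.index.iloc[i]
            row = {"subject_id": tensor.subject_id,
                   "epoch_index": int(meta["epoch_index"]),
                   "class_id": int(meta["class_id"]),
                   "video_instance": int(meta["video_instance"]),
                   "family": fam, "band": band}
            row.update({f"v{j + 1}": X[i, j] for j in range(X.shape[1])})
            rows.append(row)
    cols = (["subject_id", "epoch_index", "class_id", "video_instance", "family", "band"]
            + [f"v{j + 1}" for j in range(_MAX_DIM)])
    pd.DataFrame(rows).reindex(columns=cols).to_csv(path, sep="\t", index=False)
    meta_path = path.with_suffix(".meta.json")
    meta_path.write_text(json.dumps(tensor.metadata, indent=2))
    return path


def read_feature_tensor(path) -> FeatureTensor:
    path = Path(path)
    if not path.exists():
        raise DataError(f"feature table not found: {path}")
    df = pd.read_csv(path, sep="\t")
    subject_id = int(df["subject_id"].iloc[0])
    vcols = [c for c in df.columns if c.startswith("v") and c[1:].isdigit()]
    values = {}
    index = None
    for (fam, band), sub in df.groupby(["family", "band"], sort=False):
        sub = sub.sort_values("epoch_index")
        X = sub[vcols].to_numpy(dtype=float)
        X = X[:, ~np.isnan(X).all(axis=0)]  # trim padding columns
        values[(fam, band)] = X
        if index is None:
            index = sub[["epoch_index", "class_id", "video_instance"]].reset_index(drop=True)
    meta_path = path.with_suffix(".meta.json")
    metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return FeatureTensor(subject_id=subject_id, index=index, values=values, metadata=metadata)


# ---------------------------------------------------------------------------
# evaluation grids

def write_grid(grid, out_dir, prefix: str = "grid") -> dict[str, Path]:
    """Write aggregate, per-cell, per-fold, and Table-style matrices as TSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    agg = grid.aggregate()
    cells = grid.to_frame()
    folds = grid.fold_frame()

    pivot = agg.copy()
    pivot["formatted"] = pivot.apply(
        lambda r: f"{100 * r.mean_accuracy:.2f} ± {100 * r.sd_accuracy:.2f}"
        if np.isfinite(r.sd_accuracy) else f"{100 * r.mean_accuracy:.2f}", axis=1)
    table = pivot.pivot_table(index=["family", "classifier"], columns="band",
                              values="formatted", aggfunc="first", sort=False)

    paths = {
        "aggregate": out_dir / f"{prefix}_aggregate.tsv",
        "cells": out_dir / f"{prefix}_cells.tsv",
        "folds": out_dir / f"{prefix}_folds.tsv",
        "table": out_dir / f"{prefix}_table.tsv",
    }
    agg.to_csv(paths["aggregate"], sep="\t", index=False, float_format="%.6f")
    cells.to_csv(paths["cells"], sep="\t", index=False, float_format="%.6f")
    folds.to_csv(paths["folds"], sep="\t", index=False, float_format="%.6f")
    table.to_csv(paths["table"], sep="\t")
    return paths


def read_grid_aggregate(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"grid file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    needed = {"family", "band", "classifier", "mean_accuracy"}
    if not needed <= set(df.columns):
        raise DataError(f"malformed grid file {path}: needs columns {sorted(needed)}")
    return df
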