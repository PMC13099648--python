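"""Tabular and matrix IO.

Canonical on-disk formats: TSV (UTF-8, header row with units where
applicable) for time series, feature tables and event tables; MatrixMarket
coordinate (1-based) plus genes.tsv / barcodes.tsv / cellmeta.tsv for count
matrices; BED-like half-open intervals for detected events; JSON sidecars
for recording metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .genes import CountMatrix
from .lfp import IisEvent, LfpRecording

__all__ = [
    "write_timeseries", "read_timeseries",
    "write_events", "read_events",
    "write_mtx", "read_mtx",
    "write_features", "read_features",
]


def write_timeseries(path, rec: LfpRecording) -> None:
    """TSV (time_s, ch1..chN µV) + JSON metadata sidecar."""
    path = Path(path)
    t = np.arange(rec.n_samples) / rec.fs_hz
    cols = {"time_s": t}
    for i in range(rec.n_channels):
        cols[f"ch{i + 1}_uv"] = rec.samples[i]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
    sidecar = {
        "fs_hz": rec.fs_hz,
        "channel_meta": rec.channel_meta,
        "activity_mask_runs": _mask_runs(rec.activity_mask, rec.fs_hz),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def _mask_runs(mask, fs):
    if mask is None:
        return None
    d = np.diff(mask.astype(np.int8))
    starts = (np.flatnonzero(d == 1) + 1).tolist()
    stops = (np.flatnonzero(d == -1) + 1).tolist()
    if mask[0]:
        starts = [0] + starts
    if mask[-1]:
        stops = stops + [mask.size]
    return [[s / fs, e / fs] for s, e in zip(starts, stops)]


def read_timeseries(path) -> LfpRecording:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "time_s" not in df.columns or df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns time_s, ch1..chN")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        side = json.loads(sidecar_path.read_text())
        fs = side["fs_hz"]
        channel_meta = side.get("channel_meta") or []
        mask_runs = side.get("activity_mask_runs")
    else:
        t = df["time_s"].to_numpy()
        fs = 1.0 / np.median(np.diff(t))
        channel_meta, mask_runs = [], None
    samples = df.drop(columns="time_s").to_numpy().T
    mask = None
    if mask_runs is not None:
        mask = np.zeros(samples.shape[1], dtype=bool)
        for a, b in mask_runs:
            mask[int(a * fs) : int(b * fs)] = True
    return LfpRecording(samples, fs, channel_meta, mask)


def write_events(path, events: list[IisEvent]) -> None:
    """BED-like TSV: channel, onset_s, offset_s, peak_sd, polarity."""
    rows = [
        {"channel": e.channel, "onset_s": e.onset_s,
         "offset_s": e.onset_s + e.duration_ms * 1e-3,
         "peak_sd": e.peak_amplitude_sd, "polarity": e.polarity}
        for e in events
    ]
    pd.DataFrame(rows, columns=["channel", "onset_s", "offset_s", "peak_sd",
                                "polarity"]).to_csv(path, sep="\t", index=False)


def read_events(path) -> list[IisEvent]:
    df = pd.read_csv(path, sep="\t")
    req = {"channel", "onset_s", "offset_s", "peak_sd", "polarity"}
    if not req.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(req)}")
    return [
        IisEvent(
            onset_s=r.onset_s,
            duration_ms=(r.offset_s - r.onset_s) * 1e3,
            peak_amplitude_sd=r.peak_sd,
            polarity=int(r.polarity),
            channel=int(r.channel),
        )
        for r in df.itertuples()
    ]


def write_mtx(prefix, cm: CountMatrix, meta: pd.DataFrame | None = None) -> None:
    """matrix.mtx + genes.tsv + barcodes.tsv (+ cellmeta.tsv) under prefix/."""
    prefix = Path(prefix)
    prefix.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(str(prefix / "matrix.mtx"), cm.counts.tocoo(), field="integer")
    (prefix / "genes.tsv").write_text("\n".join(cm.genes) + "\n")
    (prefix / "barcodes.tsv").write_text("\n".join(cm.barcodes) + "\n")
    if meta is not None:
        meta.to_csv(prefix / "cellmeta.tsv", sep="\t", index=False)


def read_mtx(prefix) -> tuple[CountMatrix, pd.DataFrame | None]:
    prefix = Path(prefix)
    try:
        mat = sio.mmread(str(prefix / "matrix.mtx"))
    except Exception as exc:  # noqa: BLE001 - normalise parser errors
        raise ValueError(f"{prefix / 'matrix.mtx'}: malformed MatrixMarket file: {exc}")
    genes = (prefix / "genes.tsv").read_text().strip().split("\n")
    barcodes = (prefix / "barcodes.tsv").read_text().strip().split("\n")
    meta = None
    meta_path = prefix / "cellmeta.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t")
    return CountMatrix(sp.csr_matrix(mat), genes, barcodes), meta


def write_features(path, features: pd.DataFrame) -> None:
    """One tidy row per cell: ids, grouping labels, then feature columns."""
    features.to_csv(path, sep="\t", index=False)


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
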