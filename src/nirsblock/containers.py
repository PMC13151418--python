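"""On-disk scan containers.

One directory per participant:

* ``intensity.csv`` — long-format table with columns ``time_s, channel_id,
  wavelength_nm, intensity``;
* ``meta.json`` — sidecar with design events, probe layout, sampling rate,
  seed, and (for synthetic scans) ground-truth block amplitudes.

Hemoglobin series produced by preprocessing use the same style
(``hb.csv`` with ``time_s, channel_id, hb_type, value`` plus a sidecar).
An optional single-file HDF5 variant mirrors the same schema.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from nirsblock.core import (
    HB_TYPES,
    BlockDesign,
    HbSeries,
    ProbeLayout,
    RawIntensityScan,
)

__all__ = [
    "save_scan",
    "load_scan",
    "save_hb",
    "load_hb",
    "save_scan_hdf5",
    "load_scan_hdf5",
]


def _scan_meta(scan: RawIntensityScan) -> dict:
    return {
        "participant": scan.participant,
        "sampling_rate": scan.sampling_rate,
        "wavelengths_nm": list(scan.wavelengths),
        "layout": {
            "channels": scan.layout.to_records(),
            "source_detector_distance_cm": scan.layout.source_detector_distance,
        },
        "design": {
            "events": scan.design.to_records(),
            "total_duration_s": scan.design.total_duration,
        },
        "meta": scan.meta,
    }


def save_scan(scan: RawIntensityScan, directory: str | Path) -> Path:
    """Write one participant's raw scan as intensity.csv + meta.json."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        n_t, n_ch, _ = scan.data.shape
        times = scan.times
        frames = []
        for wi, wl in enumerate(scan.wavelengths):
            df = pd.DataFrame(
                {
                    "time_s": np.repeat(times, n_ch),
                    "channel_id": np.tile(scan.layout.channel_ids, n_t),
                    "wavelength_nm": wl,
                    "intensity": scan.data[:, :, wi].ravel(),
                }
            )
            frames.append(df)
        table = pd.concat(frames, ignore_index=True)
        table.to_csv(directory / "intensity.csv", index=False, float_format="%.9g")
        with open(directory / "meta.json", "w") as fh:
            json.dump(_scan_meta(scan), fh, indent=1)
    except OSError as exc:
        raise OSError(f"failed writing scan container at {directory}: {exc}") from exc
    return directory


def _layout_from_meta(meta: dict) -> ProbeLayout:
    lay = meta["layout"]
    return ProbeLayout.from_records(lay["channels"], lay["source_detector_distance_cm"])


def load_scan(directory: str | Path) -> RawIntensityScan:
    directory = Path(directory)
    with open(directory / "meta.json") as fh:
        meta = json.load(fh)
    layout = _layout_from_meta(meta)
    design = BlockDesign.from_records(
        meta["design"]["events"], meta["design"]["total_duration_s"]
    )
    table = pd.read_csv(directory / "intensity.csv")
    wavelengths = tuple(meta["wavelengths_nm"])
    ids = layout.channel_ids
    n_ch = len(ids)
    times = np.sort(table["time_s"].unique())
    n_t = len(times)
    data = np.empty((n_t, n_ch, 2))
    ch_pos = {cid: i for i, cid in enumerate(ids)}
    t_pos = {t: i for i, t in enumerate(times)}
    for wi, wl in enumerate(wavelengths):
        sub = table[table["wavelength_nm"] == wl]
        rows = sub["time_s"].map(t_pos).to_numpy()
        cols = sub["channel_id"].map(ch_pos).to_numpy()
        data[rows, cols, wi] = sub["intensity"].to_numpy()
    return RawIntensityScan(
        participant=meta["participant"],
        data=data,
        sampling_rate=meta["sampling_rate"],
        wavelengths=wavelengths,
        layout=layout,
        design=design,
        meta=meta.get("meta", {}),
    )


def save_hb(
    hb: HbSeries,
    design: BlockDesign,
    directory: str | Path,
    participant: str,
    extra_meta: dict | None = None,
) -> Path:
    """Write a hemoglobin series container (hb.csv + meta.json)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n_t, n_ch, _ = hb.data.shape
    times = hb.times
    frames = []
    for hi, hb_type in enumerate(HB_TYPES):
        frames.append(
            pd.DataFrame(
                {
                    "time_s": np.repeat(times, n_ch),
                    "channel_id": np.tile(hb.layout.channel_ids, n_t),
                    "hb_type": hb_type,
                    "value": hb.data[:, :, hi].ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        directory / "hb.csv", index=False, float_format="%.9g"
    )
    meta = {
        "participant": participant,
        "sampling_rate": hb.sampling_rate,
        "layout": {
            "channels": hb.layout.to_records(),
            "source_detector_distance_cm": hb.layout.source_detector_distance,
        },
        "design": {
            "events": design.to_records(),
            "total_duration_s": design.total_duration,
        },
        "available_channels": [
            int(cid) for cid, ok in zip(hb.layout.channel_ids, hb.available) if ok
        ],
        "meta": extra_meta or {},
    }
    with open(directory / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    return directory


def load_hb(directory: str | Path) -> tuple[HbSeries, BlockDesign, dict]:
    directory = Path(directory)
    with open(directory / "meta.json") as fh:
        meta = json.load(fh)
    layout = _layout_from_meta(meta)
    design = BlockDesign.from_records(
        meta["design"]["events"], meta["design"]["total_duration_s"]
    )
    table = pd.read_csv(directory / "hb.csv")
    ids = layout.channel_ids
    times = np.sort(table["time_s"].unique())
    data = np.full((len(times), len(ids), 2), np.nan)
    ch_pos = {cid: i for i, cid in enumerate(ids)}
    t_pos = {t: i for i, t in enumerate(times)}
    for hi, hb_type in enumerate(HB_TYPES):
        sub = table[table["hb_type"] == hb_type]
        rows = sub["time_s"].map(t_pos).to_numpy()
        cols = sub["channel_id"].map(ch_pos).to_numpy()
        data[rows, cols, hi] = sub["value"].to_numpy()
    avail = np.isin(ids, meta["available_channels"])
    hb = HbSeries(data, meta["sampling_rate"], layout, avail)
    return hb, design, meta.get("meta", {})


def save_scan_hdf5(scan: RawIntensityScan, path: str | Path) -> Path:
    """Single-file HDF5 variant of the scan container (same schema)."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("intensity", data=scan.data)
        f.attrs["meta_json"] = json.dumps(_scan_meta(scan))
    return path


def load_scan_hdf5(path: str | Path) -> RawIntensityScan:
    import h5py

    with h5py.File(path, "r") as f:
        data = f["intensity"][()]
        meta = json.loads(f.attrs["meta_json"])
    layout = _layout_from_meta(meta)
    design = BlockDesign.from_records(
        meta["design"]["events"], meta["design"]["total_duration_s"]
    )
    return RawIntensityScan(
        participant=meta["participant"],
        data=data,
        sampling_rate=meta["sampling_rate"],
        wavelengths=tuple(meta["wavelengths_nm"]),
        layout=layout,
        design=design,
        meta=meta.get("meta", {}),
    )
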