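"""Readers and writers for the package's on-disk formats.

FLIM stacks travel as multi-page TIFF (one page per time-bin, frames
concatenated) with a JSON sidecar carrying the timing metadata; decay
histograms, ROI traces and event tables are plain CSV; fit reports are
JSON with the configuration hash and seed embedded so outputs are
traceable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .events import EventTrain
from .exceptions import InvalidParameterError, SpinelabError
from .flim import FlimStack, PhotonHistogram
from .timecourse import RoiTrace

__all__ = [
    "write_stack",
    "read_stack",
    "write_histogram_csv",
    "read_histogram_csv",
    "write_traces_csv",
    "read_traces_csv",
    "write_events_csv",
    "read_events_csv",
    "write_results",
]

TRACE_COLUMNS = ["time", "value", "channel", "roi_id"]
EVENT_COLUMNS = ["recording_id", "event_time_s"]


def write_stack(path: str | Path, stack: FlimStack, sidecar: str | Path) -> None:
    """Write a FLIM stack as multi-page TIFF plus a JSON metadata sidecar.

    Pages are ordered frame-major: frame 0 bins 0..B-1, then frame 1, ...
    """
    path, sidecar = Path(path), Path(sidecar)
    n_frames, rows, cols, n_bins = stack.frames.shape
    pages = np.moveaxis(stack.frames, 3, 1).reshape(n_frames * n_bins, rows, cols)
    tifffile.imwrite(path, pages.astype(np.uint16))
    meta = {
        "n_frames": int(n_frames),
        "n_bins": int(n_bins),
        "shape": [int(rows), int(cols)],
        "bin_width_ns": float(stack.bin_edges[1] - stack.bin_edges[0]),
        "period_ns": float(stack.period),
        "frame_times_s": [float(x) for x in stack.frame_times],
    }
    sidecar.write_text(json.dumps(meta, indent=2))


def read_stack(path: str | Path, sidecar: str | Path) -> FlimStack:
    """Read a FLIM stack written by :func:`write_stack`, validating shapes."""
    path, sidecar = Path(path), Path(sidecar)
    if not sidecar.exists():
        raise SpinelabError(f"missing metadata sidecar: expected {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise SpinelabError(f"malformed sidecar {sidecar}: {exc}") from exc
    try:
        pages = tifffile.imread(path)
    except Exception as exc:  # tifffile raises various types
        raise SpinelabError(f"malformed TIFF {path}: {exc}") from exc
    n_frames, n_bins = meta["n_frames"], meta["n_bins"]
    rows, cols = meta["shape"]
    if pages.shape != (n_frames * n_bins, rows, cols):
        raise SpinelabError(
            f"TIFF page count/shape {pages.shape} inconsistent with metadata "
            f"({n_frames} frames x {n_bins} bins x {rows}x{cols})"
        )
    frames = np.moveaxis(pages.reshape(n_frames, n_bins, rows, cols), 1, 3)
    edges = meta["bin_width_ns"] * np.arange(n_bins + 1)
    return FlimStack(
        frames=frames,
        frame_times=np.asarray(meta["frame_times_s"], float),
        bin_edges=edges,
        period=meta["period_ns"],
    )


def write_histogram_csv(path: str | Path, hist: PhotonHistogram) -> None:
    df = pd.DataFrame(
        {
            "bin_start": hist.bin_edges[:-1],
            "bin_end": hist.bin_edges[1:],
            "counts": hist.counts,
        }
    )
    df.to_csv(path, index=False)


def read_histogram_csv(path: str | Path, period: float | None = None) -> PhotonHistogram:
    df = pd.read_csv(path)
    for col in ("bin_start", "bin_end", "counts"):
        if col not in df.columns:
            raise InvalidParameterError(f"histogram CSV missing column {col!r}")
    edges = np.append(df["bin_start"].to_numpy(float), float(df["bin_end"].iloc[-1]))
    if period is None:
        period = float(edges[-1])
    return PhotonHistogram(bin_edges=edges, counts=df["counts"].to_numpy(), period=period)


def write_traces_csv(path: str | Path, traces: dict[str, dict[str, RoiTrace]]) -> None:
    """Write ROI traces keyed as {roi_id: {channel: RoiTrace}} to tidy CSV."""
    rows = []
    for roi_id, channels in traces.items():
        for channel, tr in channels.items():
            rows.append(
                pd.DataFrame(
                    {
                        "time": tr.times,
                        "value": tr.f,
                        "channel": channel,
                        "roi_id": roi_id,
                    }
                )
            )
    pd.concat(rows, ignore_index=True)[TRACE_COLUMNS].to_csv(path, index=False)


def read_traces_csv(path: str | Path, baseline_n: int = 7) -> dict[str, dict[str, RoiTrace]]:
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidParameterError(f"trace CSV missing columns {missing}")
    out: dict[str, dict[str, RoiTrace]] = {}
    for (roi_id, channel), grp in df.groupby(["roi_id", "channel"], sort=False):
        grp = grp.sort_values("time")
        out.setdefault(str(roi_id), {})[str(channel)] = RoiTrace(
            times=grp["time"].to_numpy(float),
            f=grp["value"].to_numpy(float),
            channel=str(channel),
            baseline_n=baseline_n,
        )
    return out


def write_events_csv(path: str | Path, trains: dict[str, EventTrain]) -> None:
    rows = [
        {"recording_id": rid, "event_time_s": t}
        for rid, train in trains.items()
        for t in train.event_times
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_events_csv(
    path: str | Path,
    recording_window: tuple[float, float],
    stim_window: tuple[float, float] | None = None,
) -> dict[str, EventTrain]:
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidParameterError(f"event CSV missing columns {missing}")
    return {
        str(rid): EventTrain(
            event_times=grp["event_time_s"].to_numpy(float),
            recording_window=recording_window,
            stim_window=stim_window,
        )
        for rid, grp in df.groupby("recording_id", sort=False)
    }


def write_results(
    outdir: str | Path,
    tables: dict[str, pd.DataFrame] | None = None,
    images: dict[str, np.ndarray] | None = None,
    report: dict | None = None,
) -> dict[str, Path]:
    """Write analysis outputs: CSV tables, TIFF images, a JSON report.

    Table columns keep their given order; the report is written as
    ``report.json`` and should carry the configuration hash and seed.
    Returns the mapping of logical name to written path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in (tables or {}).items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        written[name] = p
    for name, arr in (images or {}).items():
        p = outdir / f"{name}.tiff"
        tifffile.imwrite(p, np.asarray(arr, dtype=np.float32))
        written[name] = p
    if report is not None:
        p = outdir / "report.json"
        p.write_text(json.dumps(report, indent=2, default=_json_default))
        written["report"] = p
    return written


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON-serializable: {type(o)}")
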