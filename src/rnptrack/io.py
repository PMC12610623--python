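"""Readers and writers for the package's on-disk formats.

Formats
-------
Photon streams
    CSV: one arrival time in seconds per line; ``#`` starts a comment.  The
    writer records the acquisition duration in a ``# duration_s = ...``
    comment so roundtrips preserve it.
    Binary: 16-byte ASCII magic ``FCSPHOT1`` (null padded), little-endian
    uint64 photon count, then that many little-endian uint64 timestamps in
    nanoseconds.  The format carries no duration; the reader defaults it to
    the last timestamp unless the caller supplies one.
Correlation curves
    CSV with header ``lag_s,G,sigma`` (sigma column empty when absent); lags
    are written with 17 significant digits so refitting is reproducible.
Image stacks
    Multi-page grayscale TIFF, one file per channel, read/written through
    tifffile preserving integer pixel values.
ROIs
    CSV with header ``label,x,y,width,height`` or a JSON list of objects
    with the same keys.
Reports / sidecars
    JSON; every CLI output gets a ``<name>.meta.json`` sidecar recording
    inputs, parameters, seed and package version.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from rnptrack.errors import FormatError
from rnptrack.fcs.correlate import CorrelationCurve, PhotonStream
from rnptrack.zstack import ROI, AxialOffsetReport

__all__ = [
    "read_photon_stream",
    "write_photon_stream",
    "read_curve",
    "write_curve",
    "read_stack",
    "write_stack",
    "read_rois",
    "write_rois",
    "write_report",
    "write_sidecar",
]

_MAGIC = b"FCSPHOT1".ljust(16, b"\x00")
_NS = 1e-9


def write_photon_stream(
    stream: PhotonStream, path: str | Path, format: str = "csv"
) -> Path:
    """Write a photon stream as CSV (seconds) or FCSPHOT1 binary (ns)."""
    path = Path(path)
    if format == "csv":
        with path.open("w") as fh:
            fh.write("# photon arrival timestamps, seconds\n")
            fh.write(f"# duration_s = {float(stream.duration)!r}\n")
            for t in stream.timestamps:
                fh.write(f"{float(t)!r}\n")
    elif format == "binary":
        ns = np.round(stream.timestamps / _NS).astype("<u8")
        with path.open("wb") as fh:
            fh.write(_MAGIC)
            fh.write(struct.pack("<Q", ns.size))
            fh.write(ns.tobytes())
    else:
        raise FormatError(f"unknown photon stream format {format!r}")
    return path


def read_photon_stream(
    path: str | Path, format: str | None = None, duration: float | None = None
) -> PhotonStream:
    """Read a photon stream; format inferred from the magic when omitted."""
    path = Path(path)
    data = path.read_bytes()
    if format is None:
        format = "binary" if data[:16] == _MAGIC else "csv"
    if format == "binary":
        if len(data) < 24:
            raise FormatError(f"{path}: truncated before header (got {len(data)} bytes)")
        if data[:16] != _MAGIC:
            raise FormatError(
                f"{path}: bad magic in bytes 0-15 (expected FCSPHOT1)"
            )
        (count,) = struct.unpack_from("<Q", data, 16)
        expected = 24 + 8 * count
        if len(data) < expected:
            raise FormatError(
                f"{path}: truncated at byte {len(data)} (header promises "
                f"{expected} bytes)"
            )
        ns = np.frombuffer(data, dtype="<u8", count=count, offset=24)
        ts = ns.astype(float) * _NS
    elif format == "csv":
        ts_list: list[float] = []
        for lineno, raw in enumerate(data.decode().splitlines(), start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("duration_s") and duration is None:
                    try:
                        duration = float(body.split("=", 1)[1])
                    except (IndexError, ValueError):
                        pass
                continue
            try:
                ts_list.append(float(line))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
        ts = np.asarray(ts_list)
    else:
        raise FormatError(f"unknown photon stream format {format!r}")
    if ts.size and np.any(np.diff(ts) < 0):
        raise FormatError(f"{path}: timestamps are not sorted")
    if duration is None:
        duration = float(ts[-1]) if ts.size else 1.0
    return PhotonStream(timestamps=ts, duration=duration)


def write_curve(curve: CorrelationCurve, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("lag_s,G,sigma\n")
        for i in range(len(curve)):
            sigma = "" if curve.sigma is None else f"{curve.sigma[i]:.17g}"
            fh.write(f"{curve.lags[i]:.17g},{curve.values[i]:.17g},{sigma}\n")
    return path


def read_curve(path: str | Path) -> CorrelationCurve:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    for col in ("lag_s", "G"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    sigma = None
    if "sigma" in df.columns and df["sigma"].notna().all():
        sigma = df["sigma"].to_numpy(float)
    return CorrelationCurve(
        lags=df["lag_s"].to_numpy(float),
        values=df["G"].to_numpy(float),
        sigma=sigma,
    )


def write_stack(stack: np.ndarray, path: str | Path) -> Path:
    """Write a (slices, height, width) array as a multi-page grayscale TIFF."""
    path = Path(path)
    arr = np.asarray(stack)
    if arr.ndim != 3:
        raise FormatError("stack must be (slices, height, width)")
    tifffile.imwrite(path, arr, photometric="minisblack")
    return path


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page grayscale TIFF as a (slices, height, width) array."""
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except Exception as exc:
        raise FormatError(f"{path}: not a readable TIFF ({exc})") from exc
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise FormatError(
            f"{path}: expected a single-channel z-stack, got shape "
            f"{arr.shape}; split channels first (one TIFF per channel)"
        )
    return arr


def write_rois(rois: Sequence[ROI], path: str | Path) -> Path:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = [
            {"label": r.label, "x": r.x, "y": r.y, "width": r.width,
             "height": r.height}
            for r in rois
        ]
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        with path.open("w") as fh:
            fh.write("label,x,y,width,height\n")
            for r in rois:
                fh.write(f"{r.label},{r.x},{r.y},{r.width},{r.height}\n")
    return path


def read_rois(path: str | Path) -> list[ROI]:
    path = Path(path)
    if path.suffix.lower() == ".json":
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: {exc}") from exc
        return [
            ROI(x=int(r["x"]), y=int(r["y"]), width=int(r["width"]),
                height=int(r["height"]), label=str(r.get("label", i)))
            for i, r in enumerate(payload)
        ]
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    for col in ("label", "x", "y", "width", "height"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return [
        ROI(x=int(row.x), y=int(row.y), width=int(row.width),
            height=int(row.height), label=str(row.label))
        for row in df.itertuples()
    ]


def write_report(report: AxialOffsetReport, path: str | Path) -> Path:
    """Write an axial-offset report as CSV (per-ROI rows then summary rows)
    or JSON, chosen by the file extension."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "per_roi": [
                {"roi": label, "peak_slice_ch1": p1, "peak_slice_ch2": p2,
                 "delta_z": dz}
                for label, p1, p2, dz in report.per_roi
            ],
            "summary": report.summary_dict(),
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path
    frame = report.to_frame(one_based=False)
    fiji = report.to_frame(one_based=True)
    frame["peak_slice_ch1_fiji"] = fiji["peak_slice_ch1"]
    frame["peak_slice_ch2_fiji"] = fiji["peak_slice_ch2"]
    with path.open("w") as fh:
        frame.to_csv(fh, index=False)
        fh.write("\n# summary\n")
        for key, value in report.summary_dict().items():
            fh.write(f"# {key},{value}\n")
    return path


def write_sidecar(
    output_path: str | Path,
    inputs: dict | None = None,
    parameters: dict | None = None,
    seed: int | None = None,
) -> Path:
    """Write the JSON metadata sidecar for an output artifact."""
    from rnptrack import __version__

    output_path = Path(output_path)
    sidecar = output_path.with_name(output_path.name + ".meta.json")
    payload = {
        "output": output_path.name,
        "inputs": {k: str(v) for k, v in (inputs or {}).items()},
        "parameters": parameters or {},
        "seed": seed,
        "package_version": __version__,
    }
    sidecar.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return sidecar
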