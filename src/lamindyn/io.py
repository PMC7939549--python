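"""Readers and writers for the pipeline's file formats.

Images travel as multi-channel TIFF with the pixel size recorded in the
resolution tags; traces, trajectories and correlation curves as headered
CSV; ground truth and run manifests as JSON sidecars.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .fcs import FCSCurve
from .imagequant import NucleusImage
from .photobleach import CPTrace
from .trajectory import Trajectory3D

CHANNEL_ORDER = ("lamin", "dna")


def write_tiff(path, image: NucleusImage) -> None:
    """Write channels as a (C, ...) TIFF stack; pixel size in resolution tags."""
    roles = [r for r in CHANNEL_ORDER if r in image.channels]
    roles += [r for r in image.channels if r not in roles]
    stack = np.stack([image.channels[r] for r in roles]).astype(np.float32)
    ppu = 1.0 / image.pixel_size  # pixels per micron
    tifffile.imwrite(
        path, stack, resolution=(ppu, ppu), resolutionunit="MICROMETER",
        metadata={"axes": "C" + "ZYX"[-(stack.ndim - 1):],
                  "channel_roles": roles,
                  "pixel_size_um": image.pixel_size},
    )


def read_tiff(path, pixel_size: float | None = None,
              channel_roles: list[str] | None = None) -> NucleusImage:
    """Read a TIFF written by :func:`write_tiff` (or any C-first stack)."""
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    roles = channel_roles or meta.get("channel_roles")
    px = pixel_size or meta.get("pixel_size_um")
    if px is None:
        raise ValueError(f"{path}: no pixel size in metadata; pass pixel_size=")
    if arr.ndim == 2:
        arr = arr[None]
    if roles is None:
        roles = list(CHANNEL_ORDER[: arr.shape[0]])
    channels = {r: np.asarray(arr[i], dtype=float)
                for i, r in enumerate(roles)}
    return NucleusImage(channels=channels, pixel_size=float(px))


def write_trace_csv(path, trace: CPTrace) -> None:
    pd.DataFrame({"t_s": trace.t, "intensity": trace.intensity}).to_csv(
        path, index=False)


def read_trace_csv(path) -> CPTrace:
    df = pd.read_csv(path)
    _require(df, path, ["t_s", "intensity"])
    return CPTrace(t=df["t_s"].to_numpy(), intensity=df["intensity"].to_numpy())


def write_curve_csv(path, curve: FCSCurve) -> None:
    cols = {"lag_s": curve.lag, "G": curve.G}
    if curve.weights is not None:
        cols["sd"] = curve.weights
    pd.DataFrame(cols).to_csv(path, index=False)


def read_curve_csv(path) -> FCSCurve:
    df = pd.read_csv(path)
    _require(df, path, ["lag_s", "G"])
    w = df["sd"].to_numpy() if "sd" in df.columns else None
    return FCSCurve(lag=df["lag_s"].to_numpy(), G=df["G"].to_numpy(), weights=w)


def write_trajectories_csv(path, trajs: list[Trajectory3D]) -> None:
    rows = []
    for tr in trajs:
        for f in range(tr.n_points):
            if tr.missing[f]:
                continue
            rows.append((tr.telomere_id, tr.nucleus_id, f, tr.t[f],
                         tr.xyz[f, 0], tr.xyz[f, 1], tr.xyz[f, 2]))
    pd.DataFrame(rows, columns=["telomere_id", "nucleus_id", "frame", "t_s",
                                "x_um", "y_um", "z_um"]).to_csv(path,
                                                                index=False)


def read_trajectories_csv(path, n_frames: int | None = None
                          ) -> list[Trajectory3D]:
    """Read tracks; frames absent from the file are flagged missing."""
    df = pd.read_csv(path)
    _require(df, path, ["telomere_id", "nucleus_id", "frame", "t_s",
                        "x_um", "y_um", "z_um"])
    if n_frames is None:
        n_frames = int(df["frame"].max()) + 1
    frame_t = (df.drop_duplicates("frame").set_index("frame")["t_s"]
               .reindex(range(n_frames)))
    dt = np.nanmedian(np.diff(frame_t.to_numpy()))
    t_full = frame_t.to_numpy()
    nan = np.isnan(t_full)
    if nan.any():  # fill gaps on the nominal uniform grid
        t_full[nan] = t_full[~nan][0] + dt * (np.flatnonzero(nan)
                                              - np.flatnonzero(~nan)[0])
    trajs = []
    for (tid, nid), g in df.groupby(["telomere_id", "nucleus_id"]):
        xyz = np.full((n_frames, 3), np.nan)
        miss = np.ones(n_frames, dtype=bool)
        idx = g["frame"].to_numpy(dtype=int)
        xyz[idx] = g[["x_um", "y_um", "z_um"]].to_numpy()
        miss[idx] = False
        xyz[miss] = 0.0
        trajs.append(Trajectory3D(int(tid), int(nid), t_full, xyz,
                                  missing=miss))
    return trajs


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2))


def write_manifest(path, config: dict, seed: int | None,
                   inputs: list[str] = ()) -> None:
    """Machine-readable run manifest: config echo, seed, versions, checksums."""
    manifest = {
        "config": _jsonable(config),
        "seed": seed,
        "versions": {"python": platform.python_version(),
                     "numpy": np.__version__, "pandas": pd.__version__},
        "input_checksums": {str(p): _sha256(p) for p in inputs},
    }
    write_json(path, manifest)


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _require(df: pd.DataFrame, path, cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


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
    if isinstance(obj, Path):
        return str(obj)
    return obj
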