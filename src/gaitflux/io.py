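"""Plain-text I/O: tracks, state sequences, mask stacks, reports.

Formats are deliberately simple and lossless at representation precision:

* **Tracks** — one CSV per cell with header ``t,x,y,ex,ey`` (seconds,
  micrometers, unit-vector components; orientation columns optional), plus
  a JSON manifest recording the generating configuration and seed.
* **State sequences** — CSV of ``(T_n, state)`` rows plus a JSON summary.
* **Mask stacks** — run-length-encoded label images (0 background,
  1 flagellar region, 2 body) in a single JSON file.
* **Reports** — JSON with sorted keys, so identical analyses are
  byte-identical on disk.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .core import GaitStateSequence, RegionPair, Track
from .ctmc_inference import RateMatrix
from .synthetic_motility import SimulationConfig

__all__ = [
    "write_track",
    "read_track",
    "read_tracks",
    "write_tracks",
    "write_manifest",
    "read_manifest",
    "write_state_sequence",
    "read_state_sequence",
    "write_masks",
    "read_masks",
    "write_report",
    "read_report",
    "config_to_dict",
    "config_from_dict",
]


def write_track(track: Track, path: str | Path) -> None:
    """Write one track as delimited text (columns t,x,y[,ex,ey])."""
    data = {
        "t": track.times,
        "x": track.positions[:, 0],
        "y": track.positions[:, 1],
    }
    if track.orientation is not None:
        data["ex"] = track.orientation[:, 0]
        data["ey"] = track.orientation[:, 1]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")


def read_track(path: str | Path) -> Track:
    """Parse one track file; malformed rows are dropped with line numbers.

    Raises
    ------
    ValueError
        On missing required columns or non-monotone time stamps.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"t", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path.name}: missing required columns {sorted(required - set(df.columns))}")
    has_orient = {"ex", "ey"}.issubset(df.columns)
    cols = ["t", "x", "y"] + (["ex", "ey"] if has_orient else [])
    numeric = df[cols].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        lines = [int(i) + 2 for i in numeric.index[bad]]  # +2: header + 1-based
        warnings.warn(
            f"{path.name}: dropped {bad.sum()} malformed row(s) at line(s) {lines}"
        )
        numeric = numeric[~bad]
    if len(numeric) == 0:
        raise ValueError(f"{path.name}: no valid rows")
    t = numeric["t"].to_numpy()
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        raise ValueError(f"{path.name}: time stamps are not strictly increasing")
    return Track(
        times=t,
        positions=numeric[["x", "y"]].to_numpy(),
        orientation=numeric[["ex", "ey"]].to_numpy() if has_orient else None,
        track_id=path.stem,
    )


def write_tracks(tracks: Sequence[Track], directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, track in enumerate(tracks):
        name = track.track_id or f"track_{i:04d}"
        p = directory / f"{name}.csv"
        write_track(track, p)
        paths.append(p)
    return paths


def read_tracks(directory: str | Path) -> list[Track]:
    """Read every track CSV in a directory; skip unreadable files with a warning."""
    directory = Path(directory)
    files = sorted(directory.glob("*.csv"))
    tracks = []
    for f in files:
        try:
            tracks.append(read_track(f))
        except ValueError as exc:
            warnings.warn(f"skipping {f.name}: {exc}")
    if not tracks:
        raise ValueError(f"no tracks found in {directory}")
    return tracks


def config_to_dict(config: SimulationConfig) -> dict[str, Any]:
    d = dataclasses.asdict(config)
    d["rate_matrix"] = np.asarray(config.rate_matrix.q).tolist()
    d["rate_matrix_labels"] = (
        list(config.rate_matrix.labels) if config.rate_matrix.labels else None
    )
    d["mask_shape"] = list(config.mask_shape)
    return d


def config_from_dict(d: dict[str, Any]) -> SimulationConfig:
    d = dict(d)
    labels = d.pop("rate_matrix_labels", None)
    d["rate_matrix"] = RateMatrix(np.asarray(d["rate_matrix"]), labels=labels)
    d["mask_shape"] = tuple(d["mask_shape"])
    return SimulationConfig(**d)


def write_manifest(config: SimulationConfig, path: str | Path, **extra: Any) -> None:
    payload = {"config": config_to_dict(config), **extra}
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=2))


def read_manifest(path: str | Path) -> dict[str, Any]:
    payload = json.loads(Path(path).read_text())
    payload["config"] = config_from_dict(payload["config"])
    return payload


def write_state_sequence(seq: GaitStateSequence, path: str | Path) -> None:
    """CSV of sojourn start time and state, with censoring in the header."""
    df = pd.DataFrame({"t_start": seq.boundaries[:-1], "state": seq.states})
    with open(path, "w") as fh:
        fh.write(
            f"# end={float(seq.boundaries[-1])!r} censored_first={seq.censored_first} "
            f"censored_last={seq.censored_last}\n"
        )
        df.to_csv(fh, index=False, float_format="%.10g")


def read_state_sequence(path: str | Path) -> GaitStateSequence:
    path = Path(path)
    header = path.read_text().splitlines()[0]
    meta = dict(item.split("=") for item in header.lstrip("# ").split())
    df = pd.read_csv(path, comment="#")
    boundaries = np.concatenate((df["t_start"].to_numpy(), [float(meta["end"])]))
    return GaitStateSequence(
        boundaries=boundaries,
        states=df["state"].to_numpy(dtype=int),
        censored_first=meta["censored_first"] == "True",
        censored_last=meta["censored_last"] == "True",
        sequence_id=path.stem,
    )


def _rle_encode(flat: np.ndarray) -> tuple[list[int], list[int]]:
    change = np.flatnonzero(np.diff(flat)) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [flat.size])))
    return flat[starts].tolist(), lengths.tolist()


def write_masks(pairs: Sequence[RegionPair], path: str | Path) -> None:
    """Run-length-encoded label-image stack (single JSON file)."""
    if not pairs:
        raise ValueError("no masks to write")
    frames = []
    for pair in pairs:
        values, lengths = _rle_encode(pair.to_labels().ravel())
        frames.append({"values": values, "lengths": lengths})
    payload = {
        "shape": list(pairs[0].body.shape),
        "pixel_size": pairs[0].pixel_size,
        "frames": frames,
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def read_masks(path: str | Path) -> list[RegionPair]:
    payload = json.loads(Path(path).read_text())
    shape = tuple(payload["shape"])
    px = payload["pixel_size"]
    pairs = []
    for frame in payload["frames"]:
        flat = np.repeat(
            np.asarray(frame["values"], dtype=np.uint8),
            np.asarray(frame["lengths"], dtype=int),
        )
        pairs.append(RegionPair.from_labels(flat.reshape(shape), pixel_size=px))
    return pairs


def write_report(report: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, sort_keys=True, indent=2))


def read_report(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())
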