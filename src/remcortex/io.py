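"""On-disk session layout.

A recording is a directory. The canonical payload format is raw float32
(C-order) next to a JSON sidecar declaring shape and rate; movies may instead
be stored as multi-page TIFF. Traces may also be read from two-column CSV
(time_s, value). Hypnograms, laser schedules and events are CSV; region maps
and ground truth are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import EventSeries, Hypnogram, Recording, RegionMap


def _write_sidecar(path: Path, **fields):
    path.write_text(json.dumps(fields, indent=1))


def _load_sidecar(path: Path) -> dict:
    if not path.exists():
        raise FileNotFoundError(f"missing sidecar {path}")
    return json.loads(path.read_text())


def _validate_count(name: str, n: int, side: dict):
    rate = side["rate_hz"]
    if rate <= 0:
        raise ValueError(f"{name}: rate_hz must be positive")
    if "duration_s" in side:
        expected = int(round(side["duration_s"] * rate))
        if abs(n - expected) > 0:
            raise ValueError(
                f"{name}: payload has {n} samples but sidecar declares "
                f"{side['duration_s']} s at {rate} Hz ({expected} samples)"
            )


def write_movie(movie: np.ndarray, rate: float, path: Path, fmt: str = "bin"):
    path = Path(path)
    movie = np.asarray(movie, dtype=np.float32)
    side = dict(shape=list(movie.shape), rate_hz=rate, dtype="float32",
                duration_s=movie.shape[0] / rate)
    if fmt == "bin":
        movie.tofile(path.with_suffix(".bin"))
    elif fmt == "tiff":
        tifffile.imwrite(path.with_suffix(".tif"), movie)
    else:
        raise ValueError(f"unknown movie format {fmt!r}")
    _write_sidecar(path.with_suffix(".json"), **side)


def read_movie(path: Path):
    """Read a movie from ``<stem>.bin`` or ``<stem>.tif`` plus sidecar."""
    path = Path(path)
    side = _load_sidecar(path.with_suffix(".json"))
    shape = tuple(side["shape"])
    if path.with_suffix(".bin").exists():
        movie = np.fromfile(path.with_suffix(".bin"), dtype=np.float32)
        if movie.size != int(np.prod(shape)):
            raise ValueError(
                f"movie: payload has {movie.size} values but sidecar declares "
                f"shape {shape}"
            )
        movie = movie.reshape(shape)
    elif path.with_suffix(".tif").exists():
        movie = tifffile.imread(path.with_suffix(".tif")).astype(np.float32)
        if movie.shape != shape:
            raise ValueError(
                f"movie: TIFF shape {movie.shape} != sidecar shape {shape}"
            )
    else:
        raise FileNotFoundError(f"no movie payload next to {path}")
    _validate_count("movie", movie.shape[0], side)
    return movie, float(side["rate_hz"])


def write_trace(trace: np.ndarray, rate: float, path: Path, fmt: str = "bin"):
    path = Path(path)
    trace = np.asarray(trace, dtype=np.float32)
    if fmt == "bin":
        trace.tofile(path.with_suffix(".bin"))
        _write_sidecar(path.with_suffix(".json"), n=int(trace.size), rate_hz=rate,
                       dtype="float32", duration_s=trace.size / rate)
    elif fmt == "csv":
        pd.DataFrame({"time_s": np.arange(trace.size) / rate, "value": trace}
                     ).to_csv(path.with_suffix(".csv"), index=False)
    else:
        raise ValueError(f"unknown trace format {fmt!r}")


def read_trace(path: Path):
    path = Path(path)
    if path.with_suffix(".bin").exists():
        side = _load_sidecar(path.with_suffix(".json"))
        trace = np.fromfile(path.with_suffix(".bin"), dtype=np.float32)
        if trace.size != side["n"]:
            raise ValueError(
                f"{path.stem}: payload has {trace.size} samples, sidecar "
                f"declares n={side['n']}"
            )
        _validate_count(path.stem, trace.size, side)
        return trace, float(side["rate_hz"])
    if path.with_suffix(".csv").exists():
        df = pd.read_csv(path.with_suffix(".csv"))
        t = df["time_s"].to_numpy()
        rate = 1.0 / np.median(np.diff(t)) if t.size > 1 else 1.0
        return df["value"].to_numpy(dtype=np.float32), float(round(rate, 6))
    raise FileNotFoundError(f"no trace payload next to {path}")


def write_laser(laser, path: Path):
    pd.DataFrame(laser, columns=["onset_s", "duration_s"]).to_csv(path, index=False)


def read_laser(path: Path):
    df = pd.read_csv(path)
    return [(float(r.onset_s), float(r.duration_s)) for r in df.itertuples()]


def write_hypnogram(hyp: Hypnogram, path: Path):
    hyp.to_frame().to_csv(path, index=False)


def read_hypnogram(path: Path, epoch_s: float = 5.0) -> Hypnogram:
    return Hypnogram.from_frame(pd.read_csv(path), epoch_s=epoch_s)


def write_events(events: EventSeries, path: Path):
    events.to_frame().to_csv(path, index=False)


def read_events(path: Path) -> EventSeries:
    df = pd.read_csv(path)
    return EventSeries(df["time_s"].to_numpy(), df.drop(columns=["time_s"]))


def write_region_map(rm: RegionMap, path: Path):
    Path(path).write_text(json.dumps(
        {"names": list(rm.names), "label_image": rm.label_image.tolist()}))


def read_region_map(path: Path) -> RegionMap:
    d = json.loads(Path(path).read_text())
    return RegionMap(np.asarray(d["label_image"]), tuple(d["names"]))


def write_recording(rec: Recording, out_dir, movie_format: str = "bin"):
    """Write one session directory; returns the directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if rec.movie is not None:
        write_movie(rec.movie, rec.movie_rate, out / "movie", fmt=movie_format)
    for name in ("eeg", "emg", "lfp"):
        if getattr(rec, name) is not None:
            write_trace(getattr(rec, name), rec.phys_rate, out / name)
    for name in ("face", "eye"):
        if getattr(rec, name) is not None:
            write_trace(getattr(rec, name), rec.video_rate, out / name)
    if rec.laser:
        write_laser(rec.laser, out / "laser.csv")
    (out / "meta.json").write_text(json.dumps(rec.meta, default=str, indent=1))
    return out


def read_recording(in_dir) -> Recording:
    src = Path(in_dir)
    if not src.is_dir():
        raise FileNotFoundError(f"{src} is not a directory")
    kw = {}
    if (src / "movie.json").exists():
        kw["movie"], kw["movie_rate"] = read_movie(src / "movie")
    for name in ("eeg", "emg", "lfp"):
        if (src / f"{name}.json").exists() or (src / f"{name}.csv").exists():
            kw[name], kw["phys_rate"] = read_trace(src / name)
    for name in ("face", "eye"):
        if (src / f"{name}.json").exists() or (src / f"{name}.csv").exists():
            kw[name], kw["video_rate"] = read_trace(src / name)
    if (src / "laser.csv").exists():
        kw["laser"] = read_laser(src / "laser.csv")
    if (src / "meta.json").exists():
        kw["meta"] = json.loads((src / "meta.json").read_text())
    return Recording(**kw)
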