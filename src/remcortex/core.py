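"""Core data model shared by all pipeline stages.

Conventions: all times are seconds from recording start, all intervals are
half-open, all indexing is 0-based. The 5-s scoring epoch is the universal
clock; per-frame state labels are derived by epoch lookup.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical state names, in arousal order.
STATES = ("Wake", "NREM", "REM")

#: Default scoring epoch length (states are scored every 5 s).
EPOCH_S = 5.0

#: EEG band edges in Hz, half-open [lo, hi).
BANDS = {"delta": (0.5, 4.0), "theta": (6.0, 10.0), "sigma": (9.0, 17.0)}

#: The nine cortical regions of the reference map (id 1..9; 0 = outside brain).
REGION_NAMES = ("MOs", "MOp", "SSb", "SSu", "SSl", "VISp", "VISs", "RSPd", "RSPl")

OCCIPITAL_REGIONS = ("VISp", "VISs", "RSPd", "RSPl")
SOMATOMOTOR_REGIONS = ("MOs", "MOp", "SSb", "SSu", "SSl")


@dataclass
class Hypnogram:
    """Per-epoch brain-state labels on a fixed epoch grid.

    Parameters
    ----------
    labels : array of str
        One of ``STATES`` per epoch.
    epoch_s : float
        Epoch length in seconds (default 5 s).
    flags : dict of str -> bool array
        Per-epoch substate annotations (``active_wake``, ``phasic_rem``,
        ``microarousal``), each aligned with ``labels``.
    """

    labels: np.ndarray
    epoch_s: float = EPOCH_S
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype="<U4")
        bad = set(np.unique(self.labels)) - set(STATES)
        if bad:
            raise ValueError(f"unknown state labels: {sorted(bad)}")
        if self.epoch_s <= 0:
            raise ValueError("epoch_s must be positive")
        for name, arr in self.flags.items():
            arr = np.asarray(arr, dtype=bool)
            if arr.shape != self.labels.shape:
                raise ValueError(f"flag {name!r} misaligned with labels")
            self.flags[name] = arr

    @property
    def n_epochs(self) -> int:
        return self.labels.size

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_s

    @property
    def epoch_starts(self) -> np.ndarray:
        return np.arange(self.n_epochs) * self.epoch_s

    def state_at(self, times_s) -> np.ndarray:
        """State label at each time (nearest-epoch lookup, half-open bins)."""
        idx = np.floor(np.asarray(times_s, dtype=float) / self.epoch_s).astype(int)
        idx = np.clip(idx, 0, self.n_epochs - 1)
        return self.labels[idx]

    def frame_labels(self, rate: float, n_frames: int) -> np.ndarray:
        """Per-frame labels for a trace sampled at ``rate`` Hz."""
        return self.state_at(np.arange(n_frames) / rate)

    def bouts(self, state: str):
        """Contiguous runs of ``state`` as (start_s, end_s) half-open spans."""
        mask = self.labels == state
        out = []
        start = None
        for i, m in enumerate(mask):
            if m and start is None:
                start = i
            elif not m and start is not None:
                out.append((start * self.epoch_s, i * self.epoch_s))
                start = None
        if start is not None:
            out.append((start * self.epoch_s, self.n_epochs * self.epoch_s))
        return out

    def fraction(self, state: str) -> float:
        return float(np.mean(self.labels == state))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"epoch_start_s": self.epoch_starts, "state": self.labels})
        for name in ("active_wake", "phasic_rem", "microarousal"):
            if name in self.flags:
                df[name] = self.flags[name].astype(int)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, epoch_s: float = EPOCH_S) -> "Hypnogram":
        flags = {
            name: df[name].to_numpy().astype(bool)
            for name in ("active_wake", "phasic_rem", "microarousal")
            if name in df.columns
        }
        return cls(df["state"].to_numpy(), epoch_s=epoch_s, flags=flags)


@dataclass
class EventSeries:
    """Discrete detected events: anchor times plus per-event properties."""

    times_s: np.ndarray
    props: pd.DataFrame = None

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.props is None:
            self.props = pd.DataFrame(index=range(self.times_s.size))
        if len(self.props) != self.times_s.size:
            raise ValueError("props must align 1:1 with times_s")
        if self.times_s.size and np.any(np.diff(self.times_s) < 0):
            order = np.argsort(self.times_s, kind="stable")
            self.times_s = self.times_s[order]
            self.props = self.props.iloc[order].reset_index(drop=True)

    def __len__(self) -> int:
        return self.times_s.size

    def to_frame(self) -> pd.DataFrame:
        df = self.props.copy()
        df.insert(0, "time_s", self.times_s)
        return df


@dataclass
class RegionMap:
    """Per-pixel region labels: 0 outside the brain, 1..9 the named regions."""

    label_image: np.ndarray
    names: tuple = REGION_NAMES

    def __post_init__(self):
        self.label_image = np.asarray(self.label_image, dtype=np.int32)
        present = set(np.unique(self.label_image)) - {0}
        allowed = set(range(1, len(self.names) + 1))
        if not present <= allowed:
            raise ValueError(f"label image contains ids outside 1..{len(self.names)}")
        missing = allowed - present
        if missing:
            raise ValueError(
                f"empty regions: {[self.names[i - 1] for i in sorted(missing)]}"
            )

    @property
    def brain_mask(self) -> np.ndarray:
        return self.label_image > 0

    def region_mask(self, name: str) -> np.ndarray:
        return self.label_image == self.names.index(name) + 1


@dataclass
class Recording:
    """One session: movie, physiology and behavior traces, laser schedule."""

    movie: np.ndarray = None          # (frames, H, W)
    movie_rate: float = 10.0
    eeg: np.ndarray = None
    emg: np.ndarray = None
    lfp: np.ndarray = None
    phys_rate: float = 1000.0
    face: np.ndarray = None
    eye: np.ndarray = None
    video_rate: float = 25.0
    laser: list = field(default_factory=list)   # (onset_s, duration_s) pairs
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("movie_rate", "phys_rate", "video_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        durs = []
        if self.movie is not None:
            self.movie = np.asarray(self.movie)
            durs.append(("movie", self.movie.shape[0] / self.movie_rate, self.movie_rate))
        for name in ("eeg", "emg", "lfp"):
            tr = getattr(self, name)
            if tr is not None:
                setattr(self, name, np.asarray(tr, dtype=np.float32))
                durs.append((name, len(tr) / self.phys_rate, self.phys_rate))
        for name in ("face", "eye"):
            tr = getattr(self, name)
            if tr is not None:
                setattr(self, name, np.asarray(tr, dtype=np.float32))
                durs.append((name, len(tr) / self.video_rate, self.video_rate))
        if durs:
            ref_name, ref, _ = durs[0]
            for name, d, rate in durs[1:]:
                if abs(d - ref) > 1.0 / min(rate, durs[0][2]) + 1e-9:
                    raise ValueError(
                        f"duration mismatch: {name} spans {d:.3f} s but "
                        f"{ref_name} spans {ref:.3f} s"
                    )

    @property
    def duration_s(self) -> float:
        if self.movie is not None:
            return self.movie.shape[0] / self.movie_rate
        for tr, rate in ((self.eeg, self.phys_rate), (self.emg, self.phys_rate),
                         (self.face, self.video_rate)):
            if tr is not None:
                return len(tr) / rate
        return 0.0


def epoch_slices(n_samples: int, rate: float, epoch_s: float = EPOCH_S):
    """Half-open index ranges covering successive epochs; last partial dropped.

    Returns a list of ``slice`` objects of equal length ``round(epoch_s*rate)``.
    """
    if epoch_s <= 0:
        raise ValueError("epoch_s must be positive")
    step = int(round(epoch_s * rate))
    n_epochs = n_samples // step
    return [slice(k * step, (k + 1) * step) for k in range(n_epochs)]


def resample_to(trace, from_rate: float, to_rate: float) -> np.ndarray:
    """Linear-interpolation resampling; output length = floor(duration*to_rate)."""
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("cannot resample an empty trace")
    if from_rate <= 0 or to_rate <= 0:
        raise ValueError("rates must be positive")
    if from_rate == to_rate:
        return trace.copy()
    duration = trace.size / from_rate
    n_out = int(np.floor(duration * to_rate))
    t_out = np.arange(n_out) / to_rate
    t_in = np.arange(trace.size) / from_rate
    return np.interp(t_out, t_in, trace)


def moving_average(x, window: int) -> np.ndarray:
    """Centered moving average with edge truncation (shorter windows at ends)."""
    x = np.asarray(x, dtype=float)
    if window <= 1:
        return x.copy()
    if window % 2 == 0:
        window += 1            # keep the window symmetric around each sample
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den
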