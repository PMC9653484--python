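"""Rule-based Wake/NREM/REM scoring from EEG/EMG, plus substate annotation.

Scoring criteria follow the standard rodent definitions: wakefulness is
desynchronized EEG with high EMG; NREM is high-amplitude delta (0.5-4 Hz)
with low EMG; REM is high theta (6-10 Hz) with low EMG. The semi-automatic
manual validation step of a lab workflow is replaced by a deterministic
threshold cascade so the scorer is a pure function of its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator

from .core import BANDS, EPOCH_S, Hypnogram, epoch_slices, resample_to

#: FFT frequency resolution, Hz.
FREQ_RES = 0.18


@dataclass
class Spectrogram:
    """Per-epoch EEG power on a uniform frequency grid."""

    times_s: np.ndarray       # epoch start times
    freqs_hz: np.ndarray
    power: np.ndarray         # (epochs, freqs), >= 0

    def band_power(self, lo: float, hi: float) -> np.ndarray:
        """Total power over the half-open band [lo, hi) per epoch."""
        sel = (self.freqs_hz >= lo) & (self.freqs_hz < hi)
        return self.power[:, sel].sum(axis=1)


@dataclass
class ScoreConfig:
    """Thresholds of the scoring cascade (z-scores are per recording)."""

    emg_z_wake: float = 0.5
    delta_z_nrem: float = 0.0       # reserved stricter NREM gate; cascade default off
    theta_delta_rem: float = 1.0
    smoothing: int = 3              # majority-filter width, epochs (odd)
    microarousal_max_s: float = 15.0
    microarousal_emg_z: float = 1.0

    def __post_init__(self):
        if self.smoothing % 2 != 1:
            raise ValueError("smoothing width must be odd")


def compute_spectrogram(eeg, rate: float, epoch_s: float = EPOCH_S) -> Spectrogram:
    """Per-epoch FFT power spectrum with ~0.18-Hz bin spacing.

    Each epoch is zero-padded to ``round(rate / 0.18)`` samples, so the grid
    spacing is the standard 0.18-Hz scoring resolution regardless of epoch
    length.
    """
    eeg = np.asarray(eeg, dtype=float)
    if rate < 2 * max(hi for _, hi in BANDS.values()):
        raise ValueError("sampling rate below twice the highest band edge")
    slices = epoch_slices(eeg.size, rate, epoch_s)
    if not slices:
        raise ValueError("trace shorter than one epoch")
    step = slices[0].stop - slices[0].start
    nfft = max(int(round(rate / FREQ_RES)), step)
    segs = np.stack([eeg[s] for s in slices])
    spec = np.fft.rfft(segs, n=nfft, axis=1)
    power = (np.abs(spec) ** 2) / (rate * step)
    power[:, 1:-1] *= 2.0                       # one-sided density
    freqs = np.fft.rfftfreq(nfft, d=1.0 / rate)
    times = np.arange(len(slices)) * epoch_s
    return Spectrogram(times, freqs, power)


def emg_epoch_z(emg, rate: float, epoch_s: float = EPOCH_S) -> np.ndarray:
    """Per-epoch EMG RMS, z-scored across the recording."""
    emg = np.asarray(emg, dtype=float)
    slices = epoch_slices(emg.size, rate, epoch_s)
    rms = np.array([np.sqrt(np.mean(emg[s] ** 2)) for s in slices])
    sd = rms.std()
    if sd == 0:
        raise ValueError("EMG is constant across epochs; cannot z-score")
    return (rms - rms.mean()) / sd


def _majority_filter(labels: np.ndarray, width: int) -> np.ndarray:
    if width <= 1 or labels.size < width:
        return labels.copy()
    half = width // 2
    out = labels.copy()
    for i in range(half, labels.size - half):
        window = labels[i - half: i + half + 1]
        vals, counts = np.unique(window, return_counts=True)
        top = counts.max()
        if top > width // 2 and (counts == top).sum() == 1:
            out[i] = vals[np.argmax(counts)]
    return out


def score_states(eeg, emg, rate: float, cfg: ScoreConfig = None,
                 epoch_s: float = EPOCH_S) -> Hypnogram:
    """Threshold-cascade scoring on the 5-s epoch grid.

    Per epoch: EMG-RMS z above ``emg_z_wake`` scores Wake regardless of the
    EEG; otherwise a theta/delta band-power ratio above ``theta_delta_rem``
    scores REM, else NREM. Ties (statistic exactly at threshold) fall to
    the lower-arousal branch. A width-``smoothing`` majority filter removes
    single-epoch flickers.
    """
    cfg = cfg or ScoreConfig()
    spec = compute_spectrogram(eeg, rate, epoch_s)
    emg_z = emg_epoch_z(emg, rate, epoch_s)
    n = min(spec.power.shape[0], emg_z.size)
    delta = spec.band_power(*BANDS["delta"])[:n]
    theta = spec.band_power(*BANDS["theta"])[:n]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(delta > 0, theta / np.maximum(delta, 1e-300), np.inf)
    labels = np.where(
        emg_z[:n] > cfg.emg_z_wake, "Wake",
        np.where(ratio > cfg.theta_delta_rem, "REM", "NREM"))
    labels = _majority_filter(labels.astype("<U4"), cfg.smoothing)
    return Hypnogram(labels, epoch_s=epoch_s)


def annotate_substates(hyp: Hypnogram, face=None, video_rate: float = 25.0,
                       emg=None, phys_rate: float = 1000.0,
                       cfg: ScoreConfig = None) -> Hypnogram:
    """Add active/quiet-wake, tonic/phasic-REM and microarousal flags.

    Phasic REM: REM epochs whose mean face motion strictly exceeds the mean
    over all REM epochs (so constant motion gives all-tonic). Active wake is
    the analogous split of Wake. Microarousals: contiguous NREM spans with
    per-epoch EMG z above threshold lasting at most ``microarousal_max_s``.
    """
    cfg = cfg or ScoreConfig()
    flags = dict(hyp.flags)
    if face is not None:
        face = np.asarray(face, dtype=float)
        slices = epoch_slices(face.size, video_rate, hyp.epoch_s)
        fmean = np.array([face[s].mean() for s in slices])
        fmean = fmean[:hyp.n_epochs]
        if fmean.size < hyp.n_epochs:
            fmean = np.pad(fmean, (0, hyp.n_epochs - fmean.size), mode="edge")
        for flag, state in (("phasic_rem", "REM"), ("active_wake", "Wake")):
            out = np.zeros(hyp.n_epochs, bool)
            sel = hyp.labels == state
            if sel.any():
                out[sel] = fmean[sel] > fmean[sel].mean()
            flags[flag] = out
    if emg is not None:
        z = emg_epoch_z(emg, phys_rate, hyp.epoch_s)[:hyp.n_epochs]
        if z.size < hyp.n_epochs:
            z = np.pad(z, (0, hyp.n_epochs - z.size), mode="edge")
        ma = np.zeros(hyp.n_epochs, bool)
        max_ep = int(cfg.microarousal_max_s // hyp.epoch_s)
        hot = (hyp.labels == "NREM") & (z > cfg.microarousal_emg_z)
        i = 0
        while i < hyp.n_epochs:
            if hot[i]:
                j = i
                while j < hyp.n_epochs and hot[j]:
                    j += 1
                if j - i <= max_ep:
                    ma[i:j] = True
                i = j
            else:
                i += 1
        flags["microarousal"] = ma
    return replace(hyp, flags=flags)


class SleepScorer(BaseEstimator):
    """Estimator wrapper around the scoring cascade.

    ``fit`` consumes ``X = (eeg, emg)`` and computes the per-recording
    statistics (spectrogram, EMG z-scores); ``predict`` returns the epoch
    labels and ``predict_hypnogram`` the full :class:`Hypnogram`.
    """

    def __init__(self, rate=1000.0, epoch_s=EPOCH_S, emg_z_wake=0.5,
                 theta_delta_rem=1.0, smoothing=3):
        self.rate = rate
        self.epoch_s = epoch_s
        self.emg_z_wake = emg_z_wake
        self.theta_delta_rem = theta_delta_rem
        self.smoothing = smoothing

    def _config(self) -> ScoreConfig:
        return ScoreConfig(emg_z_wake=self.emg_z_wake,
                           theta_delta_rem=self.theta_delta_rem,
                           smoothing=self.smoothing)

    def fit(self, X, y=None):
        eeg, emg = X
        self.hypnogram_ = score_states(eeg, emg, self.rate, self._config(),
                                       self.epoch_s)
        return self

    def predict(self, X=None):
        if X is not None:
            self.fit(X)
        return self.hypnogram_.labels

    def predict_hypnogram(self, X=None) -> Hypnogram:
        self.predict(X)
        return self.hypnogram_


def sigma_power_trace(eeg, rate: float, bin_s: float = 1.0) -> np.ndarray:
    """EEG sigma-band (9-17 Hz) power per ``bin_s``-second bin."""
    spec = compute_spectrogram(eeg, rate, epoch_s=bin_s)
    return spec.band_power(*BANDS["sigma"])


def theta_delta_ratio(eeg, rate: float, epoch_s: float = EPOCH_S) -> np.ndarray:
    """Theta/delta band-power ratio per epoch."""
    spec = compute_spectrogram(eeg, rate, epoch_s)
    delta = spec.band_power(*BANDS["delta"])
    theta = spec.band_power(*BANDS["theta"])
    return theta / np.maximum(delta, 1e-300)
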