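"""The REM-like frame statistic and its dynamics.

PC1-of-REM (the first principal component computed from REM-sleep frames
only, an occipital/retrosplenial-weighted template) is correlated with
every imaging frame; frames with correlation above +0.4 are "REM-like",
below -0.4 "REM-opponent". This module computes the template, the
frame-wise correlation trace, occurrence statistics over states and over
defined NREM periods (e.g. the 20 s immediately before a NREM->REM
transition), and event-triggered alignments against pontine P-waves, eye
movements, the infra-slow sigma oscillation and the theta/delta ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats
from sklearn.base import BaseEstimator

from .core import (EPOCH_S, EventSeries, Hypnogram, STATES, moving_average,
                   resample_to)
from .patterns import SpatialPattern, run_pca
from .preprocess import PreprocessedMovie
from .scoring import sigma_power_trace, theta_delta_ratio

CC_HI = 0.4
CC_LO = -0.4

PERIOD_KINDS = ("preREM", "NW1", "NW2", "NR1", "NR2",
                "NREM1", "NREM2", "NREM3", "NREM4")


@dataclass
class FrameCorrelationTrace:
    """Per-frame Pearson correlation with the REM template, plus labels."""

    cc: np.ndarray
    rate: float
    thresholds: tuple = (CC_HI, CC_LO)
    labels: np.ndarray = None

    def __post_init__(self):
        if self.labels is None:
            hi, lo = self.thresholds
            self.labels = np.where(
                self.cc > hi, "REM-like",
                np.where(self.cc < lo, "REM-opponent", "neutral")).astype("<U12")


def compute_pc1rem(pre: PreprocessedMovie, hyp: Hypnogram) -> SpatialPattern:
    """First PC of the REM-sleep frames (no temporal down-sampling)."""
    labels = hyp.frame_labels(pre.rate, pre.dff.shape[0])
    rem = np.flatnonzero(labels == "REM")
    if rem.size == 0:
        raise ValueError("no REM frames in the recording")
    pats = run_pca(pre, frame_subset=rem, downsample=1, n_components=2)
    return pats[0]


def frame_cc(pre: PreprocessedMovie, template: SpatialPattern,
             thresholds=(CC_HI, CC_LO)) -> FrameCorrelationTrace:
    """Pearson correlation of every frame with the template map.

    Computed over analyzable pixels; a zero-variance frame gets cc = 0 and
    the neutral label. Thresholds are strict, so cc exactly at +/-0.4 is
    neutral.
    """
    keep = pre.analysis_mask
    if template.map.shape != keep.shape:
        raise ValueError("template is not on the movie pixel grid")
    m = template.map[keep].astype(float)
    m = m - m.mean()
    m_norm = np.linalg.norm(m)
    F = pre.dff[:, keep].astype(float)
    F = F - F.mean(axis=1, keepdims=True)
    f_norm = np.linalg.norm(F, axis=1)
    denom = f_norm * m_norm
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = np.where(denom > 0, F @ m / np.where(denom > 0, denom, 1.0), 0.0)
    return FrameCorrelationTrace(cc=cc, rate=pre.rate, thresholds=thresholds)


def template_coefficient(pre: PreprocessedMovie, template: SpatialPattern
                         ) -> np.ndarray:
    """Per-frame projection of dF/F0 onto the template map (all frames).

    Unlike the coefficient stored on the pattern (which covers only the
    frames the PCA was fit on), this projects every frame, which is what
    event-triggered alignments need.
    """
    keep = pre.analysis_mask
    m = template.map[keep].astype(float)
    F = pre.dff[:, keep].astype(float)
    return (F - F.mean(axis=0)) @ m


class RemLikeLabeler(BaseEstimator):
    """Estimator form of the REM-like statistic.

    ``fit(X, y)`` takes a preprocessed movie and its hypnogram and learns
    the REM template (or uses a supplied one); ``transform`` returns the
    frame-correlation trace and ``predict`` the per-frame labels.
    """

    def __init__(self, cc_hi=CC_HI, cc_lo=CC_LO, template=None):
        self.cc_hi = cc_hi
        self.cc_lo = cc_lo
        self.template = template

    def fit(self, X: PreprocessedMovie, y: Hypnogram = None):
        self.template_ = (self.template if self.template is not None
                          else compute_pc1rem(X, y))
        return self

    def transform(self, X: PreprocessedMovie) -> FrameCorrelationTrace:
        return frame_cc(X, self.template_, thresholds=(self.cc_hi, self.cc_lo))

    def predict(self, X: PreprocessedMovie) -> np.ndarray:
        return self.transform(X).labels


def occurrence_by_state(fct: FrameCorrelationTrace, hyp: Hypnogram) -> pd.DataFrame:
    """Mean cc and REM-like / REM-opponent occurrence fractions per state.

    The ``ratio`` column is REM-like over REM-opponent counts with a
    zero-count guard (NaN when both are zero, inf when only the denominator
    is zero).
    """
    labels = hyp.frame_labels(fct.rate, fct.cc.size)
    rows = []
    for state in STATES:
        sel = labels == state
        n = int(sel.sum())
        if n == 0:
            rows.append((state, np.nan, np.nan, np.nan, np.nan, 0))
            continue
        like = int(np.sum(fct.labels[sel] == "REM-like"))
        opp = int(np.sum(fct.labels[sel] == "REM-opponent"))
        if like == 0 and opp == 0:
            ratio = np.nan
        elif opp == 0:
            ratio = np.inf
        else:
            ratio = like / opp
        rows.append((state, float(fct.cc[sel].mean()), like / n, opp / n,
                     ratio, n))
    return pd.DataFrame(rows, columns=["state", "mean_cc", "frac_rem_like",
                                       "frac_rem_opponent", "ratio", "n_frames"]
                        ).set_index("state")


# ---------------------------------------------------------------------------
# NREM period analysis

@dataclass
class NremPeriodSpec:
    """A named NREM window anchored to bout structure or transitions."""

    kind: str
    window_s: float = 20.0

    def __post_init__(self):
        if self.kind not in PERIOD_KINDS:
            raise ValueError(f"unknown period kind {self.kind!r}")


@dataclass
class PeriodOccurrence:
    """REM-like occurrence per NREM period plus the preREM ramp fit."""

    per_period: pd.DataFrame
    prerem_bins_s: np.ndarray = None
    prerem_timecourse: np.ndarray = None
    prerem_slope: float = np.nan
    prerem_r: float = np.nan
    skipped: dict = field(default_factory=dict)


def _transition_windows(hyp, to_state, offsets):
    """NREM windows [T+off0, T+off1) before each NREM->to_state transition."""
    out = []
    for k in range(1, hyp.n_epochs):
        if hyp.labels[k] == to_state and hyp.labels[k - 1] == "NREM":
            T = k * hyp.epoch_s
            out.append((T + offsets[0], T + offsets[1]))
    return out


def _window_is_nrem(hyp, a, b):
    if a < 0 or b > hyp.duration_s:
        return False
    e0, e1 = int(np.floor(a / hyp.epoch_s)), int(np.ceil(b / hyp.epoch_s))
    return bool(np.all(hyp.labels[e0:e1] == "NREM"))


def _period_windows(hyp: Hypnogram, spec: NremPeriodSpec):
    w = spec.window_s
    if spec.kind in ("preREM", "NR2"):
        return _transition_windows(hyp, "REM", (-w, 0.0))
    if spec.kind == "NR1":
        return _transition_windows(hyp, "REM", (-2 * w, -w))
    if spec.kind == "NW2":
        return _transition_windows(hyp, "Wake", (-w, 0.0))
    if spec.kind == "NW1":
        return _transition_windows(hyp, "Wake", (-2 * w, -w))
    q = int(spec.kind[-1])                      # NREM1..4: equal bout quarters
    out = []
    for start, end in hyp.bouts("NREM"):
        span = (end - start) / 4.0
        out.append((start + (q - 1) * span, start + q * span))
    return out


def occurrence_in_periods(fct: FrameCorrelationTrace, hyp: Hypnogram,
                          specs=None, bin_s: float = 1.0) -> PeriodOccurrence:
    """REM-like occurrence within defined NREM periods.

    Windows that leave NREM (or the recording) are skipped and counted.
    The preREM windows additionally produce a per-1-s-bin mean time course
    with a linear fit (slope in occurrence/s and Pearson r).
    """
    specs = specs if specs is not None else [NremPeriodSpec(k) for k in PERIOD_KINDS]
    is_like = (fct.labels == "REM-like").astype(float)
    rows, skipped = [], {}
    prerem_courses = None

    for spec in specs:
        windows = _period_windows(hyp, spec)
        vals, courses, n_skip = [], [], 0
        for a, b in windows:
            if b - a < bin_s or not _window_is_nrem(hyp, a, b):
                n_skip += 1
                continue
            i0, i1 = int(round(a * fct.rate)), int(round(b * fct.rate))
            seg = is_like[i0:i1]
            vals.append(seg.mean())
            n_bins = int((b - a) // bin_s)
            spb = int(round(bin_s * fct.rate))
            if seg.size >= n_bins * spb:
                courses.append(seg[:n_bins * spb].reshape(n_bins, spb).mean(axis=1))
        rows.append((spec.kind, np.mean(vals) if vals else np.nan, len(vals)))
        skipped[spec.kind] = n_skip
        if spec.kind == "preREM" and courses:
            lens = min(c.size for c in courses)
            prerem_courses = np.stack([c[:lens] for c in courses])
    per = pd.DataFrame(rows, columns=["kind", "occurrence", "n_windows"]
                       ).set_index("kind")
    out = PeriodOccurrence(per_period=per, skipped=skipped)
    if prerem_courses is not None:
        mean_course = prerem_courses.mean(axis=0)
        bins = (np.arange(mean_course.size) + 0.5) * bin_s - \
            specs[[s.kind for s in specs].index("preREM")].window_s
        fit = stats.linregress(bins, mean_course)
        out.prerem_bins_s = bins
        out.prerem_timecourse = mean_course
        out.prerem_slope = float(fit.slope)
        out.prerem_r = float(fit.rvalue)
    return out


# ---------------------------------------------------------------------------
# Event-triggered averaging and detectors

@dataclass
class TriggeredAverage:
    lags_s: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_events: int

    @property
    def peak_lag_s(self) -> float:
        return float(self.lags_s[np.argmax(self.mean)])


def event_triggered_average(trace, rate: float, events: EventSeries,
                            window_s: float = 4.0,
                            zscore: bool = False) -> TriggeredAverage:
    """Mean +/- SEM of trace segments around event anchors.

    Events whose window leaves the trace are dropped; at least one complete
    window is required. With ``zscore`` the trace is standardized first
    (the per-recording normalization used before across-animal averaging).
    """
    trace = np.asarray(trace, dtype=float)
    if zscore:
        sd = trace.std()
        trace = (trace - trace.mean()) / (sd if sd > 0 else 1.0)
    half = int(round(window_s * rate))
    segs = []
    for t in events.times_s:
        i = int(round(t * rate))
        if i - half >= 0 and i + half + 1 <= trace.size:
            segs.append(trace[i - half: i + half + 1])
    if not segs:
        raise ValueError("no event window lies fully inside the trace")
    segs = np.stack(segs)
    lags = np.arange(-half, half + 1) / rate
    sem = segs.std(axis=0, ddof=1) / np.sqrt(len(segs)) if len(segs) > 1 \
        else np.zeros(segs.shape[1])
    return TriggeredAverage(lags, segs.mean(axis=0), sem, len(segs))


def detect_pwaves(lfp, rate: float, hyp: Hypnogram, threshold_sd: float = 4.0,
                  min_sep_s: float = 0.1) -> EventSeries:
    """Large negative pontine LFP deflections during REM sleep.

    The SD reference comes from REM-restricted LFP; peaks are negative
    excursions beyond ``threshold_sd`` SDs with at least ``min_sep_s``
    between anchors (the deeper peak wins), anchored at the negative peak.
    """
    lfp = np.asarray(lfp, dtype=float)
    labels = hyp.frame_labels(rate, lfp.size)
    rem = labels == "REM"
    if not rem.any():
        return EventSeries(np.array([]), pd.DataFrame(columns=["amplitude"]))
    sd = lfp[rem].std()
    if sd == 0:
        return EventSeries(np.array([]), pd.DataFrame(columns=["amplitude"]))
    idx, _ = signal.find_peaks(-lfp, height=threshold_sd * sd,
                               distance=max(int(round(min_sep_s * rate)), 1))
    idx = idx[rem[idx]]
    return EventSeries(idx / rate, pd.DataFrame({"amplitude": lfp[idx]}))


def detect_eye_bouts(eye, rate: float = 25.0, baseline_points: int = 500,
                     threshold_sd: float = 1.0,
                     merge_gap_s: float = 0.5) -> EventSeries:
    """Bouts of horizontal eye movement from a 25-Hz position trace.

    The trace is rectified to movement speed, an adaptive 500-point moving
    average subtracted, and samples exceeding one SD of the excess mark
    movement; bouts separated by less than ``merge_gap_s`` merge. Anchors
    are bout onsets.
    """
    eye = np.asarray(eye, dtype=float)
    speed = np.abs(np.gradient(eye)) * rate
    excess = speed - moving_average(speed, baseline_points)
    sd = excess.std()
    if sd == 0:
        return EventSeries(np.array([]), pd.DataFrame(columns=["duration_s"]))
    above = excess > threshold_sd * sd
    onsets, offsets = _runs(above)
    merged = []
    for a, b in zip(onsets, offsets):
        if merged and (a - merged[-1][1]) / rate < merge_gap_s:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    times = np.array([a / rate for a, _ in merged])
    durs = np.array([(b - a) / rate for a, b in merged])
    return EventSeries(times, pd.DataFrame({"duration_s": durs}))


def _runs(mask):
    d = np.diff(mask.astype(int))
    onsets = np.flatnonzero(d == 1) + 1
    offsets = np.flatnonzero(d == -1) + 1
    if mask.size and mask[0]:
        onsets = np.r_[0, onsets]
    if mask.size and mask[-1]:
        offsets = np.r_[offsets, mask.size]
    return onsets, offsets


def lagged_pearson(x, y, rate: float, max_lag_s: float):
    """r(lag) = corr(x[t], y[t + lag]) over lags in [-max_lag, +max_lag].

    A positive peak lag means y is a delayed copy of x.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = min(x.size, y.size)
    x, y = x[:n], y[:n]
    max_lag = int(round(max_lag_s * rate))
    lags = np.arange(-max_lag, max_lag + 1)
    rs = np.full(lags.size, np.nan)
    for i, l in enumerate(lags):
        if l >= 0:
            a, b = x[:n - l], y[l:]
        else:
            a, b = x[-l:], y[:n + l]
        if a.size > 2 and a.std() > 0 and b.std() > 0:
            rs[i] = np.corrcoef(a, b)[0, 1]
    return lags / rate, rs


def sigma_crosscorr(eeg, phys_rate: float, fct: FrameCorrelationTrace,
                    hyp: Hypnogram, min_bout_s: float = 120.0,
                    max_lag_s: float = 60.0, smooth_s: float = 10.0):
    """Cross-correlogram of infra-slow EEG sigma power vs the smoothed cc.

    Sigma power (9-17 Hz) is computed per 1-s bin and the cc trace smoothed
    with a centered 10-s window and resampled to 1 Hz; both are restricted
    to NREM bouts of at least ``min_bout_s`` carrying no microarousal flag,
    z-scored per bout, and the lagged Pearson correlation pooled over bouts.
    Returns (lags_s, r, peak_lag_s).
    """
    ma = hyp.flags.get("microarousal", np.zeros(hyp.n_epochs, bool))
    bouts = []
    for start, end in hyp.bouts("NREM"):
        e0, e1 = int(start / hyp.epoch_s), int(end / hyp.epoch_s)
        if end - start >= min_bout_s and not ma[e0:e1].any():
            bouts.append((start, end))
    if not bouts:
        raise ValueError("no qualifying NREM bout (>=120 s, microarousal-free)")
    sigma = sigma_power_trace(eeg, phys_rate, bin_s=1.0)
    cc_s = moving_average(fct.cc, int(round(smooth_s * fct.rate)))
    cc_1hz = resample_to(cc_s, fct.rate, 1.0)

    max_lag = int(max_lag_s)
    lags = np.arange(-max_lag, max_lag + 1)
    pairs = {l: ([], []) for l in lags}
    for start, end in bouts:
        a, b = int(start), int(end)
        x = sigma[a:b]
        y = cc_1hz[a:b]
        n = min(x.size, y.size)
        x = (x - x[:n].mean()) / (x[:n].std() or 1.0)
        y = (y - y[:n].mean()) / (y[:n].std() or 1.0)
        for l in lags:
            if l >= 0:
                aa, bb = x[:n - l], y[l:n]
            else:
                aa, bb = x[-l:n], y[:n + l]
            pairs[l][0].append(aa)
            pairs[l][1].append(bb)
    rs = np.full(lags.size, np.nan)
    for i, l in enumerate(lags):
        xa = np.concatenate(pairs[l][0])
        ya = np.concatenate(pairs[l][1])
        if xa.size > 2 and xa.std() > 0 and ya.std() > 0:
            rs[i] = np.corrcoef(xa, ya)[0, 1]
    peak = float(lags[np.nanargmax(rs)])
    return lags.astype(float), rs, peak


def theta_delta_corr(eeg, phys_rate: float, coeff, coeff_rate: float,
                     hyp: Hypnogram, epoch_s: float = EPOCH_S) -> float:
    """Pearson r between 5-s-window means of theta/delta and the coefficient.

    Restricted to REM epochs; requires at least three windows.
    """
    ratio = theta_delta_ratio(eeg, phys_rate, epoch_s)
    spe = int(round(epoch_s * coeff_rate))
    coeff = np.asarray(coeff, float)
    n_ep = min(ratio.size, coeff.size // spe, hyp.n_epochs)
    cmean = coeff[:n_ep * spe].reshape(n_ep, spe).mean(axis=1)
    sel = hyp.labels[:n_ep] == "REM"
    if sel.sum() < 3:
        raise ValueError("fewer than three REM windows")
    return float(stats.pearsonr(ratio[:n_ep][sel], cmean[sel]).statistic)
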