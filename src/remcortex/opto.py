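"""Trial-aligned brain-state analysis for optogenetic sessions.

Covers the per-5-s-bin state-percentage time course around laser onset, the
y/x transition-probability table with 12-bin (60-s) bars and a 300-s
pre-laser baseline, REM bout counting, the stimulation-vs-baseline EEG
spectrum comparison, and the hierarchical (trials-within-mouse) bootstrap
used for inference on nested trial data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import EPOCH_S, Hypnogram, STATES
from .scoring import compute_spectrogram

BASELINE_S = 300.0        # pre-onset span covered by each trial window
BAR_BINS = 12             # bins per transition-probability bar (60 s)


@dataclass
class TrialSet:
    """One session's laser trials on the 5-s grid.

    ``labels`` is (trials, bins); ``bin_offsets_s`` gives each bin's start
    time relative to laser onset, spanning [-baseline_s, duration + post_s).
    """

    mouse_id: str
    labels: np.ndarray
    bin_offsets_s: np.ndarray
    trial_duration_s: float
    baseline_s: float = BASELINE_S
    n_dropped: int = 0

    @property
    def n_trials(self) -> int:
        return self.labels.shape[0]

    @property
    def laser_bins(self) -> np.ndarray:
        return (self.bin_offsets_s >= 0) & (
            self.bin_offsets_s < self.trial_duration_s)

    @property
    def baseline_bins(self) -> np.ndarray:
        return (self.bin_offsets_s >= -self.baseline_s) & (self.bin_offsets_s < 0)


def build_trial_set(hyp: Hypnogram, laser, mouse_id: str = "m0",
                    baseline_s: float = BASELINE_S,
                    post_s: float = None) -> TrialSet:
    """Extract trial-aligned label sequences from a scored hypnogram.

    Trials whose window is not fully scored (runs off either end of the
    recording) are dropped and counted. Overlapping trials are an error.
    """
    laser = sorted(laser)
    for (o1, d1), (o2, _d) in zip(laser, laser[1:]):
        if o1 + d1 > o2:
            raise ValueError("overlapping laser trials")
    dur = laser[0][1]
    post = post_s if post_s is not None else dur
    offsets = np.arange(-baseline_s, dur + post, hyp.epoch_s)
    rows, dropped = [], 0
    for onset, d in laser:
        if abs(d - dur) > 1e-9:
            raise ValueError("trials must share one duration")
        idx = np.round((onset + offsets) / hyp.epoch_s).astype(int)
        if idx[0] < 0 or idx[-1] >= hyp.n_epochs:
            dropped += 1
            continue
        rows.append(hyp.labels[idx])
    if not rows:
        raise ValueError("no fully-scored trial windows")
    return TrialSet(mouse_id=mouse_id, labels=np.stack(rows),
                    bin_offsets_s=offsets, trial_duration_s=dur,
                    baseline_s=baseline_s, n_dropped=dropped)


def state_percentage_timecourse(trial_sets) -> pd.DataFrame:
    """Per-bin mean percentage of each state, +/- SEM across sessions.

    Fractions are computed within each session (TrialSet) first, then
    averaged across sessions. Accepts one TrialSet or a list.
    """
    if isinstance(trial_sets, TrialSet):
        trial_sets = [trial_sets]
    offsets = trial_sets[0].bin_offsets_s
    per_session = {s: [] for s in STATES}
    for ts in trial_sets:
        if not np.array_equal(ts.bin_offsets_s, offsets):
            raise ValueError("trial sets are not on the same bin grid")
        for s in STATES:
            per_session[s].append(100.0 * np.mean(ts.labels == s, axis=0))
    out = {"bin_offset_s": offsets}
    for s in STATES:
        arr = np.stack(per_session[s])
        out[f"{s}_mean"] = arr.mean(axis=0)
        out[f"{s}_sem"] = (arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
                           if arr.shape[0] > 1 else np.zeros(arr.shape[1]))
    return pd.DataFrame(out)


@dataclass
class TransitionTable:
    """y/x transition probabilities per 5-s bin relative to laser onset."""

    bin_offsets_s: np.ndarray            # bins with a defined "next" bin
    x: dict                              # state -> trials in state per bin
    y: dict                              # (s, s') -> transitions per bin
    probability: dict                    # (s, s') -> y/x (NaN where x == 0)
    bars: pd.DataFrame                   # 60-s (12-bin) block means
    baseline: dict                       # (s, s') -> mean over pre-laser bins


def transition_probability(ts: TrialSet) -> TransitionTable:
    """Count-based transition table for one session.

    For bin t and ordered state pair (s, s'): x = trials in s at t,
    y = those entering s' at t+1, P = y/x. Bins with x = 0 are undefined
    and excluded from the 12-bin bars and the baseline mean (the mean over
    all defined bins within 300 s before onset).
    """
    lab = ts.labels
    offs = ts.bin_offsets_s[:-1]
    x = {s: (lab[:, :-1] == s).sum(axis=0) for s in STATES}
    y, p = {}, {}
    for s, s2 in itertools.product(STATES, STATES):
        cnt = ((lab[:, :-1] == s) & (lab[:, 1:] == s2)).sum(axis=0)
        y[(s, s2)] = cnt
        with np.errstate(invalid="ignore", divide="ignore"):
            p[(s, s2)] = np.where(x[s] > 0, cnt / np.maximum(x[s], 1), np.nan)
            p[(s, s2)][x[s] == 0] = np.nan

    n_blocks = offs.size // BAR_BINS
    rows = []
    for b in range(n_blocks):
        sel = slice(b * BAR_BINS, (b + 1) * BAR_BINS)
        row = {"block_start_s": float(offs[sel][0])}
        for pair, arr in p.items():
            vals = arr[sel]
            row[f"{pair[0]}->{pair[1]}"] = (np.nanmean(vals)
                                            if np.isfinite(vals).any() else np.nan)
        rows.append(row)
    bars = pd.DataFrame(rows)
    base_sel = (offs >= -ts.baseline_s) & (offs < 0)
    baseline = {}
    for pair, arr in p.items():
        vals = arr[base_sel]
        baseline[pair] = float(np.nanmean(vals)) if np.isfinite(vals).any() else np.nan
    return TransitionTable(bin_offsets_s=offs, x=x, y=y, probability=p,
                           bars=bars, baseline=baseline)


# ---------------------------------------------------------------------------
# Hierarchical bootstrap

@dataclass
class BootstrapResult:
    """Hierarchical bootstrap of the across-mouse mean of mouse means."""

    mean: float
    ci_low: float
    ci_high: float
    p_value: float = None
    diff_mean: float = None
    diff_ci: tuple = None
    iterations: int = 0
    trial_counts: dict = field(default_factory=dict)
    n_mice: int = 0
    distribution: np.ndarray = None
    diff_distribution: np.ndarray = None


def bootstrap_effect(laser_values: dict, baseline_values: dict = None,
                     iterations: int = 100_000, seed: int = 0,
                     ci: float = 95.0) -> BootstrapResult:
    """Resample m_i trials per mouse (with replacement), average per mouse,
    then across mice; repeat for ``iterations`` draws.

    ``laser_values`` maps mouse -> per-trial measurements. When
    ``baseline_values`` gives paired per-trial baselines, the same resampled
    trials feed both conditions and the laser-minus-baseline difference
    distribution yields a two-sided p-value (2 * min tail fraction with a
    +1 continuity guard, so p >= 1/iterations and p is never 0).
    """
    mice = sorted(laser_values)
    if len(mice) < 2:
        raise ValueError("need at least two mice")
    rng = np.random.default_rng(seed)
    las, base = {}, {}
    for m in mice:
        v = np.asarray(laser_values[m], dtype=float)
        if v.size == 0:
            raise ValueError(f"mouse {m!r} has zero trials")
        las[m] = v
        if baseline_values is not None:
            b = np.asarray(baseline_values[m], dtype=float)
            if b.size != v.size:
                raise ValueError(f"mouse {m!r}: unpaired baseline trials")
            base[m] = b

    mouse_means = np.zeros((len(mice), iterations))
    mouse_base = np.zeros_like(mouse_means) if baseline_values is not None else None
    for k, m in enumerate(mice):
        mi = las[m].size
        idx = rng.integers(0, mi, size=(iterations, mi))
        mouse_means[k] = las[m][idx].mean(axis=1)
        if mouse_base is not None:
            mouse_base[k] = base[m][idx].mean(axis=1)
    dist = mouse_means.mean(axis=0)
    lo, hi = np.percentile(dist, [(100 - ci) / 2, 100 - (100 - ci) / 2])
    res = BootstrapResult(
        mean=float(dist.mean()), ci_low=float(lo), ci_high=float(hi),
        iterations=iterations, n_mice=len(mice),
        trial_counts={m: int(las[m].size) for m in mice}, distribution=dist)
    if mouse_base is not None:
        diff = dist - mouse_base.mean(axis=0)
        n_le = int(np.sum(diff <= 0))
        n_ge = int(np.sum(diff >= 0))
        p = 2.0 * min(n_le + 1, n_ge + 1) / (iterations + 1)
        res.p_value = float(min(p, 1.0))
        res.diff_mean = float(diff.mean())
        res.diff_ci = tuple(np.percentile(diff, [(100 - ci) / 2,
                                                 100 - (100 - ci) / 2]))
        res.diff_distribution = diff
    return res


def trial_state_percentages(hyp: Hypnogram, laser, state: str = "REM",
                            baseline_s: float = 120.0) -> pd.DataFrame:
    """Per-trial % time in ``state``: laser-on vs the window just before.

    The baseline is the ``baseline_s`` seconds immediately preceding each
    onset (2 min by default, matching the 2-min stimulation).
    """
    rows = []
    for k, (onset, dur) in enumerate(sorted(laser)):
        e_on = int(round(onset / hyp.epoch_s))
        e_off = int(round((onset + dur) / hyp.epoch_s))
        e_pre = int(round((onset - baseline_s) / hyp.epoch_s))
        if e_pre < 0 or e_off > hyp.n_epochs:
            continue
        rows.append({
            "trial": k,
            "baseline_pct": 100.0 * np.mean(hyp.labels[e_pre:e_on] == state),
            "laser_pct": 100.0 * np.mean(hyp.labels[e_on:e_off] == state),
        })
    return pd.DataFrame(rows)


def rem_bout_count(hyp: Hypnogram, windows) -> int:
    """Number of REM-bout onsets falling inside the given (start, end) windows."""
    onsets = [start for start, _ in hyp.bouts("REM")]
    return sum(1 for t in onsets
               for a, b in windows if a <= t < b)


def stim_spectrum_compare(eeg, rate: float, hyp: Hypnogram, laser,
                          state: str = "NREM", baseline_s: float = 120.0,
                          trim_s: float = 10.0, norm_band=(0.5, 18.0)):
    """Mean EEG spectrum in ``state`` epochs: laser-on vs 2-min pre-laser.

    The first and last ``trim_s`` seconds of every state bout are occluded
    (bouts shorter than twice the trim vanish entirely); each condition's
    mean spectrum is normalized by its own mean over ``norm_band`` so the
    returned curves average to 1 there. The comparison statistic is a
    Wilcoxon signed-rank test across the in-band frequency bins of the two
    normalized curves. Missing conditions yield a None curve and a flag.
    """
    spec = compute_spectrogram(np.asarray(eeg, float), rate, hyp.epoch_s)
    n_ep = min(spec.power.shape[0], hyp.n_epochs)
    ok = np.zeros(n_ep, bool)
    trim_ep = int(np.ceil(trim_s / hyp.epoch_s))
    for start, end in hyp.bouts(state):
        e0, e1 = int(start / hyp.epoch_s), int(end / hyp.epoch_s)
        if e1 - e0 > 2 * trim_ep:
            ok[e0 + trim_ep: min(e1 - trim_ep, n_ep)] = True
    t_ep = np.arange(n_ep) * hyp.epoch_s
    in_laser = np.zeros(n_ep, bool)
    in_base = np.zeros(n_ep, bool)
    for onset, dur in laser:
        in_laser |= (t_ep >= onset) & (t_ep < onset + dur)
        in_base |= (t_ep >= onset - baseline_s) & (t_ep < onset)

    out = {"freqs_hz": spec.freqs_hz, "state": state, "flags": []}
    curves = {}
    for name, sel in (("stim", ok & in_laser), ("baseline", ok & in_base)):
        if not sel.any():
            out[name] = None
            out["flags"].append(f"no {state} epochs in {name} condition")
            continue
        curve = spec.power[:n_ep][sel].mean(axis=0)
        band = (spec.freqs_hz >= norm_band[0]) & (spec.freqs_hz < norm_band[1])
        curve = curve / curve[band].mean()
        out[name] = curve
        curves[name] = curve[band]
    if len(curves) == 2:
        d = curves["stim"] - curves["baseline"]
        if np.allclose(d, 0):
            out["stat"], out["p_value"] = 0.0, 1.0
        else:
            w = stats.wilcoxon(curves["stim"], curves["baseline"])
            out["stat"], out["p_value"] = float(w.statistic), float(w.pvalue)
    return out
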