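"""Synthetic session generator.

Emulates the statistical structure the analysis pipeline assumes: a
semi-Markov Wake/NREM/REM hypnogram on a 5-s epoch grid; EEG built from
band-limited noise with state-dependent power (delta-dominant NREM,
theta-dominant REM, infra-slow sigma modulation in NREM); state-dependent
EMG amplitude; pontine LFP with large negative P-wave deflections during
REM; a widefield movie carrying two orthonormal planted spatial patterns
(occipital vs somatomotor) over a nine-region atlas, with transient
PC-like events, a pre-REM occipital ramp, bleaching, a shared global
signal, vessel artifacts and pixel noise; face/eye behavior traces; and
laser trials that multiply the NREM->REM transition hazard.

Reproducibility: one master seed, with an independent substream per signal,
so e.g. changing the movie noise never changes the hypnogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage, signal

from .core import (
    BANDS,
    EPOCH_S,
    OCCIPITAL_REGIONS,
    REGION_NAMES,
    SOMATOMOTOR_REGIONS,
    STATES,
    Hypnogram,
    Recording,
    RegionMap,
)

_STREAMS = {
    "hypnogram": 1, "eeg": 2, "emg": 3, "lfp": 4, "movie": 5,
    "face": 6, "eye": 7, "laser": 8, "events": 9, "phasic": 10,
    "coeff_occ": 11, "coeff_som": 12, "global": 13, "remdrive": 14,
}


def _default_state_params():
    # Bout means tuned so stationary occupancy hits Wake 27 / NREM 65 / REM 8 %
    # (54 : 130 : 0.2*80 = 27 : 65 : 8).
    return {
        "Wake": {"mean_s": 54.0, "exit": {"NREM": 1.0}},
        "NREM": {"mean_s": 130.0, "exit": {"Wake": 0.8, "REM": 0.2}},
        "REM": {"mean_s": 80.0, "exit": {"Wake": 1.0}},
    }


def _default_band_powers():
    # Per-state SD of each EEG band component and of broadband EMG,
    # in arbitrary recording units.
    return {
        "Wake": {"delta": 0.5, "theta": 1.0, "sigma": 0.3, "emg": 2.0},
        "NREM": {"delta": 2.0, "theta": 0.7, "sigma": 1.0, "emg": 0.3},
        "REM": {"delta": 0.5, "theta": 2.0, "sigma": 0.3, "emg": 0.15},
    }


def _default_pattern_gains():
    # Mean coefficient of each planted map per state (dff template units).
    # Wake carries the occipital pattern with negative sign, so wake frames
    # tend to the REM-opponent side of the frame-correlation statistic.
    return {
        "Wake": {"occipital": -0.5, "somatomotor": 0.8},
        "NREM": {"occipital": 0.45, "somatomotor": 0.45},
        "REM": {"occipital": 1.3, "somatomotor": 0.1},
    }


@dataclass
class SimConfig:
    """All generator parameters for one synthetic session."""

    seed: int = 0
    duration_s: float = 1800.0
    movie_rate: float = 10.0
    phys_rate: float = 1000.0
    video_rate: float = 25.0
    image_shape: tuple = (64, 64)
    epoch_s: float = EPOCH_S
    start_state: str = "Wake"
    state_params: dict = field(default_factory=_default_state_params)
    occupancy_target: dict = field(default_factory=lambda: {
        "Wake": 0.27, "NREM": 0.65, "REM": 0.08})
    band_powers: dict = field(default_factory=_default_band_powers)
    sigma_infraslow_hz: float = 0.02
    sigma_infraslow_depth: float = 0.8
    pattern_gains: dict = field(default_factory=_default_pattern_gains)
    coeff_noise_sd: float = 0.12        # slow coefficient fluctuation
    event_rate_per_min: float = 3.0     # transient PC-like events, per pattern
    event_sigma_s: float = 0.9          # Gaussian sigma of each event
    event_amp: float = 1.0
    pwave_rate_per_min: float = 12.0
    pwave_lag_s: float = 0.9            # P-wave -> occipital activation lag
    pwave_amp_sd: float = 9.0           # deflection amplitude in baseline SDs
    lfp_noise_sd: float = 1.0
    lfp_noise_clip_sd: float = 3.5      # bounded noise floor (clipped Gaussian)
    prerem_ramp_s: float = 20.0
    prerem_ramp_amp: float = 0.8
    rem_drive_gain: float = 0.5         # shared slow REM fluctuation -> occ coeff
    rem_theta_coupling: float = 0.4     # same fluctuation -> REM theta amplitude
    phasic_fraction: float = 0.3        # fraction of each REM bout that is phasic
    bleach_params: tuple = (0.04, 200.0, 0.06, 2000.0)   # a1, tau1, a2, tau2
    bleach: bool = True
    global_gain: float = 0.02
    noise_sd: float = 0.01              # pixel noise, dff units
    f_base: float = 100.0
    vessel_contrast: float = 0.3
    # Optogenetics
    laser_schedule: list = None          # explicit [(onset_s, duration_s)] or None
    laser_hazard_multiplier: float = 1.0
    trial_duration_s: float = 120.0
    trial_interval_s: tuple = (300.0, 420.0)
    n_trials: int = 21

    def __post_init__(self):
        if self.duration_s < self.epoch_s:
            raise ValueError("duration_s must cover at least one epoch")
        for name in ("movie_rate", "phys_rate", "video_rate", "epoch_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        occ = sum(self.occupancy_target.values())
        if abs(occ - 1.0) > 1e-6:
            raise ValueError("occupancy_target must sum to 1")
        if self.phys_rate % self.movie_rate != 0:
            raise ValueError("movie_rate must divide phys_rate")
        if min(self.image_shape) < 32:
            raise ValueError("image_shape must be at least 32x32")
        if self.start_state not in STATES:
            raise ValueError(f"unknown start_state {self.start_state!r}")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Everything planted, for parameter-recovery tests."""

    hypnogram: Hypnogram = None
    pattern_maps: dict = field(default_factory=dict)
    pattern_coeffs: dict = field(default_factory=dict)
    event_times: dict = field(default_factory=dict)
    pwave_times: np.ndarray = None
    eye_event_times: np.ndarray = None
    phasic_epochs: np.ndarray = None
    global_trace: np.ndarray = None
    bleach_trace: np.ndarray = None
    laser_trials: list = field(default_factory=list)
    hazard_multiplier: float = 1.0

    def to_json_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()
        return {
            "hypnogram": None if self.hypnogram is None
            else self.hypnogram.labels.tolist(),
            "event_times": {k: arr(v) for k, v in self.event_times.items()},
            "pwave_times": arr(self.pwave_times),
            "eye_event_times": arr(self.eye_event_times),
            "phasic_epochs": arr(self.phasic_epochs),
            "laser_trials": [list(t) for t in self.laser_trials],
            "hazard_multiplier": self.hazard_multiplier,
        }


# ---------------------------------------------------------------------------
# Atlas and planted spatial patterns

def synthetic_atlas(shape=(64, 64)) -> RegionMap:
    """Nine-region reference map on an elliptical brain outline.

    Anterior (top) rows hold motor cortex, the middle band somatosensory
    areas, and the posterior band retrosplenial (medial) and visual
    (lateral) areas — the mediolateral/anteroposterior layout of a
    flattened dorsal cortex map.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2, (w - 1) / 2
    brain = ((yy - cy) / (0.46 * h)) ** 2 + ((xx - cx) / (0.42 * w)) ** 2 <= 1.0
    fy = (yy - (cy - 0.46 * h)) / (0.92 * h)          # 0 anterior -> 1 posterior
    fx = np.abs(xx - cx) / (0.42 * w)                  # 0 medial -> 1 lateral
    labels = np.zeros(shape, dtype=np.int32)

    def rid(name):
        return REGION_NAMES.index(name) + 1

    ant = fy < 0.30
    mid = (fy >= 0.30) & (fy < 0.60)
    post = fy >= 0.60
    labels[brain & ant & (fx < 0.45)] = rid("MOs")
    labels[brain & ant & (fx >= 0.45)] = rid("MOp")
    labels[brain & mid & (fx < 0.38)] = rid("SSu")
    labels[brain & mid & (fx >= 0.38) & (fx < 0.70)] = rid("SSl")
    labels[brain & mid & (fx >= 0.70)] = rid("SSb")
    labels[brain & post & (fx < 0.22)] = rid("RSPd")
    labels[brain & post & (fx >= 0.22) & (fx < 0.45)] = rid("RSPl")
    labels[brain & post & (fx >= 0.45) & (fx < 0.75)] = rid("VISp")
    labels[brain & post & (fx >= 0.75)] = rid("VISs")
    return RegionMap(labels)


def planted_pattern_maps(atlas: RegionMap):
    """Two orthonormal per-pixel maps: occipital-weighted and somatomotor-weighted."""
    def build(region_names):
        m = np.zeros(atlas.label_image.shape, dtype=float)
        for name in region_names:
            m[atlas.region_mask(name)] = 1.0
        m = ndimage.gaussian_filter(m, 1.5)
        m[~atlas.brain_mask] = 0.0
        return m

    occ = build(OCCIPITAL_REGIONS)
    som = build(SOMATOMOTOR_REGIONS)
    occ = occ / np.linalg.norm(occ)
    som = som - occ * np.sum(som * occ)        # Gram-Schmidt after smoothing
    norm = np.linalg.norm(som)
    if norm == 0:
        raise ValueError("pattern maps are not normalizable")
    som = som / norm
    return {"occipital": occ, "somatomotor": som}


# ---------------------------------------------------------------------------
# Hypnogram

def generate_hypnogram(cfg: SimConfig, laser=None, hazard_multiplier=None) -> Hypnogram:
    """Semi-Markov state sequence on the epoch grid.

    Exit hazards per 5-s epoch are ``1 - exp(-epoch_s / mean_bout_s)``, split
    across exit targets by the configured weights; during laser-on epochs the
    NREM->REM branch hazard is multiplied by ``hazard_multiplier``.
    """
    n_epochs = int(cfg.duration_s // cfg.epoch_s)
    if n_epochs < 1:
        raise ValueError("duration shorter than one epoch")
    mult = cfg.laser_hazard_multiplier if hazard_multiplier is None else hazard_multiplier
    laser = laser if laser is not None else (cfg.laser_schedule or [])
    laser_on = np.zeros(n_epochs, dtype=bool)
    for onset, dur in laser:
        a = int(np.floor(onset / cfg.epoch_s))
        b = int(np.ceil((onset + dur) / cfg.epoch_s))
        laser_on[max(a, 0):min(b, n_epochs)] = True

    rng = cfg.rng("hypnogram")
    labels = np.empty(n_epochs, dtype="<U4")
    state = cfg.start_state
    for k in range(n_epochs):
        labels[k] = state
        params = cfg.state_params[state]
        exits = {s: w for s, w in params["exit"].items() if w > 0}
        total_w = sum(exits.values())
        u = rng.random()
        if total_w == 0:
            continue
        p_exit = 1.0 - np.exp(-cfg.epoch_s / params["mean_s"])
        hazards = {s: p_exit * w / total_w for s, w in exits.items()}
        if state == "NREM" and laser_on[k] and "REM" in hazards:
            hazards["REM"] *= mult
        acc = 0.0
        for s, hz in hazards.items():
            acc += hz
            if u < acc:
                state = s
                break
    return Hypnogram(labels, epoch_s=cfg.epoch_s)


# ---------------------------------------------------------------------------
# Polysomnography

def _band_noise(rng, n, rate, band):
    lo, hi = band
    x = rng.standard_normal(n)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    y = signal.sosfiltfilt(sos, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def _epoch_envelope(values_per_epoch, n_samples, samples_per_epoch):
    env = np.repeat(values_per_epoch, samples_per_epoch)
    if env.size < n_samples:
        env = np.pad(env, (0, n_samples - env.size), mode="edge")
    return env[:n_samples]


def _rem_drive(cfg: SimConfig, duration_s: float, rate: float) -> np.ndarray:
    """Slow (<0.1 Hz) unit-SD fluctuation shared by REM theta power and the
    occipital coefficient, generated on a fixed 10-Hz grid so every consumer
    sees the same waveform regardless of its sampling rate."""
    base_rate = 10.0
    n_base = int(round(duration_s * base_rate))
    drive = _lowpass_noise(cfg.rng("remdrive"), n_base, base_rate, 0.1, 1.0)
    if rate == base_rate:
        return drive
    from .core import resample_to
    out = resample_to(drive, base_rate, rate)
    n = int(round(duration_s * rate))
    if out.size < n:
        out = np.pad(out, (0, n - out.size), mode="edge")
    return out[:n]


def generate_polysomnography(hyp: Hypnogram, cfg: SimConfig):
    """EEG, EMG and pontine LFP traces; returns (eeg, emg, lfp, pwave_times)."""
    if hyp.duration_s < cfg.duration_s - cfg.epoch_s:
        raise ValueError("hypnogram does not cover the configured duration")
    rate = cfg.phys_rate
    n = int(round(hyp.duration_s * rate))
    spe = int(round(cfg.epoch_s * rate))
    t = np.arange(n) / rate

    eeg = np.zeros(n)
    rng = cfg.rng("eeg")
    for band_name, band in BANDS.items():
        comp = _band_noise(rng, n, rate, band)
        amp = np.array([cfg.band_powers[s][band_name] for s in hyp.labels])
        env = _epoch_envelope(amp, n, spe)
        if band_name == "sigma":
            infra = 1.0 + cfg.sigma_infraslow_depth * np.sin(
                2 * np.pi * cfg.sigma_infraslow_hz * t)
            nrem = _epoch_envelope((hyp.labels == "NREM").astype(float), n, spe)
            env = env * np.where(nrem > 0, infra, 1.0)
        if band_name == "theta" and cfg.rem_theta_coupling:
            drive = _rem_drive(cfg, hyp.duration_s, rate)
            # bounded so theta stays the dominant REM band at every phase
            mod = np.clip(1.0 + cfg.rem_theta_coupling * drive, 0.5, 1.5)
            rem = _epoch_envelope((hyp.labels == "REM").astype(float), n, spe)
            env = env * np.where(rem > 0, mod, 1.0)
        eeg += env * comp

    emg_amp = np.array([cfg.band_powers[s]["emg"] for s in hyp.labels])
    emg = _epoch_envelope(emg_amp, n, spe) * cfg.rng("emg").standard_normal(n)

    rng_lfp = cfg.rng("lfp")
    # clipped-Gaussian noise floor: P-wave deflections always dominate it
    clip = cfg.lfp_noise_clip_sd
    lfp = cfg.lfp_noise_sd * np.clip(rng_lfp.standard_normal(n), -clip, clip)
    # P-waves avoid bout edges: they ride phasic REM, not state transitions
    pwave_times = _poisson_times_in_bouts(
        hyp.bouts("REM"), cfg.pwave_rate_per_min / 60.0, rng_lfp,
        min_gap_s=0.2, edge_s=3.0)
    width_s = 0.015
    half = int(4 * width_s * rate)
    kernel = -np.exp(-0.5 * (np.arange(-half, half + 1) / (width_s * rate)) ** 2)
    amp = cfg.pwave_amp_sd * max(cfg.lfp_noise_sd, 1e-12)
    for pt in pwave_times:
        i = int(round(pt * rate))
        a, b = max(i - half, 0), min(i + half + 1, n)
        lfp[a:b] += amp * kernel[a - (i - half): b - (i - half)]
    return (eeg.astype(np.float32), emg.astype(np.float32),
            lfp.astype(np.float32), pwave_times)


def _poisson_times_in_bouts(bouts, rate_hz, rng, min_gap_s=0.0, edge_s=0.0):
    times = []
    for start, end in bouts:
        lo, hi = start + edge_s, end - edge_s
        if hi <= lo:
            continue
        k = rng.poisson(rate_hz * (hi - lo))
        ts = np.sort(rng.uniform(lo, hi, size=k))
        for x in ts:
            if not times or x - times[-1] >= min_gap_s:
                times.append(x)
    return np.asarray(times)


# ---------------------------------------------------------------------------
# Movie

def _add_gaussian_bumps(trace, times, rate, sigma_s, amp):
    n = trace.size
    half = int(4 * sigma_s * rate)
    shape = np.exp(-0.5 * (np.arange(-half, half + 1) / (sigma_s * rate)) ** 2)
    for pt in np.atleast_1d(times):
        i = int(round(pt * rate))
        a, b = max(i - half, 0), min(i + half + 1, n)
        if a < b:
            trace[a:b] += amp * shape[a - (i - half): b - (i - half)]
    return trace


def _lowpass_noise(rng, n, rate, cutoff, sd):
    if sd == 0:
        return np.zeros(n)
    x = rng.standard_normal(n)
    sos = signal.butter(2, cutoff, btype="lowpass", fs=rate, output="sos")
    y = signal.sosfiltfilt(sos, x)
    s = y.std()
    return sd * (y / s if s > 0 else y)


def bleach_curve(t, params):
    """Two-term exponential decay, normalized to 1 at t = 0."""
    a1, tau1, a2, tau2 = params
    c = 1.0 - a1 - a2
    return c + a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)


def generate_pattern_coefficients(hyp: Hypnogram, cfg: SimConfig, pwave_times=None):
    """Planted coefficient traces of the two maps at the movie rate.

    Occipital: high in REM, anti-phase infra-slow oscillation against the
    somatomotor map in NREM (in phase with the sigma-power modulation),
    linear ramp over the last ``prerem_ramp_s`` seconds of NREM before each
    NREM->REM transition, transient Gaussian events at Poisson times —
    except in REM, where occipital events follow planted P-waves at
    ``pwave_lag_s``.
    """
    rate = cfg.movie_rate
    n = int(round(hyp.duration_s * rate))
    t = np.arange(n) / rate
    labels = hyp.frame_labels(rate, n)
    rng = cfg.rng("events")

    occ = np.array([cfg.pattern_gains[s]["occipital"] for s in labels], dtype=float)
    som = np.array([cfg.pattern_gains[s]["somatomotor"] for s in labels], dtype=float)
    osc = np.sin(2 * np.pi * cfg.sigma_infraslow_hz * t)
    nrem = labels == "NREM"
    occ[nrem] *= (1.0 + osc[nrem])
    som[nrem] *= (1.0 - osc[nrem])

    # pre-REM occipital ramp
    for k in range(1, hyp.n_epochs):
        if hyp.labels[k] == "REM" and hyp.labels[k - 1] == "NREM":
            T = k * hyp.epoch_s
            sel = (t >= T - cfg.prerem_ramp_s) & (t < T) & nrem
            occ[sel] += cfg.prerem_ramp_amp * (
                t[sel] - (T - cfg.prerem_ramp_s)) / cfg.prerem_ramp_s

    event_times = {}
    rate_hz = cfg.event_rate_per_min / 60.0
    non_rem_bouts = hyp.bouts("Wake") + hyp.bouts("NREM")
    occ_events = _poisson_times_in_bouts(
        sorted(non_rem_bouts), rate_hz, rng, min_gap_s=4 * cfg.event_sigma_s)
    if pwave_times is not None and len(pwave_times):
        rem_events = np.asarray(pwave_times) + cfg.pwave_lag_s
        rem_events = rem_events[rem_events < hyp.duration_s]
        occ_events = np.sort(np.concatenate([occ_events, rem_events]))
    event_times["occipital"] = occ_events
    som_events = _poisson_times_in_bouts(
        sorted(non_rem_bouts), rate_hz, rng, min_gap_s=4 * cfg.event_sigma_s)
    event_times["somatomotor"] = som_events
    if cfg.event_amp:
        _add_gaussian_bumps(occ, occ_events, rate, cfg.event_sigma_s, cfg.event_amp)
        _add_gaussian_bumps(som, som_events, rate, cfg.event_sigma_s, cfg.event_amp)

    if cfg.rem_drive_gain:
        drive = _rem_drive(cfg, hyp.duration_s, rate)[:n]
        occ[labels == "REM"] += cfg.rem_drive_gain * drive[labels == "REM"]
    occ += _lowpass_noise(cfg.rng("coeff_occ"), n, rate, 0.2, cfg.coeff_noise_sd)
    som += _lowpass_noise(cfg.rng("coeff_som"), n, rate, 0.2, cfg.coeff_noise_sd)
    return {"occipital": occ, "somatomotor": som}, event_times


def generate_movie(hyp: Hypnogram, cfg: SimConfig, pwave_times=None):
    """Raw widefield movie; returns (movie, GroundTruth part dict)."""
    atlas = synthetic_atlas(cfg.image_shape)
    maps = planted_pattern_maps(atlas)
    coeffs, event_times = generate_pattern_coefficients(hyp, cfg, pwave_times)
    rate = cfg.movie_rate
    n = coeffs["occipital"].size
    t = np.arange(n) / rate

    g = _lowpass_noise(cfg.rng("global"), n, rate, 0.5, 1.0) * cfg.global_gain
    bleach = bleach_curve(t, cfg.bleach_params) if cfg.bleach else np.ones(n)

    h, w = cfg.image_shape
    f0 = np.full((h, w), cfg.f_base)
    vessels = _vessel_image(cfg.image_shape)
    f0 = f0 * (1.0 - cfg.vessel_contrast * vessels)

    rng = cfg.rng("movie")
    movie = np.empty((n, h, w), dtype=np.float32)
    occ_map, som_map = maps["occipital"], maps["somatomotor"]
    chunk = 2000
    for a in range(0, n, chunk):
        b = min(a + chunk, n)
        block = (1.0
                 + coeffs["occipital"][a:b, None, None] * occ_map
                 + coeffs["somatomotor"][a:b, None, None] * som_map
                 + g[a:b, None, None])
        if cfg.noise_sd:
            block = block + cfg.noise_sd * rng.standard_normal((b - a, h, w))
        movie[a:b] = (f0 * block * bleach[a:b, None, None]).astype(np.float32)

    gt = dict(pattern_maps=maps, pattern_coeffs=coeffs, event_times=event_times,
              global_trace=g, bleach_trace=bleach)
    return movie, atlas, gt


def _vessel_image(shape):
    """A few dark 1-2 px curvilinear streaks, as large-vein stand-ins."""
    h, w = shape
    img = np.zeros(shape)
    yy = np.arange(h)
    for frac, width in ((0.35, 1), (0.55, 2), (0.72, 1)):
        x = (frac * w + 3.0 * np.sin(2 * np.pi * yy / h)).astype(int)
        for dx in range(width):
            xi = np.clip(x + dx, 0, w - 1)
            img[yy, xi] = 1.0
    return img


# ---------------------------------------------------------------------------
# Behavior

def generate_behavior(hyp: Hypnogram, cfg: SimConfig, occ_event_times=None):
    """Face motion energy and horizontal eye traces at the video rate.

    Returns (face, eye, phasic_epochs, eye_event_times).
    """
    rate = cfg.video_rate
    n = int(round(hyp.duration_s * rate))
    labels = hyp.frame_labels(rate, n)

    # per-REM-bout contiguous phasic block covering cfg.phasic_fraction
    rng_ph = cfg.rng("phasic")
    phasic_epochs = np.zeros(hyp.n_epochs, dtype=bool)
    for start, end in hyp.bouts("REM"):
        e0, e1 = int(start / hyp.epoch_s), int(end / hyp.epoch_s)
        n_ep = e1 - e0
        k = int(round(cfg.phasic_fraction * n_ep))
        if k > 0:
            off = rng_ph.integers(0, n_ep - k + 1)
            phasic_epochs[e0 + off: e0 + off + k] = True

    rng = cfg.rng("face")
    amp = np.full(n, 0.1)
    amp[labels == "Wake"] = 1.0
    phasic_frames = phasic_epochs[np.clip(
        (np.arange(n) / rate / hyp.epoch_s).astype(int), 0, hyp.n_epochs - 1)]
    amp[(labels == "REM") & phasic_frames] = 0.8
    face = np.abs(amp * rng.standard_normal(n))

    # slow low-amplitude drift: camera-tracked eye position is smooth
    eye = _lowpass_noise(cfg.rng("eye"), n, rate, 2.0, 0.02)
    eye_events = np.asarray([]) if occ_event_times is None else np.asarray(occ_event_times)
    if eye_events.size:
        rem_mask = hyp.state_at(eye_events) == "REM"
        eye_events = eye_events[rem_mask]
        _add_gaussian_bumps(eye, eye_events, rate, 0.12, 1.0)
    return (face.astype(np.float32), eye.astype(np.float32),
            phasic_epochs, eye_events)


# ---------------------------------------------------------------------------
# Sessions

def auto_laser_schedule(cfg: SimConfig):
    """Trial onsets: fixed duration, uniform 5-7-min inter-trial intervals."""
    rng = cfg.rng("laser")
    lo, hi = cfg.trial_interval_s
    onsets = []
    t = float(rng.uniform(lo, hi))
    while len(onsets) < cfg.n_trials and t + cfg.trial_duration_s < cfg.duration_s:
        onsets.append(t)
        t += cfg.trial_duration_s + float(rng.uniform(lo, hi))
    return [(o, cfg.trial_duration_s) for o in onsets]


def _check_schedule(schedule):
    for (o1, d1), (o2, _d2) in zip(schedule, schedule[1:]):
        if o1 + d1 > o2:
            raise ValueError("overlapping laser trials")


def generate_session(cfg: SimConfig, movie=True, behavior=True):
    """Full synthetic session; returns (Recording, GroundTruth)."""
    hyp = generate_hypnogram(cfg)
    eeg, emg, lfp, pwaves = generate_polysomnography(hyp, cfg)
    gt = GroundTruth(hypnogram=hyp, pwave_times=pwaves)
    kw = dict(eeg=eeg, emg=emg, lfp=lfp, phys_rate=cfg.phys_rate,
              movie_rate=cfg.movie_rate, video_rate=cfg.video_rate,
              meta={"config": cfg.to_dict()})
    if movie:
        mov, atlas, part = generate_movie(hyp, cfg, pwaves)
        kw["movie"] = mov
        kw["meta"]["atlas"] = "synthetic"
        gt.pattern_maps = part["pattern_maps"]
        gt.pattern_coeffs = part["pattern_coeffs"]
        gt.event_times = part["event_times"]
        gt.global_trace = part["global_trace"]
        gt.bleach_trace = part["bleach_trace"]
    if behavior:
        occ_events = gt.event_times.get("occipital") if movie else None
        face, eye, phasic, eye_ev = generate_behavior(hyp, cfg, occ_events)
        kw["face"], kw["eye"] = face, eye
        gt.phasic_epochs, gt.eye_event_times = phasic, eye_ev
    return Recording(**kw), gt


def generate_opto_session(cfg: SimConfig, signals=True):
    """Laser-trial session: hazard-modulated hypnogram plus polysomnography.

    Set ``signals=False`` for hypnogram-only sessions (fast path for
    transition/bootstrap simulations, where only state labels matter).
    """
    schedule = cfg.laser_schedule if cfg.laser_schedule else auto_laser_schedule(cfg)
    if not schedule:
        raise ValueError("empty laser schedule")
    _check_schedule(schedule)
    hyp = generate_hypnogram(cfg, laser=schedule,
                             hazard_multiplier=cfg.laser_hazard_multiplier)
    gt = GroundTruth(hypnogram=hyp, laser_trials=list(schedule),
                     hazard_multiplier=cfg.laser_hazard_multiplier)
    kw = dict(laser=list(schedule), phys_rate=cfg.phys_rate,
              movie_rate=cfg.movie_rate, video_rate=cfg.video_rate,
              meta={"config": cfg.to_dict()})
    if signals:
        eeg, emg, lfp, pwaves = generate_polysomnography(hyp, cfg)
        kw.update(eeg=eeg, emg=emg, lfp=lfp)
        gt.pwave_times = pwaves
    return Recording(**kw), gt
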