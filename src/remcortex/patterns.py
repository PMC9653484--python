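"""Spatial pattern extraction: grid correlation networks, PCA, PC events.

The cortex is tiled with a fixed 16x16 patch grid for pairwise-correlation
network analysis, and decomposed by PCA into spatial patterns whose
coefficient traces carry ~1-s transient events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import cluster, ndimage, optimize, signal, spatial
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .core import EventSeries, Hypnogram, moving_average, resample_to
from .preprocess import PreprocessedMovie

GRID_N = 16                    # patches per image side
EVENT_BASELINE_S = 20.0        # moving-average baseline for event detection
EVENT_WINDOW_S = 2.0           # fit window half-width around each peak
EVENT_RATE_HZ = 5.0            # coefficient sampling rate for event analysis


@dataclass
class GridCorrelation:
    """Pairwise Pearson correlations between grid-patch traces in one state."""

    patch_ids: list               # (row, col) of each retained patch
    matrix: np.ndarray            # (patches, patches), symmetric, unit diagonal
    state: str
    clusters: np.ndarray = None   # patch -> cluster id, set by cluster_networks
    linkage: np.ndarray = None


@dataclass
class SpatialPattern:
    """A per-pixel map with its coefficient trace and explained variance."""

    map: np.ndarray               # (H, W), unit norm, masked pixels filled
    coeff: np.ndarray             # per-frame coefficient
    explained_var: float          # percent of total variance
    rate: float
    polarity: int = 1             # -1 if the component was sign-flipped
    raw_map: np.ndarray = None    # before inpainting/smoothing (NaN at mask)


def grid_correlation(pre: PreprocessedMovie, hyp: Hypnogram, state: str,
                     n_grid: int = GRID_N) -> GridCorrelation:
    """Patch-trace correlation matrix restricted to frames of one state.

    The image is divided into an ``n_grid x n_grid`` grid (patch size scales
    with the image); a patch trace is the mean dF/F0 over its analyzable
    pixels, and patches without any in-brain non-vessel pixel are dropped.
    """
    labels = hyp.frame_labels(pre.rate, pre.dff.shape[0])
    sel = labels == state
    if sel.sum() < 2 * int(hyp.epoch_s * pre.rate):
        raise ValueError(f"fewer than two {state} epochs in the recording")
    keep = pre.analysis_mask
    h, w = keep.shape
    ys = np.linspace(0, h, n_grid + 1).astype(int)
    xs = np.linspace(0, w, n_grid + 1).astype(int)
    traces, ids = [], []
    frames = pre.dff[sel]
    for i in range(n_grid):
        for j in range(n_grid):
            patch = keep[ys[i]:ys[i + 1], xs[j]:xs[j + 1]]
            if not patch.any():
                continue
            block = frames[:, ys[i]:ys[i + 1], xs[j]:xs[j + 1]]
            traces.append(block[:, patch].mean(axis=1))
            ids.append((i, j))
    mat = np.corrcoef(np.stack(traces))
    return GridCorrelation(patch_ids=ids, matrix=mat, state=state)


def cluster_networks(gc: GridCorrelation, n_groups: int = 2,
                     distance_threshold: float = None,
                     min_patches: int = 4) -> np.ndarray:
    """Agglomerative (average-linkage) grouping of grid patches.

    Distance between patches is ``1 - r`` where r is the correlation between
    their rows of the correlation matrix. The dendrogram is cut to
    ``n_groups`` (or at ``distance_threshold`` if given); groups smaller than
    ``min_patches`` are merged into the group with the highest mean
    inter-group correlation. Cluster ids are stored on ``gc.clusters``.
    """
    n = gc.matrix.shape[0]
    if n_groups > n:
        raise ValueError("more groups requested than patches")
    rows = gc.matrix
    sds = rows.std(axis=1)
    if np.all(sds == 0):          # e.g. all-ones matrix: one degenerate cluster
        gc.clusters = np.zeros(n, dtype=int)
        gc.meta_degenerate = True
        return gc.clusters
    row_corr = np.corrcoef(rows)
    dist = np.clip(1.0 - row_corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = cluster.hierarchy.linkage(spatial.distance.squareform(dist, checks=False),
                                  method="average")
    if distance_threshold is not None:
        labels = cluster.hierarchy.fcluster(Z, distance_threshold, "distance")
    else:
        labels = cluster.hierarchy.fcluster(Z, n_groups, "maxclust")
    labels = labels - labels.min()

    # merge undersized clusters into the most-correlated neighbor
    changed = True
    while changed:
        changed = False
        uniq, counts = np.unique(labels, return_counts=True)
        if uniq.size <= 1:
            break
        small = uniq[counts < min_patches]
        if small.size == 0:
            break
        cid = small[np.argmin(counts[np.isin(uniq, small)])]
        members = labels == cid
        best, best_r = None, -np.inf
        for other in uniq:
            if other == cid:
                continue
            r = gc.matrix[np.ix_(members, labels == other)].mean()
            if r > best_r:
                best_r, best = r, other
        labels[members] = best
        changed = True
    _, labels = np.unique(labels, return_inverse=True)
    gc.clusters = labels
    gc.linkage = Z
    return labels


# ---------------------------------------------------------------------------
# PCA patterns

def _diffusion_inpaint(img, fill_mask, n_iter=200, tol=1e-8):
    """Fill ``fill_mask`` pixels by iterative 4-neighborhood averaging."""
    out = img.copy()
    out[fill_mask] = img[~fill_mask].mean() if (~fill_mask).any() else 0.0
    kernel = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float) / 4.0
    for _ in range(n_iter):
        prev = out[fill_mask].copy()
        smoothed = ndimage.convolve(out, kernel, mode="nearest")
        out[fill_mask] = smoothed[fill_mask]
        if prev.size == 0 or np.max(np.abs(out[fill_mask] - prev)) < tol:
            break
    return out


def _finalize_map(vec, keep, vessel_mask, brain_mask, smooth=True):
    """Embed a component vector, inpaint vessels, smooth 5x5, brain-mask."""
    h, w = keep.shape
    img = np.zeros((h, w))
    img[keep] = vec
    raw = np.full((h, w), np.nan)
    raw[keep] = vec
    fill = vessel_mask & brain_mask if brain_mask is not None else vessel_mask
    if fill.any():
        img = _diffusion_inpaint(img, fill)
    if smooth:
        img = ndimage.uniform_filter(img, size=5)
    if brain_mask is not None:
        img[~brain_mask] = 0.0
    norm = np.linalg.norm(img)
    if norm > 0:
        img = img / norm
    return img, raw


def _fix_polarity(map_img, coeff, keep):
    s = map_img[keep].sum()
    if s == 0:
        s = map_img.flat[np.argmax(np.abs(map_img))]
    if s < 0:
        return -map_img, -coeff, -1
    return map_img, coeff, 1


class PatternPCA(BaseEstimator):
    """PCA decomposition of a preprocessed movie into spatial patterns.

    SVD runs on the (frames x analyzable-pixels) matrix with per-pixel means
    removed, optionally on temporally decimated frames (``downsample``); the
    coefficients are then projected for every selected frame at the native
    rate. Maps are inpainted over the vessel mask by diffusion, smoothed
    with a 5x5 averaging filter, brain-masked, and sign-fixed so a positive
    coefficient corresponds to a fluorescence increase.

    Fitted attributes: ``patterns_`` (list of :class:`SpatialPattern`),
    ``components_``, ``explained_var_``.
    """

    def __init__(self, n_components=5, downsample=1, smooth=True):
        self.n_components = n_components
        self.downsample = downsample
        self.smooth = smooth

    def fit(self, X: PreprocessedMovie, y=None, frame_subset=None):
        pre = X
        keep = pre.analysis_mask
        frames = np.arange(pre.dff.shape[0]) if frame_subset is None \
            else np.asarray(frame_subset)
        data = pre.dff[frames][:, keep].astype(float)
        fit_data = data[::max(int(self.downsample), 1)]
        if fit_data.shape[0] < 2:
            raise ValueError("need at least two frames for PCA")
        n_comp = min(self.n_components, *fit_data.shape)
        pca = PCA(n_components=n_comp, svd_solver="full")
        pca.fit(fit_data)
        # drop numerically-null components of rank-deficient input
        good = pca.explained_variance_ > 1e-12 * max(pca.explained_variance_[0], 1e-30)
        comps = pca.components_[good]
        evr = 100.0 * pca.explained_variance_ratio_[good]
        coeffs = (data - data.mean(axis=0)) @ comps.T
        brain = pre.region_map.brain_mask if pre.region_map is not None else None
        self.patterns_ = []
        for k in range(comps.shape[0]):
            img, raw = _finalize_map(comps[k], keep, pre.vessel_mask, brain,
                                     self.smooth)
            img, coeff, pol = _fix_polarity(img, coeffs[:, k].copy(), keep)
            raw = raw * pol
            self.patterns_.append(SpatialPattern(
                map=img, coeff=coeff, explained_var=float(evr[k]),
                rate=pre.rate, polarity=pol, raw_map=raw))
        self.components_ = comps
        self.explained_var_ = evr
        return self

    def transform(self, X: PreprocessedMovie):
        data = X.dff[:, X.analysis_mask].astype(float)
        return (data - data.mean(axis=0)) @ self.components_.T


def run_pca(pre: PreprocessedMovie, frame_subset=None, downsample: int = 1,
            n_components: int = 5, smooth: bool = True):
    """Functional wrapper over :class:`PatternPCA`; returns the pattern list."""
    est = PatternPCA(n_components=n_components, downsample=downsample,
                     smooth=smooth)
    est.fit(pre, frame_subset=frame_subset)
    return est.patterns_


# ---------------------------------------------------------------------------
# PC events

def _gauss(t, a, mu, sig, c):
    return a * np.exp(-0.5 * ((t - mu) / sig) ** 2) + c


def detect_pc_events(coeff, rate: float, threshold_sd: float = 1.0,
                     baseline_s: float = EVENT_BASELINE_S,
                     window_s: float = EVENT_WINDOW_S,
                     target_rate: float = EVENT_RATE_HZ) -> EventSeries:
    """Transient activations of a PC coefficient trace.

    The trace is resampled to 5 Hz, an adaptive baseline (20-s centered
    moving average) subtracted, and local maxima exceeding ``threshold_sd``
    SDs of the residual kept; among peaks whose +/-2-s windows overlap only
    the largest survives. Each event window is fit with a Gaussian whose
    sigma is reported as the event half-width (NaN when the fit fails).
    """
    coeff = np.asarray(coeff, dtype=float)
    if target_rate and rate != target_rate:
        coeff = resample_to(coeff, rate, target_rate)
        rate = target_rate
    resid = coeff - moving_average(coeff, int(round(baseline_s * rate)))
    sd = resid.std()
    if sd == 0:
        return EventSeries(np.array([]), pd.DataFrame(
            columns=["amplitude", "half_width_s", "fit_ok"]))
    idx, _ = signal.find_peaks(resid, height=threshold_sd * sd)
    # overlapping +/-window_s windows keep the larger peak
    order = idx[np.argsort(resid[idx])[::-1]]
    min_sep = 2 * window_s * rate
    accepted = []
    for i in order:
        if all(abs(i - j) >= min_sep for j in accepted):
            accepted.append(i)
    accepted = np.sort(np.asarray(accepted, dtype=int))

    half = int(round(window_s * rate))
    times, amps, widths, oks = [], [], [], []
    n = resid.size
    for i in accepted:
        a, b = max(i - half, 0), min(i + half + 1, n)
        t = (np.arange(a, b) - i) / rate
        y = resid[a:b]
        times.append(i / rate)
        amps.append(resid[i])
        try:
            popt, _ = optimize.curve_fit(
                _gauss, t, y, p0=(resid[i], 0.0, 0.45, 0.0),
                bounds=([0, -window_s, 1e-3, -np.inf],
                        [np.inf, window_s, 4 * window_s, np.inf]),
                maxfev=5000)
            widths.append(float(popt[2]))
            oks.append(True)
        except (RuntimeError, ValueError):
            widths.append(np.nan)
            oks.append(False)
    props = pd.DataFrame({"amplitude": amps, "half_width_s": widths,
                          "fit_ok": oks})
    return EventSeries(np.asarray(times), props)


def pc_spectrum(coeff, rate: float, fmax: float = 5.0, seg_s: float = 10.0):
    """Welch power spectrum of a coefficient trace, unit area over [0, fmax].

    Returns (freqs, power) with ``trapezoid(power, freqs) == 1``.
    """
    coeff = np.asarray(coeff, dtype=float)
    if coeff.size / rate < 60.0:
        raise ValueError("need at least 60 s of coefficient data")
    nperseg = min(coeff.size, int(round(seg_s * rate)))
    f, p = signal.welch(coeff, fs=rate, nperseg=nperseg)
    sel = f <= fmax
    f, p = f[sel], p[sel]
    area = np.trapezoid(p, f)
    if area > 0:
        p = p / area
    return f, p
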