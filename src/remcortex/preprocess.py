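"""Raw movie -> masked, global-signal-removed dF/F0 on a region map.

Fixed stage order: bleaching correction -> dF/F0 -> vessel mask -> global
signal removal (GSR). The baseline F0 is the per-pixel mean over *all*
frames of the recording; GSR regresses every pixel trace on the spatial
mean of dF/F0 (intercept included) and keeps the residual, which leaves
each pixel exactly uncorrelated with the removed global trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from sklearn.base import BaseEstimator, TransformerMixin
from skimage import filters

from .core import Hypnogram, RegionMap, STATES


@dataclass
class PreprocessedMovie:
    """dF/F0 movie plus everything removed from it."""

    dff: np.ndarray                   # (frames, H, W), float32
    rate: float
    f0: np.ndarray
    vessel_mask: np.ndarray           # True = excluded pixel
    region_map: RegionMap = None
    global_trace: np.ndarray = None
    bleach_fit: dict = None
    meta: dict = field(default_factory=dict)

    @property
    def analysis_mask(self) -> np.ndarray:
        """In-brain, non-vessel pixels."""
        brain = (self.region_map.brain_mask if self.region_map is not None
                 else np.ones(self.dff.shape[1:], bool))
        return brain & ~self.vessel_mask


def compute_dff(movie):
    """dF/F0 with F0 the per-pixel mean over all frames.

    Returns (dff, f0); raises if any pixel baseline is non-positive.
    """
    movie = np.asarray(movie)
    if movie.ndim != 3 or movie.shape[0] < 2:
        raise ValueError("movie must be (frames, H, W) with >= 2 frames")
    f0 = movie.mean(axis=0)
    n_bad = int(np.sum(f0 <= 0))
    if n_bad:
        raise ValueError(f"{n_bad} pixels have non-positive baseline F0")
    dff = (movie - f0) / f0
    return dff.astype(np.float32), f0


def _two_exp(t, a1, tau1, a2, tau2, c):
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2) + c


def correct_bleaching(movie, rate: float = 10.0):
    """Divide out a two-term exponential fit to the per-frame mean intensity.

    Returns (corrected_movie, fit) where fit records the parameters of
    ``a1*exp(-t/tau1) + a2*exp(-t/tau2) + c`` and a convergence flag. On
    fit failure the movie is returned unchanged and the flag is False.
    """
    movie = np.asarray(movie)
    m = movie.mean(axis=(1, 2)).astype(float)
    t = np.arange(m.size) / rate
    span = t[-1] if t[-1] > 0 else 1.0
    m0 = m.mean()
    drop = max(m[0] - m[-1], 1e-3 * abs(m0) + 1e-12)
    p0 = (0.5 * drop, span / 10.0, 0.5 * drop, span, m[-1])
    fit = {"a1": 0.0, "tau1": 1.0, "a2": 0.0, "tau2": 1.0, "c": float(m0),
           "converged": False}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                _two_exp, t, m, p0=p0, maxfev=20000,
                bounds=([0, 1e-6, 0, 1e-6, -np.inf],
                        [np.inf, np.inf, np.inf, np.inf, np.inf]))
        fit.update(dict(zip(("a1", "tau1", "a2", "tau2", "c"), map(float, popt))),
                   converged=True)
    except (RuntimeError, ValueError):
        warnings.warn("bleaching fit did not converge; identity correction applied")
        return movie.copy(), fit
    curve = _two_exp(t, *[fit[k] for k in ("a1", "tau1", "a2", "tau2", "c")])
    corrected = movie / (curve / curve[0])[:, None, None]
    return corrected, fit


def remove_global_signal(dff, mask=None):
    """Regress each pixel trace on the brain-wide mean trace, keep residuals.

    ``mask`` marks excluded pixels (vessels / outside brain); they do not
    enter the global trace but are residualized like any other pixel.
    Returns (dff_gsr, global_trace).
    """
    dff = np.asarray(dff, dtype=float)
    nt, h, w = dff.shape
    flat = dff.reshape(nt, -1)
    keep = np.ones(h * w, bool) if mask is None else ~np.asarray(mask).reshape(-1)
    g = flat[:, keep].mean(axis=1)
    gc = g - g.mean()
    denom = float(gc @ gc)
    if denom == 0:
        return dff.astype(np.float32), g
    beta = (gc @ (flat - flat.mean(axis=0))) / denom
    alpha = flat.mean(axis=0) - beta * g.mean()
    # float64 residuals keep the pixel-vs-global orthogonality exact
    resid = flat - np.outer(g, beta) - alpha
    return resid.reshape(nt, h, w), g


def build_vessel_mask(mean_image, sensitivity: float = 0.5, manual=None,
                      scales=(1, 2, 3), brain_mask=None):
    """Dark curvilinear structures via multiscale ridge (vesselness) filtering.

    A Sato Hessian-eigenvalue filter enhances dark ridges at ``scales``; the
    mask keeps pixels whose vesselness exceeds a local mean plus
    ``(1 - sensitivity)`` global SDs, so larger sensitivity admits more
    pixels. ``manual`` exclusion regions are OR-ed in.
    """
    img = np.asarray(mean_image, dtype=float)
    vness = filters.sato(img, sigmas=scales, black_ridges=True, mode="reflect")
    if brain_mask is not None:
        vness = vness * brain_mask
    sd = vness.std()
    if sd == 0:
        mask = np.zeros_like(vness, bool)
    else:
        local = ndimage.uniform_filter(vness, size=max(img.shape) // 8 or 1)
        mask = vness > local + (1.0 - sensitivity) * sd
    if manual is not None:
        mask |= np.asarray(manual, bool)
    ref = brain_mask if brain_mask is not None else np.ones_like(mask)
    if mask[ref > 0].mean() > 0.5:
        warnings.warn("vessel mask covers more than half of the brain pixels")
    return mask


def _binarize_outline(img):
    img = np.asarray(img, dtype=float)
    thr = 0.5 * (img.min() + img.max())
    return img > thr


def _mask_pose(mask):
    ys, xs = np.nonzero(mask)
    pts = np.c_[ys, xs].astype(float)
    centroid = pts.mean(axis=0)
    return centroid, float(len(pts))


def align_region_map(mean_image, reference: RegionMap) -> RegionMap:
    """Similarity-transform (scale/translation) alignment of the reference map.

    The brain outline of the mean image is matched to the reference brain
    mask: scale from the area ratio, translation from centroids, then a
    small grid refinement of the translation maximizing outline overlap.
    Raises if the final Jaccard overlap is below 0.5.
    """
    target = _binarize_outline(mean_image)
    if not target.any():
        raise ValueError("could not binarize a brain outline from the mean image")
    ref_mask = reference.brain_mask
    c_t, a_t = _mask_pose(target)
    c_r, a_r = _mask_pose(ref_mask)
    scale = np.sqrt(a_r / a_t)          # output->reference coordinate scale

    def transform_labels(shift):
        # output coords y -> reference coords: scale*(y - c_t - shift) + c_r
        matrix = np.diag([scale, scale])
        offset = c_r - scale * (c_t + shift)
        return ndimage.affine_transform(
            reference.label_image, matrix, offset=offset, order=0,
            output_shape=target.shape, mode="constant", cval=0)

    best, best_j = None, -1.0
    for dy in (-2, -1, 0, 1, 2):
        for dx in (-2, -1, 0, 1, 2):
            lab = transform_labels(np.array([dy, dx], float))
            got = lab > 0
            j = np.sum(got & target) / max(np.sum(got | target), 1)
            if j > best_j:
                best_j, best = j, lab
    if best_j < 0.5:
        raise ValueError(f"atlas alignment failed: Jaccard overlap {best_j:.2f} < 0.5")
    try:
        return RegionMap(best, reference.names)
    except ValueError as err:      # a region vanished under the fitted pose
        raise ValueError(f"atlas alignment failed: {err}") from err


def regional_state_activation(pre: PreprocessedMovie, hyp: Hypnogram) -> pd.DataFrame:
    """Per-state regional mean dF/F0, z-scored across the nine regions.

    Rows are the region names; columns Wake/NREM/REM. A state absent from
    the hypnogram yields a NaN column.
    """
    if pre.region_map is None:
        raise ValueError("preprocessed movie has no region map")
    labels = hyp.frame_labels(pre.rate, pre.dff.shape[0])
    names = pre.region_map.names
    out = pd.DataFrame(index=list(names), columns=list(STATES), dtype=float)
    keep = pre.analysis_mask
    for state in STATES:
        sel = labels == state
        if not sel.any():
            out[state] = np.nan
            continue
        mean_img = pre.dff[sel].mean(axis=0)
        vals = np.array([mean_img[pre.region_map.region_mask(nm) & keep].mean()
                         for nm in names])
        sd = vals.std()
        out[state] = (vals - vals.mean()) / sd if sd > 0 else 0.0
    return out


class MoviePreprocessor(BaseEstimator, TransformerMixin):
    """Transformer running the fixed preprocessing chain on a raw movie.

    Parameters
    ----------
    rate : float
        Movie frame rate in Hz.
    bleach_correct, gsr : bool
        Enable the bleaching-fit division and global signal removal.
    sensitivity : float
        Vessel-mask threshold sensitivity in [0, 1]; larger masks more.
    reference : RegionMap or None
        Reference atlas to align onto the data; None skips alignment.
    manual_mask : bool array or None
        Extra exclusion regions merged into the vessel mask.

    Fitted attributes: ``f0_``, ``mean_image_``, ``bleach_fit_``,
    ``vessel_mask_``, ``region_map_``.
    """

    def __init__(self, rate=10.0, bleach_correct=True, gsr=True,
                 sensitivity=0.5, reference=None, manual_mask=None):
        self.rate = rate
        self.bleach_correct = bleach_correct
        self.gsr = gsr
        self.sensitivity = sensitivity
        self.reference = reference
        self.manual_mask = manual_mask

    def fit(self, X, y=None):
        movie = np.asarray(X)
        if self.bleach_correct:
            movie, self.bleach_fit_ = correct_bleaching(movie, self.rate)
        else:
            self.bleach_fit_ = None
        self.f0_ = movie.mean(axis=0)
        self.mean_image_ = self.f0_
        self.region_map_ = (align_region_map(self.mean_image_, self.reference)
                            if self.reference is not None else None)
        brain = self.region_map_.brain_mask if self.region_map_ is not None else None
        self.vessel_mask_ = build_vessel_mask(
            self.mean_image_, self.sensitivity, manual=self.manual_mask,
            brain_mask=brain)
        return self

    def transform(self, X) -> PreprocessedMovie:
        movie = np.asarray(X)
        bleach_fit = getattr(self, "bleach_fit_", None)
        if self.bleach_correct and bleach_fit and bleach_fit["converged"]:
            t = np.arange(movie.shape[0]) / self.rate
            curve = _two_exp(t, *[bleach_fit[k]
                                  for k in ("a1", "tau1", "a2", "tau2", "c")])
            movie = movie / (curve / curve[0])[:, None, None]
        dff, f0 = compute_dff(movie)
        g = None
        if self.gsr:
            brain = (self.region_map_.brain_mask if self.region_map_ is not None
                     else np.zeros(dff.shape[1:], bool))
            excl = self.vessel_mask_ | ~brain if self.region_map_ is not None \
                else self.vessel_mask_
            dff, g = remove_global_signal(dff, mask=excl)
        return PreprocessedMovie(
            dff=dff, rate=self.rate, f0=f0, vessel_mask=self.vessel_mask_,
            region_map=self.region_map_, global_trace=g,
            bleach_fit=bleach_fit,
            meta={"gsr": self.gsr, "bleach_correct": self.bleach_correct})


def preprocess_movie(movie, rate=10.0, reference=None, **params) -> PreprocessedMovie:
    """One-shot convenience wrapper over :class:`MoviePreprocessor`."""
    prep = MoviePreprocessor(rate=rate, reference=reference, **params)
    return prep.fit(movie).transform(movie)
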