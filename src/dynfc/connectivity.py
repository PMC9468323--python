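"""Dynamic and static functional-connectivity features.

A subject's component (or ROI-mean) time courses are segmented by a sliding
window (default width 50 TR, step 1 TR); within each window the K x K Pearson
correlation matrix is computed with its sign kept (no Fisher transform, no
taper), and the strictly-upper-triangular entries are flattened row-major into
a feature vector of length K(K-1)/2 — 105 for K=15 components, 6670 for the
116-region AAL parcellation.  Stacking the w window vectors column-wise gives
the d x w feature sequence consumed by the sequence classifier; the static
variant is the single vector obtained from the whole time course.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "SlidingWindowPlan",
    "plan_windows",
    "postprocess_timecourses",
    "window_correlation",
    "triu_vectorize",
    "triu_unvectorize",
    "dfc_sequence",
    "static_fc",
    "roi_mean_timecourses",
    "SlidingWindowConnectivity",
]


@dataclass(frozen=True)
class SlidingWindowPlan:
    """Window layout: window j covers [j*step, j*step + width), 0-based."""
    width: int
    step: int
    count: int

    def bounds(self, j):
        if not 0 <= j < self.count:
            raise IndexError(f"window {j} out of range [0, {self.count})")
        start = j * self.step
        return start, start + self.width


def plan_windows(T, width=50, step=1):
    """Number of windows w = floor((T - width)/step) + 1."""
    if width < 2 or step < 1:
        raise ValueError("width must be >= 2 and step >= 1")
    if T < width:
        raise ValueError(f"series of length {T} shorter than window {width}")
    return SlidingWindowPlan(int(width), int(step),
                             (int(T) - int(width)) // int(step) + 1)


def postprocess_timecourses(tc, tr, band=(0.01, 0.08), nuisance=None):
    """Detrend, optionally regress out nuisance signals, band-pass filter.

    Per signal: remove the linear trend, project out ``nuisance`` columns
    (if given), then apply a zero-phase 2nd-order Butterworth band-pass
    (default 0.01-0.08 Hz, forward-backward).  Output is zero-mean per signal.

    Parameters
    ----------
    tc : (T, K) array
    tr : float
        Sampling interval in seconds.
    band : (low, high) in Hz; must lie inside (0, Nyquist).
    nuisance : optional (T, R) regressor matrix.
    """
    tc = np.asarray(tc, dtype=float)
    T = tc.shape[0]
    nyq = 0.5 / tr
    lo, hi = band
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band {band} infeasible for tr={tr} (Nyquist {nyq:g} Hz)")
    out = sps.detrend(tc, axis=0, type="linear")
    if nuisance is not None:
        X = np.column_stack([np.ones(T), np.asarray(nuisance, dtype=float)])
        beta, *_ = np.linalg.lstsq(X, out, rcond=None)
        out = out - X @ beta
    sos = sps.butter(2, [lo, hi], btype="bandpass", fs=1.0 / tr, output="sos")
    out = sps.sosfiltfilt(sos, out, axis=0)
    return out - out.mean(axis=0, keepdims=True)


def _corr_matrix(segment):
    """Pearson correlation of a (n, K) segment; constant columns give 0."""
    seg = np.asarray(segment, dtype=float)
    seg = seg - seg.mean(axis=0, keepdims=True)
    sd = seg.std(axis=0)
    bad = sd == 0
    if bad.any():
        warnings.warn("constant segment: undefined correlations set to 0",
                      RuntimeWarning, stacklevel=3)
    sd_safe = np.where(bad, 1.0, sd)
    z = seg / sd_safe
    r = (z.T @ z) / seg.shape[0]
    r[bad, :] = 0.0
    r[:, bad] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return r


def window_correlation(tc, plan, j):
    """K x K Pearson matrix of window ``j``; diagonal exactly 1, sign kept."""
    tc = np.asarray(tc, dtype=float)
    a, b = plan.bounds(j)
    return _corr_matrix(tc[a:b])


def triu_vectorize(R):
    """Strict upper triangle in row-major order (p < q); length K(K-1)/2."""
    R = np.asarray(R)
    iu = np.triu_indices(R.shape[0], k=1)
    return R[iu]


def triu_unvectorize(v, K):
    """Inverse of :func:`triu_vectorize` for a unit-diagonal symmetric matrix."""
    R = np.eye(K)
    iu = np.triu_indices(K, k=1)
    R[iu] = v
    R[(iu[1], iu[0])] = v
    return R


def dfc_sequence(tc, plan=None, width=50, step=1):
    """Dynamic connectivity feature sequence, one triu vector per window.

    Returns a (d, w) matrix, d = K(K-1)/2.  All windows are computed in one
    vectorized pass over a strided view of the series.
    """
    tc = np.asarray(tc, dtype=float)
    T, K = tc.shape
    if plan is None:
        plan = plan_windows(T, width, step)
    wins = sliding_window_view(tc, plan.width, axis=0)[::plan.step]  # (w, K, width)
    wins = wins - wins.mean(axis=2, keepdims=True)
    sd = wins.std(axis=2)
    bad = sd == 0
    if bad.any():
        warnings.warn("constant segment: undefined correlations set to 0",
                      RuntimeWarning, stacklevel=2)
    z = wins / np.where(bad, 1.0, sd)[..., None]
    r = np.einsum("wkt,wjt->wkj", z, z) / plan.width
    r[np.broadcast_to(bad[:, :, None], r.shape)] = 0.0
    r[np.broadcast_to(bad[:, None, :], r.shape)] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    iu = np.triu_indices(K, k=1)
    return r[:, iu[0], iu[1]].T


def static_fc(tc):
    """Whole-course connectivity vector (no window): triu of corr(tc)."""
    tc = np.asarray(tc, dtype=float)
    if tc.shape[0] < 2:
        raise ValueError("need at least 2 time points")
    return triu_vectorize(_corr_matrix(tc))


def roi_mean_timecourses(voxel_series, atlas_labels, background=0):
    """Average voxel series within each atlas region.

    Parameters
    ----------
    voxel_series : (T, V) array
    atlas_labels : (V,) integer array; ``background`` is ignored.

    Returns
    -------
    (T, n_regions) array ordered by ascending region id, plus the region ids.
    """
    voxel_series = np.asarray(voxel_series, dtype=float)
    atlas_labels = np.asarray(atlas_labels)
    regions = np.unique(atlas_labels)
    regions = regions[regions != background]
    out = np.empty((voxel_series.shape[0], len(regions)))
    for i, rid in enumerate(regions):
        m = atlas_labels == rid
        if not m.any():
            raise ValueError(f"atlas region {rid} covers no voxels")
        out[:, i] = voxel_series[:, m].mean(axis=1)
    return out, regions


class SlidingWindowConnectivity(BaseEstimator, TransformerMixin):
    """Transformer: component time courses -> connectivity features.

    Parameters
    ----------
    width, step : int
        Sliding-window geometry in TR units (defaults 50 and 1).
    mode : {"dynamic", "static"}
        ``dynamic`` yields a (d, w) sequence per subject, ``static`` a single
        length-d vector from the whole time course.

    The transformer is stateless; ``fit`` only validates parameters.
    """

    def __init__(self, width=50, step=1, mode="dynamic"):
        self.width = width
        self.step = step
        self.mode = mode

    def fit(self, X, y=None):
        if self.mode not in ("dynamic", "static"):
            raise ValueError("mode must be 'dynamic' or 'static'")
        if self.mode == "dynamic":
            plan_windows(max(self.width, int(np.asarray(X[0]).shape[0])),
                         self.width, self.step)
        self.n_features_in_ = np.asarray(X[0]).shape[1]
        return self

    def transform(self, X):
        if self.mode == "static":
            return [static_fc(tc) for tc in X]
        return [dfc_sequence(tc, width=self.width, step=self.step) for tc in X]
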