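"""LCMV beamforming on a toy source grid and leakage correction.

The linearly constrained minimum variance (LCMV) beamformer builds, for each
source with lead-field column ``l``, the spatial filter

    w = (l' C_r^{-1} l)^{-1} l' C_r^{-1},     C_r = C + reg * mean(diag(C)) * I

which passes the target source with unit gain (w l = 1) while minimizing
output power from everything else. Source series are aggregated into ROI
series by a sign-aligned mean (or the first principal component), and
zero-lag leakage between ROI series is removed by multivariate symmetric
orthogonalization: the closest set of mutually uncorrelated series to the
input in total squared error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import EpochedSeries, RoiSeries
from .simulate import ToyLeadField


@dataclass
class SpatialFilterSet:
    weights: np.ndarray                 # sources x sensors
    regularization: float
    covariance_window: tuple[float, float] | None = None


def sensor_covariance(x: EpochedSeries, window: tuple[float, float] | None = None) -> np.ndarray:
    """Sensor covariance pooled over all trials (and optionally a time window)."""
    data = x.data
    if window is not None:
        t = x.times
        mask = (t >= window[0]) & (t <= window[1])
        data = data[:, :, mask]
    flat = data.transpose(1, 0, 2).reshape(data.shape[1], -1)
    flat = flat - flat.mean(axis=1, keepdims=True)
    return flat @ flat.T / (flat.shape[1] - 1)


def lcmv_filters(
    lf: ToyLeadField, cov: np.ndarray, reg: float = 0.05
) -> SpatialFilterSet:
    """Unit-gain LCMV spatial filters for every source of the toy grid."""
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (lf.n_sensors, lf.n_sensors):
        raise ValueError("covariance shape does not match sensor count")
    if not np.allclose(cov, cov.T, atol=1e-10 * max(1.0, np.abs(cov).max())):
        raise ValueError("covariance must be symmetric")
    if lf.n_sensors < lf.n_sources and reg <= 0:
        raise ValueError("under-determined grid requires regularization > 0")
    c_r = cov + reg * np.mean(np.diag(cov)) * np.eye(lf.n_sensors)
    try:
        c_inv = np.linalg.inv(c_r)
    except np.linalg.LinAlgError as e:
        raise ValueError("regularized covariance is singular") from e
    weights = np.empty((lf.n_sources, lf.n_sensors))
    for s in range(lf.n_sources):
        l = lf.gain[:, s]
        if not np.any(l):
            raise ValueError(f"zero lead-field column for source {s}")
        ci_l = c_inv @ l
        weights[s] = ci_l / (l @ ci_l)
    return SpatialFilterSet(weights=weights, regularization=reg)


def apply_filters(
    x: EpochedSeries,
    filters: SpatialFilterSet,
    lf: ToyLeadField,
    aggregate: str = "sign-mean",
) -> RoiSeries:
    """Project sensor epochs to source space and aggregate per ROI.

    ``aggregate='sign-mean'``: each member source is flipped to correlate
    positively with the ROI's first principal direction, then averaged —
    beamformer source polarities are arbitrary, and averaging without
    alignment can cancel the signal. ``aggregate='pc1'`` returns the first
    principal component time course instead.
    """
    if x.n_channels != filters.weights.shape[1]:
        raise ValueError("channel count does not match filter width")
    if aggregate not in ("sign-mean", "pc1"):
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    src = np.einsum("sc,tcn->tsn", filters.weights, x.data)
    labels = tuple(lf.roi_map.keys())
    n_tr, _, n_sm = src.shape
    roi_data = np.empty((n_tr, len(labels), n_sm))
    for ri, lab in enumerate(labels):
        members = lf.roi_map[lab]
        if len(members) == 0:
            raise ValueError(f"ROI {lab!r} has no member sources")
        series = src[:, members, :]                       # trials x m x samples
        if len(members) == 1:
            roi_data[:, ri, :] = series[:, 0, :]
            continue
        flat = series.transpose(1, 0, 2).reshape(len(members), -1)
        flat_c = flat - flat.mean(axis=1, keepdims=True)
        u, _, vt = np.linalg.svd(flat_c, full_matrices=False)
        pc1 = vt[0]                                       # principal time course
        if aggregate == "pc1":
            # scale so variance matches the mean member variance
            pc1_scaled = pc1 * np.sqrt(np.mean(flat_c.var(axis=1))) / max(pc1.std(), 1e-300)
            roi_data[:, ri, :] = pc1_scaled.reshape(n_tr, n_sm)
        else:
            signs = np.sign(flat_c @ pc1)
            signs[signs == 0] = 1.0
            roi_data[:, ri, :] = np.mean(signs[None, :, None] * series, axis=1)
    return RoiSeries(roi_data, fs=x.fs, t0=x.t0, region_labels=labels)


def roi_power(x: EpochedSeries, filters: SpatialFilterSet, lf: ToyLeadField) -> dict:
    """Per-ROI source power: the average of member-source variances."""
    src = np.einsum("sc,tcn->tsn", filters.weights, x.data)
    power = src.var(axis=(0, 2))
    return {lab: float(np.mean(power[idx])) for lab, idx in lf.roi_map.items()}


def symmetric_orthogonalize(
    roi: RoiSeries, tol: float = 1e-9, max_iter: int = 100
) -> RoiSeries:
    """Closest set of mutually uncorrelated region series, symmetric in the
    regions (no seed region is privileged).

    Solves min ||X - L D||_F over matrices L with orthonormal columns and
    positive diagonal D, by alternating the closest-orthonormal-matrix step
    (polar decomposition via SVD of X D) with per-region amplitude
    rescaling, until the relative objective change falls below ``tol``.
    Series are demeaned (pooled over trials) so zero correlation equals
    orthogonality.
    """
    n_tr, n_reg, n_sm = roi.data.shape
    if n_tr * n_sm < n_reg:
        raise ValueError("need at least as many pooled samples as regions")
    X = roi.data.transpose(1, 0, 2).reshape(n_reg, -1).T   # T x regions
    X = X - X.mean(axis=0, keepdims=True)

    corr = np.corrcoef(X.T)
    ii, jj = np.triu_indices(n_reg, k=1)
    collinear = np.abs(corr[ii, jj]) > 1 - 1e-10
    if np.any(collinear) or np.linalg.matrix_rank(X) < n_reg:
        k = int(np.argmax(np.abs(corr[ii, jj])))
        a, b = roi.region_labels[ii[k]], roi.region_labels[jj[k]]
        raise ValueError(f"rank-deficient input: regions {a!r} and {b!r} are collinear")

    d = np.linalg.norm(X, axis=0)
    prev_obj = np.inf
    for _ in range(max_iter):
        u, _, vt = np.linalg.svd(X * d, full_matrices=False)
        L = u @ vt                                         # closest orthonormal frame
        d = np.einsum("ts,ts->s", X, L)                    # optimal per-region scale
        P = L * d
        obj = float(np.sum((X - P) ** 2))
        if prev_obj - obj <= tol * max(prev_obj, 1e-300):
            break
        prev_obj = obj
    out = (L * d).T.reshape(n_reg, n_tr, n_sm).transpose(1, 0, 2)
    return RoiSeries(out, fs=roi.fs, t0=roi.t0, region_labels=roi.region_labels)
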