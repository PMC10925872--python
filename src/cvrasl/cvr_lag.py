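"""CVR magnitude and hemodynamic-lag mapping, and steal segmentation.

CVR is the slope of a per-voxel linear regression of the percent-normalized
BOLD signal on the aligned PetCO2 trace (%BOLD/mmHg).  Hemodynamic lag is
found per voxel by maximizing the normalized correlation against the
regressor shifted over a lag grid at the interpolated sampling step
(sub-TR resolution); CVR is re-estimated at the optimal shift.  Vascular
steal is operationalized as a strictly negative CVR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BoldSeries

__all__ = [
    "CvrMap",
    "LagMap",
    "StealMasks",
    "fit_cvr",
    "fit_cvr_map",
    "map_hemodynamic_lag",
    "segment_steal",
]


@dataclass
class CvrMap:
    """Voxelwise CVR regression results (slope in %BOLD/mmHg)."""

    cvr: np.ndarray
    intercept: np.ndarray
    fit_r: np.ndarray
    mask: np.ndarray


@dataclass
class LagMap:
    """Voxelwise hemodynamic lag (s) and the correlation at the optimum."""

    lag: np.ndarray
    lag_corr: np.ndarray
    mask: np.ndarray


@dataclass
class StealMasks:
    """Disjoint steal / non-steal partition of the analyzed mask."""

    steal: np.ndarray
    non_steal: np.ndarray


def fit_cvr(voxel_ts: np.ndarray,
            petco2: np.ndarray,
            baseline_index: np.ndarray | None = None):
    """OLS of percent-normalized signal on the PetCO2 regressor.

    voxel_ts may be (n_t,) or (n_vox, n_t).  The series is converted to
    percent of its temporal mean, or of its mean over ``baseline_index``
    frames when given (the pre-stimulus window, which pins the normalization
    to the true baseline instead of a mean inflated by the stimulus
    response).  Returns (slope, intercept, fit_r), each scalar or (n_vox,).

    Raises on a zero-variance regressor or a non-positive normalization
    mean.
    """
    ts = np.atleast_2d(np.asarray(voxel_ts, dtype=float))
    p = np.asarray(petco2, dtype=float)
    if ts.shape[1] != p.size or p.size < 3:
        raise ValueError("series and regressor must share a length >= 3")
    p_sd = p.std()
    if p_sd == 0:
        raise ValueError("zero-variance PetCO2 regressor")
    norm = (ts.mean(axis=1) if baseline_index is None
            else ts[:, baseline_index].mean(axis=1))
    if np.any(norm <= 0):
        raise ValueError("non-positive normalization mean; cannot form percent signal")
    pct = 100.0 * ts / norm[:, None]

    p_c = p - p.mean()
    y_c = pct - pct.mean(axis=1, keepdims=True)
    denom = (p_c ** 2).sum()
    slope = y_c @ p_c / denom
    intercept = pct.mean(axis=1) - slope * p.mean()
    y_sd = y_c.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(y_sd > 0, (y_c @ p_c) / (p.size * y_sd * p_sd), 0.0)
    if np.asarray(voxel_ts).ndim == 1:
        return float(slope[0]), float(intercept[0]), float(r[0])
    return slope, intercept, r


def fit_cvr_map(bold: BoldSeries,
                petco2: np.ndarray,
                mask: np.ndarray | None = None,
                baseline_index: np.ndarray | None = None) -> CvrMap:
    """Apply :func:`fit_cvr` to every in-mask voxel of a series."""
    mask = bold.brain_mask if mask is None else np.asarray(mask, dtype=bool)
    shape = bold.data.shape[:3]
    slope, intercept, r = fit_cvr(bold.data[mask], petco2,
                                  baseline_index=baseline_index)
    out = CvrMap(cvr=np.zeros(shape), intercept=np.zeros(shape),
                 fit_r=np.zeros(shape), mask=mask)
    out.cvr[mask] = slope
    out.intercept[mask] = intercept
    out.fit_r[mask] = r
    return out


def _shift_matrix(reg: np.ndarray, steps: np.ndarray) -> np.ndarray:
    """Regressor shifted by integer grid steps with edge-hold padding."""
    n = reg.size
    idx = np.arange(n)[None, :] - steps[:, None]
    return reg[np.clip(idx, 0, n - 1)]


def map_hemodynamic_lag(bold_interp: BoldSeries,
                        regressor_interp: np.ndarray,
                        lag_range: tuple[float, float] = (-5.0, 60.0),
                        mask: np.ndarray | None = None,
                        baseline_index: np.ndarray | None = None,
                        ) -> tuple[LagMap, CvrMap]:
    """Shifted-correlation lag mapping on the interpolated grid.

    For each voxel the Pearson correlation against the regressor shifted by
    every lag on the grid (spacing = interpolated dt) is computed; the lag
    with maximal correlation wins, earliest lag on ties.  CVR is then
    re-estimated with the optimally shifted regressor.  Lag values are
    invariant to affine rescaling of the regressor.
    """
    dt = bold_interp.tr
    reg = np.asarray(regressor_interp, dtype=float)
    n_t = bold_interp.n_volumes
    if reg.size != n_t:
        raise ValueError("regressor must be on the same interpolated grid")
    span = lag_range[1] - lag_range[0]
    if span <= 0:
        raise ValueError("lag_range must be increasing")
    if span > n_t * dt / 2:
        raise ValueError("lag_range exceeds half the series duration")
    if reg.std() == 0:
        raise ValueError("zero-variance regressor")

    steps = np.arange(int(np.round(lag_range[0] / dt)),
                      int(np.round(lag_range[1] / dt)) + 1)
    lags = steps * dt
    shifted = _shift_matrix(reg, steps)  # (n_lag, n_t)
    s_sd = shifted.std(axis=1)
    s_ok = s_sd > 0
    sz = np.zeros_like(shifted)
    sz[s_ok] = ((shifted[s_ok] - shifted[s_ok].mean(axis=1, keepdims=True))
                / s_sd[s_ok, None])

    mask = bold_interp.brain_mask if mask is None else np.asarray(mask, bool)
    y = bold_interp.data[mask]
    y_sd = y.std(axis=1)
    yz = np.zeros_like(y)
    vok = y_sd > 0
    yz[vok] = (y[vok] - y[vok].mean(axis=1, keepdims=True)) / y_sd[vok, None]

    corr = yz @ sz.T / n_t          # (n_vox, n_lag)
    # peak of |r|: steal voxels respond with inverted sign and would
    # otherwise land on spurious shifts; first (= earliest lag) wins ties
    best = np.argmax(np.abs(corr), axis=1)
    lag_v = lags[best]
    corr_v = corr[np.arange(len(best)), best]

    # re-fit CVR with the per-voxel optimally shifted regressor
    slope_v = np.zeros(len(best))
    icpt_v = np.zeros(len(best))
    r_v = np.zeros(len(best))
    for b in np.unique(best):
        sel = best == b
        if shifted[b].std() == 0:
            continue
        s, i, r = fit_cvr(y[sel], shifted[b],
                          baseline_index=baseline_index)
        slope_v[sel], icpt_v[sel], r_v[sel] = s, i, r

    shape = bold_interp.data.shape[:3]
    lag_map = LagMap(lag=np.zeros(shape), lag_corr=np.zeros(shape), mask=mask)
    lag_map.lag[mask] = lag_v
    lag_map.lag_corr[mask] = corr_v
    cvr_map = CvrMap(cvr=np.zeros(shape), intercept=np.zeros(shape),
                     fit_r=np.zeros(shape), mask=mask)
    cvr_map.cvr[mask] = slope_v
    cvr_map.intercept[mask] = icpt_v
    cvr_map.fit_r[mask] = r_v
    return lag_map, cvr_map


def segment_steal(cvr: CvrMap | np.ndarray,
                  analyzed_mask: np.ndarray) -> StealMasks:
    """Partition the analyzed mask into steal (CVR < 0) and non-steal.

    A CVR of exactly zero counts as non-steal (strict reading of "negative
    CVR").  The two masks are disjoint and together cover the analyzed
    mask exactly.
    """
    analyzed_mask = np.asarray(analyzed_mask, dtype=bool)
    if not analyzed_mask.any():
        raise ValueError("empty analyzed mask")
    values = cvr.cvr if isinstance(cvr, CvrMap) else np.asarray(cvr, dtype=float)
    steal = analyzed_mask & (values < 0)
    return StealMasks(steal=steal, non_steal=analyzed_mask & ~steal)
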