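"""BOLD conditioning chain for CVR analysis.

The fixed stage order is: large-vein/noisy-voxel masking (temporal
noise-to-signal, tNSR) -> bulk alignment of the PetCO2 trace to the mean
grey-matter response -> nuisance regression (linear drift plus motion
traces correlated with the GM signal) -> per-voxel wavelet denoising ->
anisotropic Gaussian spatial smoothing -> temporal upsampling for sub-TR
lag estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy.ndimage import gaussian_filter

from .core import BoldSeries, BreathingTrace

__all__ = [
    "TnsrMask",
    "compute_tnsr_mask",
    "bulk_align_trace",
    "regress_nuisance",
    "wavelet_denoise",
    "smooth_spatial",
    "interpolate_temporal",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class TnsrMask:
    """Result of temporal noise-to-signal masking."""

    retained: np.ndarray       # boolean 3D, subset of the brain mask
    threshold_value: float     # 98th-percentile tNSR over in-mask voxels
    fraction_removed: float    # of in-mask voxels


def compute_tnsr_mask(bold: BoldSeries, percentile: float = 98.0) -> TnsrMask:
    """Remove voxels whose temporal noise-to-signal exceeds the 98th percentile.

    tSNR = temporal mean / temporal sd; tNSR = 1/tSNR = sd/mean.  Large
    draining veins and residual-motion voxels sit in the extreme tNSR tail.
    Constant voxels (sd = 0) get tNSR = 0 and are retained; voxels at or
    above the percentile threshold are removed, so exactly 2% go for
    distinct values (more only under ties at the threshold).
    """
    if bold.n_volumes < 2:
        raise ValueError("need at least two time points for tNSR")
    mask = bold.brain_mask
    if not mask.any():
        raise ValueError("empty brain mask")
    ts = bold.data[mask]
    mean = ts.mean(axis=1)
    sd = ts.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tnsr = np.where(sd == 0.0, 0.0,
                        np.where(mean == 0.0, np.inf, np.abs(sd / mean)))
    finite = tnsr[np.isfinite(tnsr)]
    if finite.size == 0:
        raise ValueError("tNSR undefined for every in-mask voxel")
    thr = float(np.percentile(finite, percentile))
    # ties at the (interpolated) threshold value are removed as well
    removed = tnsr >= thr
    retained = mask.copy()
    retained[mask] = ~removed
    return TnsrMask(retained=retained, threshold_value=thr,
                    fraction_removed=float(removed.mean()))


def bulk_align_trace(trace: BreathingTrace,
                     gm_mean_ts: np.ndarray,
                     tr: float,
                     max_shift: float = 20.0,
                     manual_shift: float | None = None,
                     search_step: float | None = None,
                     ) -> tuple[BreathingTrace, float]:
    """Align the PetCO2 trace to the mean GM BOLD response.

    A positive shift means the brain response lags the gas measurement at
    the lungs; the aligned regressor is the trace evaluated at t - shift on
    the BOLD frame grid.  If ``manual_shift`` is given it is applied as-is
    (the interactive mode used clinically); otherwise the shift maximizing
    the normalized cross-correlation over +/- ``max_shift`` is used, on a
    search grid of ``search_step`` (default tr/4, the lag-analysis grid).

    Returns (aligned trace resampled to the BOLD grid, shift in seconds).
    """
    gm = np.asarray(gm_mean_ts, dtype=float)
    if gm.ndim != 1 or gm.size < 3:
        raise ValueError("gm_mean_ts must be a 1D series of length >= 3")
    if max_shift >= trace.duration:
        raise ValueError("max_shift must be smaller than the trace duration")
    if np.std(gm) == 0:
        raise ValueError("flat GM series: correlation undefined")
    frame_t = np.arange(gm.size) * tr

    if manual_shift is not None:
        shift = float(manual_shift)
    else:
        step = search_step if search_step is not None else tr / 4.0
        # integer multiples of the step so that 0 (and grid-aligned true
        # shifts) are exactly representable
        kmax = int(np.floor(max_shift / step))
        shifts = np.arange(-kmax, kmax + 1) * step
        cand = trace.sample(frame_t[None, :] - shifts[:, None])
        sd = cand.std(axis=1)
        ok = sd > 0
        if not ok.any():
            raise ValueError("trace constant over every candidate shift")
        gz = (gm - gm.mean()) / gm.std()
        cz = (cand[ok] - cand[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
        r = cz @ gz / gm.size
        shift = float(shifts[ok][np.argmax(r)])
    aligned = BreathingTrace(time=frame_t, petco2=trace.sample(frame_t - shift))
    return aligned, shift


def regress_nuisance(bold: BoldSeries,
                     motion_traces: np.ndarray | None,
                     gm_mean_ts: np.ndarray,
                     corr_threshold: float = 0.3) -> BoldSeries:
    """GLM removal of linear drift and GM-correlated motion regressors.

    Motion traces with |Pearson r| > ``corr_threshold`` against the mean GM
    series join the design (intercept + linear drift + selected motion);
    the returned series is residual + intercept, so baseline levels survive
    for later percent normalization.  Collinear design columns are dropped
    with a warning.
    """
    n_t = bold.n_volumes
    gm = np.asarray(gm_mean_ts, dtype=float)
    if gm.size != n_t:
        raise ValueError("gm_mean_ts length must match the series")
    drift = np.linspace(-0.5, 0.5, n_t)
    cols = [np.ones(n_t), drift]
    if motion_traces is not None and len(motion_traces) > 0:
        motion = np.atleast_2d(np.asarray(motion_traces, dtype=float))
        if motion.shape[1] != n_t:
            raise ValueError("motion traces must match the series length")
        gm_c = gm - gm.mean()
        gm_n = np.linalg.norm(gm_c)
        for m in motion:
            m_c = m - m.mean()
            denom = np.linalg.norm(m_c) * gm_n
            r = 0.0 if denom == 0 else float(m_c @ gm_c / denom)
            if abs(r) > corr_threshold:
                cols.append(m)
    x = np.column_stack(cols)

    # drop collinear columns (keep earliest) via rank-revealing QR pivoting
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        warnings.warn("rank-deficient nuisance design; dropping collinear columns")
        keep: list[int] = []
        for j in range(x.shape[1]):
            trial = x[:, keep + [j]]
            if np.linalg.matrix_rank(trial) > len(keep):
                keep.append(j)
        x = x[:, keep]

    mask = bold.brain_mask
    y = bold.data[mask].T  # (n_t, n_vox)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    out = resid + beta[0][None, :]  # add the intercept back
    data = bold.data.copy()
    data[mask] = out.T
    return bold.with_data(data)


def wavelet_denoise(bold: BoldSeries,
                    wavelet: str = "sym4",
                    level: int = 4,
                    mode: str = "periodization") -> BoldSeries:
    """Per-voxel wavelet shrinkage of the BOLD time series.

    Discrete wavelet decomposition (near-symmetric 8-tap family, 4 levels),
    soft universal threshold sigma * sqrt(2 ln n) with sigma estimated per
    voxel from the median absolute deviation of the finest detail scale,
    reconstruction trimmed to the original length.  Series shorter than the
    filter support pass through with a warning.
    """
    n_t = bold.n_volumes
    w = pywt.Wavelet(wavelet)
    if n_t < w.dec_len:
        warnings.warn("series shorter than the wavelet support; pass-through")
        return bold.with_data(bold.data.copy())
    level = min(level, pywt.dwt_max_level(n_t, w.dec_len))
    if level < 1:
        warnings.warn("series too short for any decomposition level; pass-through")
        return bold.with_data(bold.data.copy())

    mask = bold.brain_mask
    y = bold.data[mask]  # (n_vox, n_t)
    coeffs = pywt.wavedec(y, w, level=level, mode=mode, axis=1)
    finest = coeffs[-1]
    sigma = np.median(np.abs(finest - np.median(finest, axis=1, keepdims=True)),
                      axis=1) / 0.6745
    thr = sigma * np.sqrt(2.0 * np.log(n_t))
    denoised = [coeffs[0]]
    for d in coeffs[1:]:
        mag = np.abs(d) - thr[:, None]
        denoised.append(np.sign(d) * np.maximum(mag, 0.0))
    rec = pywt.waverec(denoised, w, mode=mode, axis=1)[:, :n_t]
    data = bold.data.copy()
    data[mask] = rec
    return bold.with_data(data)


def smooth_spatial(bold: BoldSeries,
                   fwhm_mm: tuple[float, float, float] = (4.0, 4.0, 7.0),
                   renormalize_in_mask: bool = True) -> BoldSeries:
    """Anisotropic 3D Gaussian smoothing of every volume.

    The kernel FWHM is specified in mm (default 4 x 4 x 7, matching the
    effective ASL resolution) and converted to voxels via the stored voxel
    size.  With ``renormalize_in_mask`` the volume is zero-padded outside
    the brain and the result divided by the smoothed mask, so edge voxels
    are proper averages of brain signal only; without it, plain
    zero-padding preserves the global sum (normalized kernel).
    """
    if bold.voxel_size is None or any(v <= 0 for v in bold.voxel_size):
        raise ValueError("voxel size required for mm-specified smoothing")
    sigma_vox = tuple(f * FWHM_TO_SIGMA / v for f, v in zip(fwhm_mm, bold.voxel_size))
    sigmas = sigma_vox + (0.0,)  # never smooth along time

    if renormalize_in_mask:
        mask = bold.brain_mask.astype(float)
        sm_mask = gaussian_filter(mask, sigma=sigma_vox, mode="constant")
        num = gaussian_filter(bold.data * mask[..., None], sigma=sigmas,
                              mode="constant")
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where((sm_mask > 1e-8)[..., None],
                           num / np.maximum(sm_mask, 1e-8)[..., None], 0.0)
        out[~bold.brain_mask] = 0.0
    else:
        out = gaussian_filter(bold.data, sigma=sigmas, mode="constant")
    return bold.with_data(out)


def interpolate_temporal(data: np.ndarray | BoldSeries,
                         factor: int = 4,
                         tr: float | None = None):
    """Linear upsampling onto a grid with spacing tr/factor.

    Original grid nodes are preserved exactly.  Accepts a BoldSeries (the
    time axis is last) or a bare 1D/ND array; returns the same kind.  The
    output has (n - 1) * factor + 1 samples spanning the original window.
    """
    if not (isinstance(factor, (int, np.integer)) and factor >= 1):
        raise ValueError("factor must be an integer >= 1")
    if isinstance(data, BoldSeries):
        new = interpolate_temporal(data.data, factor=factor)
        return BoldSeries(new, data.tr / factor, data.voxel_size, data.brain_mask)
    arr = np.asarray(data, dtype=float)
    if factor == 1:
        return arr.copy()
    n = arr.shape[-1]
    if n < 2:
        raise ValueError("need at least two samples to interpolate")
    old = np.arange(n, dtype=float)
    new = np.arange((n - 1) * factor + 1, dtype=float) / factor
    flat = arr.reshape(-1, n)
    out = np.empty((flat.shape[0], new.size))
    for i, row in enumerate(flat):
        out[i] = np.interp(new, old, row)
    return out.reshape(arr.shape[:-1] + (new.size,))
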