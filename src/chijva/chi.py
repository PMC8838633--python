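"""Venous attenuation extraction from near-infrared neck video.

The processing order is fixed: 4x4 mean down-sampling -> reflectance
calibration to optical attenuation -> per-pixel Kalman temporal denoising ->
PPG anticorrelation mapping -> connected-component localization of the
jugular region inferior to the neck midline -> per-frame mean attenuation
over the region, with the per-acquisition peak retained as the JVA outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as spsig
from skimage import measure as skmeasure

from .optics import FrameStack, ReferenceSignals

__all__ = [
    "AttenuationStack",
    "CorrelationMap",
    "VenousROI",
    "JvaResult",
    "downsample_4x4",
    "kalman_denoise",
    "calibrate_attenuation",
    "bandpass_cardiac",
    "correlation_map",
    "localize_ijv",
    "extract_jva",
    "process_stack",
]


@dataclass
class AttenuationStack:
    """T x h x w optical attenuation (a.u.); invalid pixels are NaN."""

    data: np.ndarray
    fs: float

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.data).all(axis=0)


@dataclass
class CorrelationMap:
    """Per-pixel Pearson correlation of attenuation against the PPG."""

    r: np.ndarray
    valid_mask: np.ndarray


@dataclass
class VenousROI:
    """One contiguous down-sampled region attributed to the jugular vein."""

    pixels: np.ndarray  # boolean mask, h x w

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())


@dataclass
class JvaResult:
    """Per-frame mean attenuation over the venous ROI, and its peak."""

    series: np.ndarray
    peak: float


def downsample_4x4(stack: FrameStack) -> FrameStack:
    """4x4 mean pixel down-sampling; trailing rows/cols not filling a block drop."""
    t, h, w = stack.data.shape
    if h < 4 or w < 4:
        raise ValueError("frames must be at least 4 x 4 pixels")
    hb, wb = h // 4, w // 4
    d = stack.data[:, : hb * 4, : wb * 4].reshape(t, hb, 4, wb, 4).mean(axis=(2, 4))
    return FrameStack(
        data=d, fs=stack.fs, illum_intensity=stack.illum_intensity, metadata=dict(stack.metadata)
    )


def kalman_denoise(series: np.ndarray, process_var: float = 1e-3, meas_var: float = 1e-3) -> np.ndarray:
    """Scalar local-level Kalman filter along the time axis (axis 0).

    The state is a slowly varying per-pixel attenuation level; the gain
    sequence depends only on the two variances, so the filter vectorizes
    over pixels.  ``process_var/meas_var`` sets the bandwidth: the default
    ratio of 1 gives a steady-state gain of ~0.62, which passes the cardiac
    band at video frame rates while roughly halving white-noise variance.
    """
    if meas_var <= 0:
        raise ValueError("meas_var must be positive")
    if process_var < 0:
        raise ValueError("process_var must be non-negative")
    z = np.asarray(series, dtype=float)
    out = np.empty_like(z)
    out[0] = z[0]
    p = meas_var
    x = z[0]
    for i in range(1, z.shape[0]):
        p_pred = p + process_var
        k = p_pred / (p_pred + meas_var)
        x = x + k * (z[i] - x)
        p = (1.0 - k) * p_pred
        out[i] = x
    return out


def calibrate_attenuation(stack: FrameStack, target_mask: np.ndarray, r_ref: float) -> AttenuationStack:
    """Attenuation A = -log10(I / I0_hat) with I0_hat from the reflectance patch.

    I0_hat is the per-frame mean intensity over the calibration patch divided
    by its known reflectance.  Non-positive intensities map to NaN and are
    excluded from the valid mask.
    """
    target_mask = np.asarray(target_mask, dtype=bool)
    if target_mask.shape != stack.data.shape[1:]:
        raise ValueError("target mask must match the frame shape")
    if not target_mask.any():
        raise ValueError("target region is empty")
    tvals = stack.data[:, target_mask]
    i0 = tvals.mean(axis=1) / r_ref
    if np.any(i0 <= 0):
        raise ValueError("calibration target intensities are non-positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        a = -np.log10(stack.data / i0[:, None, None])
    a[stack.data <= 0] = np.nan
    return AttenuationStack(data=a, fs=stack.fs)


def bandpass_cardiac(x: np.ndarray, fs: float, lo: float = 0.7, hi: float = 3.0) -> np.ndarray:
    """Zero-phase band-pass to the cardiac band; reduces respiratory leakage."""
    hi = min(hi, 0.45 * fs)
    if hi <= lo:
        return np.asarray(x, dtype=float)
    sos = spsig.butter(3, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return spsig.sosfiltfilt(sos, x, axis=0)


def correlation_map(atten: AttenuationStack, ppg: np.ndarray, prefilter_ppg: bool = True) -> CorrelationMap:
    """Pearson correlation of every pixel's attenuation series against the PPG."""
    ppg = np.asarray(ppg, dtype=float)
    t = atten.data.shape[0]
    if len(ppg) != t:
        raise ValueError("PPG and attenuation stack lengths differ")
    if t < 30:
        raise ValueError("need at least 30 frames for a stable correlation map")
    if prefilter_ppg:
        ppg = bandpass_cardiac(ppg, atten.fs)
    a = atten.data
    valid = np.isfinite(a).all(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ac = a - np.nanmean(a, axis=0)
    asd = np.sqrt(np.nansum(ac**2, axis=0))
    pc = ppg - ppg.mean()
    psd = np.sqrt((pc**2).sum())
    valid &= (asd > 0) & (psd > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.einsum("t,thw->hw", pc, np.nan_to_num(ac)) / (asd * psd)
    r[~valid] = np.nan
    r = np.clip(r, -1.0, 1.0)
    return CorrelationMap(r=r, valid_mask=valid)


def localize_ijv(
    cmap: CorrelationMap,
    midline_row: int,
    r_threshold: float = -0.3,
    connectivity: int = 2,
    max_extent_px: int | None = None,
    axis: int = 1,
) -> VenousROI | None:
    """Largest contiguous anticorrelated region strictly inferior to the midline.

    Ties between equal-sized components break deterministically toward the
    component containing the smallest row-major coordinate.  When
    ``max_extent_px`` is given, the region is trimmed along ``axis`` (the
    vessel axis) to that many pixels centered on the component centroid,
    emulating extraction from a fixed ~1 cm vessel segment.  Returns ``None``
    when no pixel qualifies.
    """
    h, w = cmap.r.shape
    if not (0 <= midline_row < h):
        raise ValueError("midline_row out of bounds")
    cand = np.zeros((h, w), dtype=bool)
    with np.errstate(invalid="ignore"):
        cand = (cmap.r < r_threshold) & cmap.valid_mask
    cand[: midline_row + 1, :] = False
    if not cand.any():
        return None
    labels = skmeasure.label(cand, connectivity=connectivity)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    best_size = sizes.max()
    tied = np.flatnonzero(sizes == best_size)
    if len(tied) > 1:
        first = {lab: np.argmax(labels.ravel() == lab) for lab in tied}
        best = min(tied, key=lambda lab: first[lab])
    else:
        best = tied[0]
    mask = labels == best
    if max_extent_px is not None:
        coords = np.nonzero(mask)[axis]
        center = coords.mean()
        half = max_extent_px / 2.0
        keep_idx = np.arange(mask.shape[axis])
        keep = (keep_idx >= np.ceil(center - half)) & (keep_idx < np.ceil(center + half))
        sl = [slice(None)] * 2
        sl[axis] = ~keep
        mask[tuple(sl)] = False
    return VenousROI(pixels=mask)


def extract_jva(atten: AttenuationStack, roi: VenousROI) -> JvaResult:
    """Per-frame mean attenuation over the ROI; the acquisition peak is the JVA."""
    if roi is None or roi.area_px == 0:
        raise ValueError("ROI is empty")
    if roi.pixels.shape != atten.data.shape[1:]:
        raise ValueError("ROI shape does not match the attenuation stack")
    series = atten.data[:, roi.pixels].mean(axis=1)
    return JvaResult(series=series, peak=float(series.max()))


def process_stack(
    stack: FrameStack,
    signals: ReferenceSignals,
    target_mask: np.ndarray,
    r_ref: float,
    midline_row: int,
    r_threshold: float = -0.3,
    process_var: float = 1e-3,
    meas_var: float = 1e-3,
    max_extent_px: int | None = None,
    roi: VenousROI | None = None,
    connectivity: int = 2,
):
    """Full extraction chain on one full-resolution acquisition.

    ``target_mask`` and ``midline_row`` are given in full-resolution
    coordinates and are mapped onto the down-sampled grid here.  An ROI from
    a previous acquisition of the same participant may be supplied to hold
    the extraction segment fixed across condition levels.

    Returns ``(JvaResult | None, VenousROI | None, CorrelationMap,
    AttenuationStack)``; the first two are None when no venous region is
    found.
    """
    ds = downsample_4x4(stack)
    h4, w4 = ds.data.shape[1:]
    tm = np.asarray(target_mask, dtype=bool)
    tm4 = tm[: h4 * 4, : w4 * 4].reshape(h4, 4, w4, 4).mean(axis=(1, 3)) == 1.0
    atten = calibrate_attenuation(ds, tm4, r_ref)
    atten = AttenuationStack(data=kalman_denoise(atten.data, process_var, meas_var), fs=atten.fs)
    cmap = correlation_map(atten, signals.ppg)
    if roi is None:
        roi = localize_ijv(
            cmap,
            midline_row // 4,
            r_threshold=r_threshold,
            connectivity=connectivity,
            max_extent_px=max_extent_px,
        )
    if roi is None:
        return None, None, cmap, atten
    return extract_jva(atten, roi), roi, cmap, atten
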