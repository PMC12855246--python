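"""Quantitative relaxometry: T2 (and R2 = 1/T2) and ADC parameter maps.

Both fits assume a mono-exponential signal model,

    T2 :  S(TE) = S0 * exp(-TE / T2)
    ADC:  S(b)  = S0 * exp(-b * ADC)

and estimate the decay rate by ordinary least squares on the
log-transformed signal.  The log-linear fit is closed-form and
deterministic; an optional Levenberg-Marquardt refinement on the raw
signal is available for users who prefer a nonlinear fit.

Voxels with any non-positive signal sample, or whose fitted decay rate is
non-positive (e.g. constant or rising signal), are flagged invalid and
excluded from the validity mask rather than silently clipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .volume import DWISeries, EchoSeries, QuantVolume

__all__ = ["ParamMaps", "fit_t2", "fit_adc", "fit_param_maps"]

log = logging.getLogger(__name__)


@dataclass
class ParamMaps:
    """Bundle of quantitative maps on a common grid.

    ``r2_per_ms`` is the reciprocal of ``t2_ms`` wherever the fit is
    valid; elsewhere all maps are zero and ``fit_validity_mask`` is False.
    """

    t2_ms: QuantVolume
    r2_per_ms: QuantVolume
    adc_mm2_s: QuantVolume
    fit_validity_mask: np.ndarray


def _loglinear_rate(signal: np.ndarray, x: np.ndarray, mask: np.ndarray | None):
    """Per-voxel OLS slope of log(S) against x; returns (rate, s0, valid).

    ``rate`` is the positive decay constant (1/T2 in 1/ms, or ADC in
    mm²/s), i.e. minus the fitted slope.
    """
    signal = np.asarray(signal, dtype=np.float64)
    nvox_shape = signal.shape[:3]
    if mask is None:
        mask = np.ones(nvox_shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != nvox_shape:
            raise ValueError(f"mask shape {mask.shape} != volume shape {nvox_shape}")

    rate = np.zeros(nvox_shape)
    s0 = np.zeros(nvox_shape)
    valid = np.zeros(nvox_shape, dtype=bool)

    positive = np.all(signal > 0, axis=3)
    fit_mask = mask & positive
    if not fit_mask.any():
        log.warning("log-linear fit: no voxel has all-positive signal inside the mask")
        return rate, s0, valid

    y = np.log(signal[fit_mask])  # (n_vox, n_obs)
    x = np.asarray(x, dtype=np.float64)
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    slope = y @ xc / denom
    intercept = y.mean(axis=1) - slope * x.mean()

    vox_rate = -slope
    ok = vox_rate > 0
    rate[fit_mask] = np.where(ok, vox_rate, 0.0)
    s0[fit_mask] = np.where(ok, np.exp(intercept), 0.0)
    v = np.zeros(ok.shape, dtype=bool)
    v[:] = ok
    valid[fit_mask] = v
    return rate, s0, valid


def _nonlinear_refine(signal: np.ndarray, x: np.ndarray, rate: np.ndarray,
                      s0: np.ndarray, valid: np.ndarray) -> None:
    """In-place Levenberg-Marquardt refinement seeded from the log-linear fit."""

    def model(xv, a, r):
        return a * np.exp(-r * xv)

    idx = np.argwhere(valid)
    for i, j, k in idx:
        y = signal[i, j, k]
        try:
            popt, _ = curve_fit(model, x, y, p0=(s0[i, j, k], rate[i, j, k]), maxfev=200)
        except RuntimeError:  # pragma: no cover - non-convergent voxel
            continue
        if popt[1] > 0:
            s0[i, j, k], rate[i, j, k] = popt


def fit_t2(series: EchoSeries, mask: np.ndarray | None = None,
           nonlinear: bool = False) -> tuple[QuantVolume, np.ndarray]:
    """Fit T2 (ms) per voxel from a multi-echo series.

    Returns the T2 map and a boolean validity mask.  Invalid voxels
    (non-positive signal anywhere along TE, or non-decaying fit) carry 0.
    """
    x = np.asarray(series.te_list_ms)
    rate, s0, valid = _loglinear_rate(series.signal, x, mask)
    if nonlinear:
        _nonlinear_refine(series.signal, x, rate, s0, valid)
    t2 = np.zeros_like(rate)
    t2[valid] = 1.0 / rate[valid]
    return QuantVolume(t2, series.spacing), valid


def fit_adc(series: DWISeries, mask: np.ndarray | None = None,
            nonlinear: bool = False) -> tuple[QuantVolume, np.ndarray]:
    """Fit ADC (mm²/s) per voxel from a multi-b DWI series."""
    x = np.asarray(series.b_values)
    rate, s0, valid = _loglinear_rate(series.signal, x, mask)
    if nonlinear:
        _nonlinear_refine(series.signal, x, rate, s0, valid)
    adc = np.where(valid, rate, 0.0)
    return QuantVolume(adc, series.spacing), valid


def fit_param_maps(echo: EchoSeries, dwi: DWISeries,
                   mask: np.ndarray | None = None) -> ParamMaps:
    """Fit T2, R2 = 1/T2 and ADC on a shared grid.

    The combined validity mask requires both fits to succeed in a voxel.
    """
    if echo.signal.shape[:3] != dwi.signal.shape[:3]:
        raise ValueError("echo and DWI series must share a voxel grid")
    t2, t2_valid = fit_t2(echo, mask)
    adc, adc_valid = fit_adc(dwi, mask)
    valid = t2_valid & adc_valid
    r2 = np.zeros_like(t2.data)
    r2[valid] = 1.0 / t2.data[valid]
    t2_out = np.where(valid, t2.data, 0.0)
    adc_out = np.where(valid, adc.data, 0.0)
    return ParamMaps(
        t2_ms=QuantVolume(t2_out, echo.spacing),
        r2_per_ms=QuantVolume(r2, echo.spacing),
        adc_mm2_s=QuantVolume(adc_out, dwi.spacing),
        fit_validity_mask=valid,
    )
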