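"""Segmented IVIM fitting of multi-b-value diffusion MRI.

The intravoxel-incoherent-motion (IVIM) signal model is bi-exponential,

    S(b) = S0 * [ f * exp(-b * D*) + (1 - f) * exp(-b * D) ],

with tissue diffusion coefficient D, perfusion fraction f (the fractional
blood volume, fBV) and pseudo-diffusion coefficient D* >> D.  The segmented
(two-step) estimator exploits that the perfusion compartment has decayed at
high b: a log-linear fit over b >= b_threshold yields D and an extrapolated
intercept S0', and f = 1 - S0'/S(0).  D* itself is not estimated.

ADC/D values are in 1e-6 mm^2/s; b-values in s/mm^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import ADC_UNIT, AdcVolume, ProstateMask, Spacing

__all__ = ["DwiSeries", "IvimMaps", "simulate_ivim_signal", "fit_segmented_ivim"]


@dataclass
class DwiSeries:
    """A multi-b-value DWI acquisition: one 3-D signal volume per b-value."""

    volumes: np.ndarray  # (nb, nx, ny, nz)
    b_values: np.ndarray  # (nb,), s/mm^2, strictly increasing, first = 0
    spacing: Spacing

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.b_values = np.asarray(self.b_values, dtype=float)
        if self.volumes.ndim != 4:
            raise ValueError("volumes must be a (nb, nx, ny, nz) array")
        if self.b_values.ndim != 1 or len(self.b_values) != self.volumes.shape[0]:
            raise ValueError("need exactly one b-value per volume")
        if len(self.b_values) < 3:
            raise ValueError("segmented IVIM needs at least 3 b-values")
        if self.b_values[0] != 0:
            raise ValueError("the first b-value must be 0")
        if np.any(np.diff(self.b_values) <= 0):
            raise ValueError("b-values must be strictly increasing")
        if np.any(self.volumes < 0):
            raise ValueError("signals must be nonnegative")
        self.spacing = tuple(float(s) for s in self.spacing)


@dataclass
class IvimMaps:
    """Fitted maps: ADC (= D, in 1e-6 mm^2/s), fBV (= f, in [0, 1]), validity."""

    adc: AdcVolume
    fbv: np.ndarray
    valid: np.ndarray


def simulate_ivim_signal(
    adc: AdcVolume,
    fbv_grid,
    pseudo_diffusion: float,
    b_values,
    s0: float = 1000.0,
) -> DwiSeries:
    """Noiseless forward bi-exponential IVIM signal for testing the fitter.

    ``pseudo_diffusion`` (D*) is in the same 1e-6 mm^2/s unit as the ADC
    grid and must exceed every ADC value.
    """
    f = np.asarray(fbv_grid, dtype=float)
    if f.shape != adc.shape:
        raise ValueError("fBV grid must match the ADC grid")
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("perfusion fraction must lie in [0, 1]")
    if pseudo_diffusion <= np.max(adc.data):
        raise ValueError("pseudo-diffusion D* must exceed the tissue ADC")
    b = np.asarray(b_values, dtype=float)
    if b[0] != 0:
        raise ValueError("the first b-value must be 0")
    d = adc.data * ADC_UNIT
    dstar = pseudo_diffusion * ADC_UNIT
    sig = np.empty((len(b),) + adc.shape)
    for i, bv in enumerate(b):
        sig[i] = s0 * (f * np.exp(-bv * dstar) + (1 - f) * np.exp(-bv * d))
    return DwiSeries(sig, b, adc.spacing)


def fit_segmented_ivim(
    dwi: DwiSeries,
    mask: ProstateMask,
    b_threshold: float = 200.0,
    b_max: float = 1000.0,
) -> IvimMaps:
    """Two-step segmented IVIM fit inside a prostate mask.

    Per masked voxel: (1) ordinary least squares of log S against b over
    b_threshold <= b <= b_max gives D (negative slope) and an intercept
    log S0'; (2) f = 1 - S0'/S(0), clipped to [0, 1].  Voxels with
    S(0) <= 0 or any non-positive high-b signal are flagged invalid rather
    than silently zeroed.  Very high b-values (> b_max, e.g. 1400-2000
    acquisitions) are excluded to avoid non-Gaussian diffusion bias.

    Raises
    ------
    ValueError
        If fewer than two b-values fall in the fitting range, making the
        line fit underdetermined for every voxel.
    """
    if mask.shape != dwi.volumes.shape[1:]:
        raise ValueError("mask grid must match the DWI grid")
    b = dwi.b_values
    high = (b >= b_threshold) & (b <= b_max)
    if high.sum() < 2:
        raise ValueError(
            f"need >= 2 b-values in [{b_threshold}, {b_max}] for the segmented fit"
        )
    bh = b[high]
    m = mask.data
    s0_meas = dwi.volumes[0][m]  # b = 0 by construction
    sig_high = dwi.volumes[high][:, m]  # (n_high, n_vox)

    valid_vox = (s0_meas > 0) & np.all(sig_high > 0, axis=0)
    logs = np.full_like(sig_high, np.nan)
    logs[:, valid_vox] = np.log(sig_high[:, valid_vox])

    # closed-form OLS of log-signal on b, shared design across voxels
    bbar = bh.mean()
    denom = float(np.sum((bh - bbar) ** 2))
    slope = np.nansum((bh - bbar)[:, None] * logs, axis=0) / denom
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN invalid voxels
        intercept = np.nanmean(logs, axis=0) - slope * bbar

    d = -slope / ADC_UNIT  # 1e-6 mm^2/s
    with np.errstate(over="ignore", invalid="ignore"):
        f = 1.0 - np.exp(intercept) / s0_meas
    f = np.clip(f, 0.0, 1.0)

    finite = np.isfinite(d) & np.isfinite(f) & (d >= 0)
    valid_vox &= finite

    adc_grid = np.full(mask.shape, np.nan)
    fbv_grid = np.full(mask.shape, np.nan)
    valid_grid = np.zeros(mask.shape, dtype=bool)
    idx = np.where(m)
    adc_grid[idx] = np.where(valid_vox, d, np.nan)
    fbv_grid[idx] = np.where(valid_vox, f, np.nan)
    valid_grid[idx] = valid_vox
    return IvimMaps(
        adc=AdcVolume(adc_grid, dwi.spacing),
        fbv=fbv_grid,
        valid=valid_grid,
    )
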