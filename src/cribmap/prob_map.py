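"""Multi-scale sliding-window inference of cribriform probability maps.

The engine slides square in-plane windows of several sizes (default 5, 7, 9,
11 and 13 voxels) over every slice of an ADC map with stride 1.  Each window
that lies fully inside the slice and covers at least ``min_mask_fraction``
of prostate voxels contributes: its feature is the 90th-percentile ADC over
the in-mask voxels it contains, converted to a cribriform probability by the
logistic model.  Overlapping predictions are consolidated by maximum
projection, in one of two flavours:

* ``cover``  — a voxel takes the maximum probability over *all* valid
  windows of any size that contain it (the default);
* ``center`` — a voxel takes the maximum over the (at most 5) valid windows
  centred on it.

Centred windows are a subset of covering windows, so cover-mode values
dominate center-mode values voxel-wise.  The patient-level score is the
maximum defined voxel probability, and patients are called positive when
that score strictly exceeds a chosen threshold.
"""

from __future__ import annotations

import warnings

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .model import LogisticCribModel
from .types import AdcVolume, ProbabilityMap, PatientScore, ProstateMask

__all__ = [
    "DEFAULT_WINDOW_SIZES",
    "sliding_window_map",
    "patient_score",
    "classify_patient",
]

DEFAULT_WINDOW_SIZES = (5, 7, 9, 11, 13)


def _window_probabilities(
    adc_slice: np.ndarray,
    mask_slice: np.ndarray,
    model: LogisticCribModel,
    w: int,
    min_mask_fraction: float,
):
    """Probability and validity for every w-window position on one slice.

    Returns arrays of shape (nx - w + 1, ny - w + 1) indexed by the window's
    top-left corner; invalid positions hold NaN/False.
    """
    nx, ny = adc_slice.shape
    if w > nx or w > ny:
        return None, None
    masked = np.where(mask_slice, adc_slice, np.nan)
    views = sliding_window_view(masked, (w, w))  # (nx-w+1, ny-w+1, w, w)
    in_mask = sliding_window_view(mask_slice, (w, w)).sum(axis=(2, 3))
    valid = in_mask >= min_mask_fraction * w * w
    # need >= 1 in-mask voxel for the percentile even at fraction 0
    valid &= in_mask > 0
    probs = np.full(valid.shape, np.nan)
    if valid.any():
        # vectorised linear-interpolation p90 over the in-mask voxels of each
        # valid window: sort pushes the NaN (out-of-mask) entries to the end,
        # then gather at the fractional position 0.9 * (n_in - 1)
        vals = np.sort(views[valid].reshape(-1, w * w), axis=1)
        pos = 0.9 * (in_mask[valid] - 1)
        lo = np.floor(pos).astype(int)
        hi = np.ceil(pos).astype(int)
        frac = pos - lo
        rows = np.arange(vals.shape[0])
        p90 = vals[rows, lo] * (1 - frac) + vals[rows, hi] * frac
        probs[valid] = model.predict(p90)
    return probs, valid


def sliding_window_map(
    adc: AdcVolume,
    mask: ProstateMask,
    model: LogisticCribModel,
    window_sizes=DEFAULT_WINDOW_SIZES,
    aggregation: str = "cover",
    min_mask_fraction: float = 0.5,
) -> ProbabilityMap:
    """Voxel-wise cribriform probability map by sliding-window max-projection.

    Parameters
    ----------
    adc, mask
        Aligned ADC volume and (already eroded) prostate mask.
    model
        The fitted single-feature logistic model.
    window_sizes
        Odd in-plane window edge lengths in voxels, each >= 3.
    aggregation
        ``"cover"`` or ``"center"`` (see module docstring).
    min_mask_fraction
        Minimum fraction of window voxels that must be inside the mask for
        the window to contribute; the percentile always uses in-mask voxels
        only.

    Returns
    -------
    ProbabilityMap
        Defined (valid) exactly on mask voxels touched by at least one valid
        window; NaN elsewhere.
    """
    if adc.shape != mask.shape:
        raise ValueError("ADC and mask grids must share a shape")
    if mask.is_empty():
        raise ValueError("cannot run inference on an empty prostate mask")
    if aggregation not in ("cover", "center"):
        raise ValueError("aggregation must be 'cover' or 'center'")
    sizes = tuple(int(w) for w in window_sizes)
    if not sizes or any(w < 3 or w % 2 == 0 for w in sizes):
        raise ValueError("window sizes must be odd and >= 3")
    if not 0.0 <= min_mask_fraction <= 1.0:
        raise ValueError("min_mask_fraction must lie in [0, 1]")

    nx, ny, nz = adc.shape
    best = np.full((nx, ny, nz), -np.inf)
    touched = np.zeros((nx, ny, nz), dtype=bool)

    for z in range(nz):
        mask_slice = mask.data[:, :, z]
        if not mask_slice.any():
            continue
        adc_slice = adc.data[:, :, z]
        for w in sizes:
            probs, valid = _window_probabilities(
                adc_slice, mask_slice, model, w, min_mask_fraction
            )
            if probs is None or not valid.any():
                continue
            if aggregation == "center":
                # window at top-left (i, j) is centred on (i + r, j + r)
                r = w // 2
                centre_view = best[r : nx - r, r : ny - r, z]
                np.maximum(
                    centre_view,
                    np.where(valid, probs, -np.inf),
                    out=centre_view,
                )
                touched[r : nx - r, r : ny - r, z] |= valid
            else:
                # voxel (i, j) is covered by windows whose top-left corner is
                # within [i-w+1, i] x [j-w+1, j]: a w x w maximum filter over
                # the position grid, anchored so the filter footprint ends at
                # the voxel.
                padded = np.full((nx, ny), -np.inf)
                padded[: probs.shape[0], : probs.shape[1]] = np.where(
                    valid, probs, -np.inf
                )
                r = w // 2
                covermax = ndimage.maximum_filter(
                    padded, size=w, mode="constant", cval=-np.inf, origin=(r, r)
                )
                np.maximum(best[:, :, z], covermax, out=best[:, :, z])
                padded_touch = np.zeros((nx, ny), dtype=bool)
                padded_touch[: valid.shape[0], : valid.shape[1]] = valid
                touched[:, :, z] |= (
                    ndimage.maximum_filter(
                        padded_touch, size=w, mode="constant", cval=0, origin=(r, r)
                    )
                    > 0
                )

    defined = touched & mask.data
    if not defined.any():
        warnings.warn(
            "no valid windows: mask is thinner than the smallest window at "
            "the requested mask fraction; returning an empty-validity map",
            RuntimeWarning,
            stacklevel=2,
        )
    values = np.where(defined, best, np.nan)
    return ProbabilityMap(
        values=values,
        valid=defined,
        spacing=adc.spacing,
        window_sizes=sizes,
        model_tag=f"logistic:{model.intercept:g},{model.slope:g}",
    )


def patient_score(pmap: ProbabilityMap, patient_id: str = "") -> PatientScore:
    """Patient-level score: the maximum probability over defined voxels."""
    if pmap.n_defined == 0:
        raise ValueError("probability map has no defined voxels")
    return PatientScore(patient_id=patient_id, score=float(np.nanmax(pmap.values[pmap.valid])))


def classify_patient(score: PatientScore | float, threshold: float) -> bool:
    """Positive (predicted cribriform) iff the score strictly exceeds the threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    s = score.score if isinstance(score, PatientScore) else float(score)
    return s > threshold
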