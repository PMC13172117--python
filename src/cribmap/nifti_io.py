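"""Reading and writing pipeline grids as NIfTI, via nibabel.

Grids are stored with the package's (x, y, z) axis order mapped directly to
NIfTI's first three dimensions, and voxel spacing in the header zooms.  When
a file carries a full affine it is preserved on round trip; the pipeline
itself only consumes shape + spacing (axis-aligned grids).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .ivim import DwiSeries
from .types import AdcVolume, ProbabilityMap, ProstateMask

__all__ = [
    "read_adc",
    "read_mask",
    "read_dwi",
    "write_volume",
    "write_mask",
    "write_probability_map",
]


def _load(path):
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def read_adc(path) -> AdcVolume:
    data, spacing = _load(path)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D ADC volume, got {data.ndim}-D")
    return AdcVolume(data.astype(float), spacing)


def read_mask(path) -> ProstateMask:
    data, spacing = _load(path)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D mask, got {data.ndim}-D")
    return ProstateMask(data > 0, spacing)


def read_dwi(path, bval_path) -> DwiSeries:
    """Load a 4-D DWI series plus its b-values (JSON list or FSL .bval)."""
    data, spacing = _load(path)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D DWI series, got {data.ndim}-D")
    text = Path(bval_path).read_text().strip()
    if text.startswith("["):
        import json

        bvals = json.loads(text)
    else:
        bvals = [float(tok) for tok in text.split()]
    # nibabel stores the series as (x, y, z, b); the pipeline wants b first
    return DwiSeries(np.moveaxis(data.astype(float), 3, 0), np.asarray(bvals), spacing)


def _affine(spacing):
    aff = np.diag(list(spacing) + [1.0])
    return aff


def write_volume(data: np.ndarray | AdcVolume, spacing=None, path=None) -> None:
    if isinstance(data, AdcVolume):
        spacing = data.spacing
        data = data.data
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(spacing))
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def write_mask(mask: ProstateMask, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.spacing))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def write_probability_map(pmap: ProbabilityMap, out_dir, stem: str = "probmap") -> None:
    """Write the probability values and their validity mask side by side."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_volume(pmap.values, pmap.spacing, out_dir / f"{stem}.nii.gz")
    img = nib.Nifti1Image(pmap.valid.astype(np.uint8), _affine(pmap.spacing))
    img.header.set_zooms(pmap.spacing)
    nib.save(img, str(out_dir / f"{stem}_valid.nii.gz"))
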