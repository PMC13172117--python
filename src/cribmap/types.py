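"""Core in-memory containers shared across the pipeline.

Conventions used throughout the package:

* Image grids are numpy arrays of shape ``(nx, ny, nz)``; the third axis is
  the slice (z) axis.  Voxel spacing is ``(sx, sy, sz)`` in millimetres.
* ADC values are expressed in 1e-6 mm^2/s (so typical prostate tissue sits
  around 700-1600).
* b-values are in s/mm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Unit of every ADC grid in the package, in mm^2/s.
ADC_UNIT = 1e-6

Spacing = tuple[float, float, float]


def _check_spacing(spacing) -> Spacing:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"voxel spacing must be 3 positive lengths, got {spacing}")
    return spacing


@dataclass
class AdcVolume:
    """A 3-D apparent-diffusion-coefficient map (units of 1e-6 mm^2/s)."""

    data: np.ndarray
    spacing: Spacing

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"ADC grid must be 3-D, got shape {self.data.shape}")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class ProstateMask:
    """Binary prostate segmentation aligned to an :class:`AdcVolume` grid."""

    data: np.ndarray
    spacing: Spacing

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"mask grid must be 3-D, got shape {arr.shape}")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be 0/1")
            arr = arr.astype(bool)
        self.data = arr
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def is_empty(self) -> bool:
        return not self.data.any()


@dataclass
class PatientRecord:
    """Patient-level clinical variables plus prostatectomy ground truth.

    ``crib_positive`` is the patient-level label: at least one cribriform
    (GP4Crib+) region anywhere in the prostatectomy specimen.
    ``max_crib_diameter_mm`` is the largest in-plane extent of any cribriform
    focus (0 for cribriform-negative patients).
    """

    patient_id: str
    psa: float
    clinical_t_stage: int
    biopsy_gg: int
    prostatectomy_gg: int
    crib_positive: bool
    max_crib_diameter_mm: float
    cpg: int = 0  # 0 = unassigned; filled by decision.assign_cpg

    def __post_init__(self) -> None:
        if self.psa <= 0:
            raise ValueError("PSA must be positive")
        if self.clinical_t_stage not in (1, 2, 3, 4):
            raise ValueError("clinical T-stage must be 1-4")
        for gg in (self.biopsy_gg, self.prostatectomy_gg):
            if gg not in (1, 2, 3, 4, 5):
                raise ValueError("grade group must be 1-5")
        if self.max_crib_diameter_mm < 0:
            raise ValueError("cribriform diameter must be nonnegative")
        if self.crib_positive and self.max_crib_diameter_mm <= 0:
            raise ValueError("cribriform-positive record needs a positive focus diameter")
        if not self.crib_positive:
            self.max_crib_diameter_mm = 0.0


@dataclass
class ProbabilityMap:
    """Voxel-wise cribriform probability, defined only where ``valid`` is set.

    ``values`` holds NaN outside the validity mask so accidental use of
    undefined voxels surfaces immediately.
    """

    values: np.ndarray
    valid: np.ndarray
    spacing: Spacing
    window_sizes: tuple[int, ...] = ()
    model_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and validity grids must share a shape")
        self.spacing = _check_spacing(self.spacing)
        defined = self.values[self.valid]
        if defined.size and (np.nanmin(defined) < 0 or np.nanmax(defined) > 1):
            raise ValueError("defined probabilities must lie in [0, 1]")

    @property
    def n_defined(self) -> int:
        return int(self.valid.sum())


@dataclass
class PatientScore:
    """Patient-level score: the maximum defined voxel probability."""

    patient_id: str
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("patient score must lie in [0, 1]")


@dataclass
class Phantom:
    """A synthetic patient: ADC volume, prostate mask, lesion labels, record."""

    adc: AdcVolume
    mask: ProstateMask
    lesion_labels: np.ndarray
    record: PatientRecord

    def __post_init__(self) -> None:
        self.lesion_labels = np.asarray(self.lesion_labels, dtype=np.int16)
        if self.lesion_labels.shape != self.adc.shape:
            raise ValueError("lesion label grid must match the ADC grid")
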