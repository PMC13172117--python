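"""Synthetic phantoms and cohorts for exercising the pipeline end to end.

No MRI cohort with voxel-level cribriform ground truth is publicly
available, so the package ships a generator that emulates the statistical
structure the analysis relies on:

* a prostate-shaped (ellipsoidal) mask on an anisotropic grid;
* spherical tumour lesions of three histologic classes — GP3, non-cribriform
  GP4 and cribriform GP4 — whose ADC distributions decrease with increasing
  architectural density, so cribriform tissue has the lowest ADC (the sign
  the deployed single-feature model depends on);
* patient-level clinical variables (PSA, biopsy grade group, T-stage)
  consistent with a requested Cambridge Prognostic Group;
* a fixed 127-patient benchmark cohort (:func:`build_fixture_cohort`) whose
  joint cribriform x grade-group cell counts reproduce a published
  radical-prostatectomy series, used to test the decision framework.

Default ADC levels (background 1400+/-200, GP3 1000+/-150, non-cribriform
GP4 900+/-150, cribriform GP4 700+/-120, in 1e-6 mm^2/s) are invented
configuration defaults chosen to preserve that ordering; every number is
user-overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np
import pandas as pd

from .decision import assign_cpg
from .types import AdcVolume, PatientRecord, Phantom, ProstateMask

__all__ = [
    "LesionClass",
    "PhantomConfig",
    "generate_phantom",
    "generate_cohort",
    "build_fixture_cohort",
    "cohort_to_dataframe",
    "records_from_dataframe",
]


class LesionClass(IntEnum):
    """Lesion label codes on the phantom's label grid (0 = background)."""

    GP3 = 1
    GP4_CRIB_NEG = 2
    GP4_CRIB_POS = 3


@dataclass
class PhantomConfig:
    """Geometry, tissue-contrast and noise settings for phantom generation."""

    grid_shape: tuple[int, int, int] = (72, 72, 12)
    voxel_spacing: tuple[float, float, float] = (0.5, 0.5, 3.0)  # mm
    prostate_semiaxes_mm: tuple[float, float, float] = (16.0, 13.0, 11.0)
    background_adc: tuple[float, float] = (1400.0, 200.0)  # (mean, sd)
    lesion_adc: dict = field(
        default_factory=lambda: {
            LesionClass.GP3: (1000.0, 150.0),
            LesionClass.GP4_CRIB_NEG: (900.0, 150.0),
            LesionClass.GP4_CRIB_POS: (700.0, 120.0),
        }
    )
    lesion_count_range: tuple[int, int] = (1, 3)
    lesion_diameter_range: tuple[float, float] = (1.0, 10.0)  # mm
    noise_model: str = "none"  # none | gaussian | rician
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.grid_shape):
            raise ValueError("grid shape must be positive")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")
        if self.background_adc[1] < 0 or any(sd < 0 for _, sd in self.lesion_adc.values()):
            raise ValueError("ADC standard deviations must be >= 0")
        crib_mean = self.lesion_adc[LesionClass.GP4_CRIB_POS][0]
        gp3_mean = self.lesion_adc[LesionClass.GP3][0]
        if crib_mean >= gp3_mean and crib_mean != gp3_mean:
            raise ValueError(
                "cribriform ADC mean must not exceed the GP3 mean (the model "
                "assumes lower ADC in cribriform tissue); set them equal for "
                "a zero-contrast control"
            )
        lo, hi = self.lesion_diameter_range
        if lo <= 0 or hi < lo:
            raise ValueError("lesion diameters must be positive and ordered")
        if self.noise_model not in ("none", "gaussian", "rician"):
            raise ValueError("noise_model must be none, gaussian or rician")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        # in-plane prostate diameter in voxels must be workable
        dx = 2 * self.prostate_semiaxes_mm[0] / self.voxel_spacing[0]
        dy = 2 * self.prostate_semiaxes_mm[1] / self.voxel_spacing[1]
        if min(dx, dy) < 15:
            raise ValueError("prostate must span >= 15 in-plane voxels")
        ext = [n * s for n, s in zip(self.grid_shape, self.voxel_spacing)]
        if any(2 * a >= e for a, e in zip(self.prostate_semiaxes_mm, ext)):
            raise ValueError("prostate ellipsoid does not fit inside the grid")


def _voxel_centers(config: PhantomConfig):
    """Physical voxel-centre coordinate grids (mm), origin at volume centre."""
    axes = []
    for n, s in zip(config.grid_shape, config.voxel_spacing):
        axes.append((np.arange(n) - (n - 1) / 2) * s)
    return np.meshgrid(*axes, indexing="ij")


def _prostate_mask_grid(config: PhantomConfig) -> np.ndarray:
    x, y, z = _voxel_centers(config)
    a, b, c = config.prostate_semiaxes_mm
    return (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0


def _lesion_voxels(config: PhantomConfig, center, diameter_mm):
    """Boolean grid of voxel centres within a sphere around ``center`` (mm)."""
    x, y, z = _voxel_centers(config)
    r = diameter_mm / 2
    return (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2 <= r**2


def _snap(value, spacing, n):
    """Snap a physical coordinate to the nearest voxel centre on that axis."""
    centers = (np.arange(n) - (n - 1) / 2) * spacing
    return centers[np.argmin(np.abs(centers - value))]


def _place_lesions(config, rng, classes, diameters, mask):
    """Rejection-sample non-overlapping spherical lesions inside the mask."""
    labels = np.zeros(config.grid_shape, dtype=np.int16)
    a, b, c = config.prostate_semiaxes_mm
    max_attempts = 200
    for cls, d in zip(classes, diameters):
        placed = False
        for _ in range(max_attempts):
            # sample inside a shrunken ellipsoid so small lesions rarely clip
            u = rng.uniform(-0.8, 0.8, size=3)
            if (u**2).sum() > 0.64:
                continue
            center = [
                _snap(u[0] * a, config.voxel_spacing[0], config.grid_shape[0]),
                _snap(u[1] * b, config.voxel_spacing[1], config.grid_shape[1]),
                _snap(u[2] * c, config.voxel_spacing[2], config.grid_shape[2]),
            ]
            vox = _lesion_voxels(config, center, d)
            if not vox.any():
                continue
            if not np.all(mask[vox]):
                continue
            if np.any(labels[vox] != 0):
                continue
            labels[vox] = int(cls)
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place a {d:.1f} mm lesion inside the prostate "
                f"after {max_attempts} attempts; enlarge the prostate or "
                "shrink the lesions"
            )
    return labels


def _measure_crib_diameter(labels: np.ndarray, config: PhantomConfig) -> float:
    """Largest in-plane extent (mm) over cribriform lesion voxels.

    Extent per slice is the maximum pairwise centre distance plus one
    in-plane voxel (accounting for the voxel footprint).
    """
    sx, sy = config.voxel_spacing[:2]
    crib = labels == int(LesionClass.GP4_CRIB_POS)
    if not crib.any():
        return 0.0
    best = 0.0
    for z in range(labels.shape[2]):
        ii, jj = np.nonzero(crib[:, :, z])
        if ii.size == 0:
            continue
        pts = np.column_stack([ii * sx, jj * sy])
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        best = max(best, float(np.sqrt(d2.max())) + min(sx, sy))
    return best


def _apply_noise(adc: np.ndarray, config: PhantomConfig, rng) -> np.ndarray:
    if config.noise_model == "none" or config.noise_sigma == 0:
        return adc
    if config.noise_model == "gaussian":
        return adc + rng.normal(0, config.noise_sigma, adc.shape)
    # rician: magnitude of a complex Gaussian perturbation
    re = adc + rng.normal(0, config.noise_sigma, adc.shape)
    im = rng.normal(0, config.noise_sigma, adc.shape)
    return np.sqrt(re**2 + im**2)


def generate_phantom(
    config: PhantomConfig,
    record_spec: dict | None = None,
    rng: np.random.Generator | None = None,
) -> Phantom:
    """Generate one synthetic patient.

    ``record_spec`` may fix any clinical field plus ``crib_positive``,
    ``n_lesions`` and ``crib_diameter_mm`` (the in-plane diameter of the
    cribriform lesion).  Unspecified fields are sampled.  The returned
    record's ``max_crib_diameter_mm`` is *measured* from the lesion voxels,
    so it agrees with the image within one in-plane voxel.

    Raises
    ------
    ValueError
        On contradictory specs (e.g. cribriform-negative with a cribriform
        diameter demanded).
    RuntimeError
        When a lesion cannot be placed inside the prostate after a bounded
        number of attempts.
    """
    spec = dict(record_spec or {})
    if rng is None:
        rng = np.random.default_rng(config.seed)

    crib_positive = bool(spec.pop("crib_positive", rng.random() < 0.5))
    crib_d = spec.pop("crib_diameter_mm", None)
    if not crib_positive and crib_d:
        raise ValueError("cribriform-negative spec cannot demand a cribriform lesion")
    lo, hi = config.lesion_count_range
    n_lesions = int(spec.pop("n_lesions", rng.integers(lo, hi + 1)))
    if crib_positive and n_lesions < 1:
        raise ValueError("a cribriform-positive phantom needs at least one lesion")

    mask_grid = _prostate_mask_grid(config)

    classes, diameters = [], []
    dlo, dhi = config.lesion_diameter_range
    if crib_positive:
        classes.append(LesionClass.GP4_CRIB_POS)
        diameters.append(float(crib_d) if crib_d else float(rng.uniform(dlo, dhi)))
    for _ in range(n_lesions - len(classes)):
        classes.append(rng.choice([LesionClass.GP3, LesionClass.GP4_CRIB_NEG]))
        diameters.append(float(rng.uniform(dlo, dhi)))
    labels = (
        _place_lesions(config, rng, classes, diameters, mask_grid)
        if classes
        else np.zeros(config.grid_shape, dtype=np.int16)
    )

    adc = rng.normal(*config.background_adc, size=config.grid_shape)
    for cls, (mean, sd) in config.lesion_adc.items():
        vox = labels == int(cls)
        if vox.any():
            adc[vox] = rng.normal(mean, sd, size=int(vox.sum()))
    adc = np.clip(_apply_noise(adc, config, rng), 0, None)

    measured_d = _measure_crib_diameter(labels, config)
    psa = float(spec.pop("psa", rng.uniform(4, 15)))
    t = int(spec.pop("clinical_t_stage", rng.integers(1, 3)))
    bgg = int(spec.pop("biopsy_gg", rng.integers(1, 3)))
    pgg = int(spec.pop("prostatectomy_gg", max(bgg, 2 if crib_positive else bgg)))
    pid = str(spec.pop("patient_id", f"SYN{rng.integers(0, 10**9):09d}"))
    if spec:
        raise ValueError(f"unknown record fields: {sorted(spec)}")
    record = PatientRecord(
        patient_id=pid,
        psa=psa,
        clinical_t_stage=t,
        biopsy_gg=bgg,
        prostatectomy_gg=pgg,
        crib_positive=crib_positive,
        max_crib_diameter_mm=measured_d,
        cpg=assign_cpg(psa, bgg, t),
    )
    return Phantom(
        adc=AdcVolume(adc, config.voxel_spacing),
        mask=ProstateMask(mask_grid, config.voxel_spacing),
        lesion_labels=labels,
        record=record,
    )


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

def _clinical_for_cpg(cpg: int, rng) -> dict:
    """Sample (psa, biopsy_gg, t-stage) consistent with a requested CPG."""
    t = int(rng.integers(1, 3))
    if cpg == 1:
        return {"psa": float(rng.uniform(3, 9.5)), "biopsy_gg": 1, "clinical_t_stage": t}
    if cpg == 2:
        if rng.random() < 0.1:  # GG1 with intermediate PSA
            return {"psa": float(rng.uniform(10.5, 18)), "biopsy_gg": 1, "clinical_t_stage": t}
        return {"psa": float(rng.uniform(4, 9.5)), "biopsy_gg": 2, "clinical_t_stage": t}
    if cpg == 3:  # the GG2 flavour used by the scenarios
        return {"psa": float(rng.uniform(10.5, 19)), "biopsy_gg": 2, "clinical_t_stage": t}
    raise ValueError("cohort generation supports CPG 1-3 only")


def _prostatectomy_gg(crib_positive: bool, rng) -> int:
    if crib_positive:  # cribriform is a GP4 pattern: prostatectomy GG >= 2
        return int(rng.choice([2, 3, 4, 5], p=[0.68, 0.20, 0.08, 0.04]))
    return int(rng.choice([1, 2, 3, 4, 5], p=[0.25, 0.55, 0.14, 0.04, 0.02]))


def _quota_counts(n: int, probs: np.ndarray, exact: bool, rng) -> np.ndarray:
    if exact:
        raw = probs * n
        counts = np.floor(raw).astype(int)
        rem = n - counts.sum()
        order = np.argsort(-(raw - counts))
        counts[order[:rem]] += 1
        return counts
    return rng.multinomial(n, probs)


def generate_cohort(
    n_patients: int,
    config: PhantomConfig,
    class_mix: dict | None = None,
    seed: int = 0,
    exact_quota: bool = True,
) -> list[Phantom]:
    """Generate a cohort of phantoms with a requested CPG x cribriform mix.

    ``class_mix`` maps ``(cpg, crib_positive)`` cells to proportions summing
    to 1; the default spreads patients over CPG 1-3 with the cribriform
    prevalence rising with risk group.  ``exact_quota=True`` apportions cell
    counts by largest remainder; otherwise they are a multinomial draw.
    """
    if class_mix is None:
        class_mix = {
            (1, False): 0.18,
            (1, True): 0.02,
            (2, False): 0.30,
            (2, True): 0.27,
            (3, False): 0.10,
            (3, True): 0.13,
        }
    cells = list(class_mix.keys())
    probs = np.array([class_mix[c] for c in cells], dtype=float)
    if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
        raise ValueError("class-mix proportions must be nonnegative and sum to 1")
    rng = np.random.default_rng(seed)
    counts = _quota_counts(n_patients, probs, exact_quota, rng)

    phantoms = []
    k = 0
    for (cpg, crib), count in zip(cells, counts):
        for _ in range(count):
            spec = _clinical_for_cpg(cpg, rng)
            spec["crib_positive"] = crib
            spec["prostatectomy_gg"] = _prostatectomy_gg(crib, rng)
            spec["patient_id"] = f"SYN{k:04d}"
            ph = generate_phantom(config, spec, rng=rng)
            if ph.record.cpg != cpg:
                raise AssertionError("clinical sampler violated the requested CPG")
            phantoms.append(ph)
            k += 1
    return phantoms


# --------------------------------------------------------------------------
# fixed benchmark cohort
# --------------------------------------------------------------------------

# (cpg, crib_positive, prostatectomy GG >= 3) -> patient count.  The joint
# cells are the unique solution of the published marginal counts combined
# with the reference-scenario outcome percentages of the same series.
_FIXTURE_CELLS = [
    (1, True, False, 3),
    (1, False, False, 23),
    (2, True, True, 8),
    (2, True, False, 25),
    (2, False, True, 4),
    (2, False, False, 35),
    (3, True, True, 8),
    (3, True, False, 8),
    (3, False, True, 2),
    (3, False, False, 11),
]

#: Placeholder focus diameter for fixture cribriform patients (>= the 1.5 mm
#: detectability cutoff; the source tables do not stratify focus size).
FIXTURE_CRIB_DIAMETER_MM = 2.0


def build_fixture_cohort() -> list[PatientRecord]:
    """The fixed 127-patient benchmark cohort for the decision framework.

    Cell structure (CPG x cribriform x prostatectomy GG >= 3):

    * CPG-1, n=26: 3 cribriform-positive, none with GG >= 3;
    * CPG-2, n=72: 33 cribriform-positive, 12 with GG >= 3;
    * CPG-3 (biopsy GG2), n=29: 16 cribriform-positive, 10 with GG >= 3.

    Representative clinical values are chosen per cell so that
    :func:`cribmap.decision.assign_cpg` reproduces the intended group.
    """
    clinical = {
        1: {"psa": 6.7, "biopsy_gg": 1, "clinical_t_stage": 2},
        2: {"psa": 7.1, "biopsy_gg": 2, "clinical_t_stage": 2},
        3: {"psa": 15.0, "biopsy_gg": 2, "clinical_t_stage": 2},
    }
    records = []
    k = 0
    for cpg, crib, adverse_gg, count in _FIXTURE_CELLS:
        base = clinical[cpg]
        for _ in range(count):
            k += 1
            records.append(
                PatientRecord(
                    patient_id=f"FIX{k:03d}",
                    psa=base["psa"],
                    clinical_t_stage=base["clinical_t_stage"],
                    biopsy_gg=base["biopsy_gg"],
                    prostatectomy_gg=3 if adverse_gg else 2,
                    crib_positive=crib,
                    max_crib_diameter_mm=FIXTURE_CRIB_DIAMETER_MM if crib else 0.0,
                    cpg=cpg,
                )
            )
    assert len(records) == 127
    return records


# --------------------------------------------------------------------------
# tabular round trip
# --------------------------------------------------------------------------

_COLUMNS = [
    "patient_id",
    "psa",
    "clinical_t_stage",
    "biopsy_gg",
    "prostatectomy_gg",
    "crib_positive",
    "max_crib_diameter_mm",
    "cpg",
]


def cohort_to_dataframe(records) -> pd.DataFrame:
    """Patient records as a tidy table (one row per patient)."""
    rows = []
    for r in records:
        rec = r.record if isinstance(r, Phantom) else r
        rows.append({c: getattr(rec, c) for c in _COLUMNS})
    return pd.DataFrame(rows, columns=_COLUMNS)


def records_from_dataframe(df: pd.DataFrame) -> list[PatientRecord]:
    return [
        PatientRecord(
            patient_id=str(row.patient_id),
            psa=float(row.psa),
            clinical_t_stage=int(row.clinical_t_stage),
            biopsy_gg=int(row.biopsy_gg),
            prostatectomy_gg=int(row.prostatectomy_gg),
            crib_positive=bool(row.crib_positive),
            max_crib_diameter_mm=float(row.max_crib_diameter_mm),
            cpg=int(row.cpg),
        )
        for row in df.itertuples()
    ]
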