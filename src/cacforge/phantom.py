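"""Synthetic cardiac CT phantoms with voxel-level calcium ground truth.

Each generated case mimics the acquisition setting of a calcium-scoring
study in a PET/CT workflow: one thin-slice, ECG-synchronized "CSCT-like"
reference volume plus two thick-slice, motion-degraded "CTAC-like"
volumes (rest and stress). Calcific lesions are ellipsoidal bright blobs
(>= 150 HU peak) inserted near the surface of an ellipsoidal heart, where
the coronary arteries run. The CTAC degradation chain — anisotropic
Gaussian blur as a motion surrogate, through-plane averaging to 5 mm
slices, additive noise — reproduces the partial-volume effect that pushes
small lesions partly below the clinical 130 HU detection threshold.

Anatomy is deliberately schematic: a soft-tissue thorax (0 HU) with two
lung fields (-800 HU) and a heart of 30-60 HU tissue with smooth +/-20 HU
texture, enough contrast for a segmentation network to learn but with no
claim to anatomical realism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import CTVolume, HU_MAX, HU_MIN, Modality, resample_mask


# ---------------------------------------------------------------------------
# Geometry configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeometryConfig:
    """Phantom geometry and degradation settings.

    Sizes are in mm. The CSCT grid uses 0.4 mm in-plane pixels and 2.5 mm
    slices; the CTAC grid 1.17 mm and 5.0 mm, matching the acquisition
    grids the analysis pipeline expects. Defaults keep the field of view
    small (a heart-centred crop rather than a full thorax) so that cohorts
    of hundreds of cases are cheap to simulate.
    """

    csct_shape: tuple[int, int, int] = (32, 192, 192)  # (nz, ny, nx)
    csct_spacing: tuple[float, float, float] = (0.4, 0.4, 2.5)  # (dx, dy, dz)
    ctac_inplane_mm: float = 1.17
    ctac_slice_mm: float = 5.0
    heart_semiaxes_mm: tuple[float, float, float] = (26.0, 24.0, 30.0)  # (ax, ay, az)
    heart_hu: tuple[int, int] = (30, 60)
    heart_texture_sd_hu: float = 20.0
    lung_hu: int = -800
    body_hu: int = 0
    lesion_extent_mm: tuple[float, float] = (1.5, 6.0)
    #: lesion centres sit at this radial fraction of the heart ellipsoid,
    #: a crude surrogate for the epicardial course of the coronary arteries
    lesion_radial_range: tuple[float, float] = (0.55, 0.85)
    blur_sigma_mm: tuple[float, float, float] = (0.8, 0.8, 1.2)  # (x, y, z)
    noise_sd_hu: float = 20.0
    max_placement_retries: int = 50


@dataclass(frozen=True)
class LesionTruth:
    lesion_id: int
    center_mm: tuple[float, float, float]  # (x, y, z) world
    extent_mm: tuple[float, float, float]  # full extent per axis
    peak_hu: int
    true_pseudomass: float  # HU*mm^3, sum of inserted HU x voxel volume
    true_agatston: float


@dataclass
class PhantomCase:
    """One synthetic patient: CSCT reference + rest/stress CTAC volumes."""

    case_id: str
    seed: int
    csct: CTVolume
    ctac_rest: CTVolume
    ctac_stress: CTVolume
    calcium_mask_csct: np.ndarray  # bool, csct grid
    inserted_hu_csct: np.ndarray  # int, csct grid: HU added by lesions
    lesion_truth: list[LesionTruth]
    heart_mask_csct: np.ndarray  # bool
    heart_mask_ctac: np.ndarray  # bool, shared by rest/stress (same grid)
    #: noiseless inserted-HU field propagated through the CTAC degradation
    #: chain (blur + slice averaging are linear); per-slice sums of this
    #: field give exact ground-truth calcium mass on the CTAC grid
    inserted_hu_ctac: np.ndarray

    @property
    def total_true_pseudomass(self) -> float:
        return float(sum(t.true_pseudomass for t in self.lesion_truth))


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _ellipsoid_mask(shape, spacing, center_mm, semiaxes_mm):
    """Boolean mask of an axis-aligned ellipsoid; shape (nz,ny,nx), spacing (dx,dy,dz)."""
    nz, ny, nx = shape
    dx, dy, dz = spacing
    z = (np.arange(nz, dtype=np.float32) * dz)[:, None, None]
    y = (np.arange(ny, dtype=np.float32) * dy)[None, :, None]
    x = (np.arange(nx, dtype=np.float32) * dx)[None, None, :]
    cx, cy, cz = center_mm
    ax, ay, az = semiaxes_mm
    r2 = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2
    return r2 <= 1.0


def _smooth_noise(rng, shape, sd, sigma_vox=3.0):
    """Zero-mean spatially smooth noise with the requested point-wise sd."""
    raw = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(raw, sigma=sigma_vox)
    s = sm.std()
    if s < 1e-12:
        return np.zeros(shape)
    return sm * (sd / s)


def _resample_inplane(arr, spacing, target_inplane, order=1):
    """Linear in-plane resampling (z axis untouched); returns array + new spacing."""
    dx, dy, dz = spacing
    nz, ny, nx = arr.shape
    out_ny = max(1, int(round(ny * dy / target_inplane)))
    out_nx = max(1, int(round(nx * dx / target_inplane)))
    yy = np.arange(out_ny) * (target_inplane / dy)
    xx = np.arange(out_nx) * (target_inplane / dx)
    gy, gx = np.meshgrid(yy, xx, indexing="ij")
    out = np.empty((nz, out_ny, out_nx), dtype=np.float32)
    coords = np.stack([gy.ravel(), gx.ravel()])
    for k in range(nz):
        out[k] = ndimage.map_coordinates(
            arr[k].astype(np.float32), coords, order=order, mode="nearest"
        ).reshape(out_ny, out_nx)
    return out, (target_inplane, target_inplane, dz)


def _box_average_z(arr, dz, target_dz):
    """Average groups of slices to reach the target slice thickness.

    Requires the thickness ratio to be (near-)integer, mirroring how thick
    slices are reconstructed by averaging thin ones.
    """
    factor = target_dz / dz
    k = int(round(factor))
    if abs(factor - k) > 1e-6:
        raise ValueError(f"slice thickness ratio {factor} is not an integer multiple")
    if k == 1:
        return arr.copy()
    nz = arr.shape[0]
    n_out = nz // k
    trimmed = arr[: n_out * k]
    return trimmed.reshape(n_out, k, *arr.shape[1:]).mean(axis=1)


# ---------------------------------------------------------------------------
# Degradation chain
# ---------------------------------------------------------------------------

def degrade_to_ctac(
    volume: CTVolume,
    blur_sigma_mm,
    noise_sd_hu: float,
    slice_thickness_mm: float,
    seed: int,
    modality: Modality = Modality.GENERIC,
) -> CTVolume:
    """Degrade a thin-slice volume into a CTAC-like thick-slice volume.

    Applies, in order: anisotropic Gaussian blur (cardiac-motion
    surrogate), through-plane box averaging to ``slice_thickness_mm``,
    and additive Gaussian noise. With zero blur, zero noise and unchanged
    thickness the volume passes through bit-identically.
    """
    dx, dy, dz = volume.spacing
    if slice_thickness_mm < dz - 1e-9:
        raise ValueError(
            f"target slice thickness {slice_thickness_mm} mm is finer than source {dz} mm"
        )
    if np.isscalar(blur_sigma_mm):
        blur_sigma_mm = (float(blur_sigma_mm),) * 3
    sx, sy, sz = (float(s) for s in blur_sigma_mm)

    arr = volume.voxels.astype(np.float64)
    identity = (sx == sy == sz == 0.0) and noise_sd_hu == 0.0 and abs(slice_thickness_mm - dz) < 1e-9
    if identity:
        return CTVolume(arr, volume.spacing, volume.origin, modality, volume.patient_id)

    if sx > 0 or sy > 0 or sz > 0:
        arr = ndimage.gaussian_filter(arr, sigma=(sz / dz, sy / dy, sx / dx))
    arr = _box_average_z(arr, dz, slice_thickness_mm)
    if noise_sd_hu > 0:
        rng = np.random.default_rng(seed)
        arr = arr + rng.normal(0.0, noise_sd_hu, size=arr.shape)
    return CTVolume(
        voxels=np.clip(np.rint(arr), HU_MIN, HU_MAX),
        spacing=(dx, dy, slice_thickness_mm),
        origin=volume.origin,
        modality=modality,
        patient_id=volume.patient_id,
    )


def _degrade_field(field, spacing, blur_sigma_mm, slice_thickness_mm, target_inplane):
    """Noise-free degradation of an additive field (blur + z-average + in-plane resample)."""
    dx, dy, dz = spacing
    sx, sy, sz = blur_sigma_mm
    arr = field.astype(np.float64)
    if sx > 0 or sy > 0 or sz > 0:
        arr = ndimage.gaussian_filter(arr, sigma=(sz / dz, sy / dy, sx / dx))
    arr = _box_average_z(arr, dz, slice_thickness_mm)
    arr, _ = _resample_inplane(arr, (dx, dy, slice_thickness_mm), target_inplane)
    return arr


# ---------------------------------------------------------------------------
# Case generation
# ---------------------------------------------------------------------------

def generate_case(
    seed: int,
    n_lesions: int,
    hu_range: tuple[float, float] = (150, 800),
    geometry: GeometryConfig | None = None,
    case_id: str | None = None,
) -> PhantomCase:
    """Generate one phantom case with known voxel-level calcium truth.

    Lesions are ellipsoidal blobs with a smooth (quadratic) radial density
    profile, peak HU drawn from ``hu_range`` and extents from the
    geometry's lesion size range, placed near the heart surface without
    mutual overlap. The same case (seed + parameters) always regenerates
    bit-identical volumes.
    """
    if n_lesions < 0:
        raise ValueError("n_lesions must be >= 0")
    if n_lesions > 0 and hu_range[0] < 150:
        raise ValueError("lesion peak HU must be >= 150 to qualify as calcium truth")
    geo = geometry or GeometryConfig()
    rng = np.random.default_rng(seed)
    case_id = case_id or f"case{seed:05d}"

    shape = geo.csct_shape
    spacing = geo.csct_spacing
    dx, dy, dz = spacing
    nz, ny, nx = shape
    fov_mm = (nx * dx, ny * dy, nz * dz)

    # --- background anatomy on the CSCT grid
    clean = np.full(shape, float(geo.body_hu), dtype=np.float32)
    cx, cy, cz = fov_mm[0] / 2, fov_mm[1] / 2, fov_mm[2] / 2
    heart = _ellipsoid_mask(shape, spacing, (cx, cy, cz), geo.heart_semiaxes_mm)
    lung_dx = geo.heart_semiaxes_mm[0] + 0.22 * fov_mm[0]
    lung_ax = (0.16 * fov_mm[0], 0.30 * fov_mm[1], 0.55 * fov_mm[2])
    for side in (-1.0, 1.0):
        lung = _ellipsoid_mask(shape, spacing, (cx + side * lung_dx, cy, cz), lung_ax)
        clean[lung & ~heart] = geo.lung_hu
    heart_mean = rng.uniform(*geo.heart_hu)
    texture = _smooth_noise(rng, shape, geo.heart_texture_sd_hu)
    clean[heart] = heart_mean + texture[heart]

    # --- lesion insertion (each blob evaluated only on its bounding box)
    inserted = np.zeros(shape, dtype=np.int32)
    truths_geom = []  # (lesion_id, center_mm, extent, peak)
    for lesion_id in range(n_lesions):
        placed = False
        for _ in range(geo.max_placement_retries):
            # direction on the unit sphere, radial fraction near the heart surface
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            frac = rng.uniform(*geo.lesion_radial_range)
            center = (
                cx + v[0] * frac * geo.heart_semiaxes_mm[0],
                cy + v[1] * frac * geo.heart_semiaxes_mm[1],
                cz + v[2] * frac * geo.heart_semiaxes_mm[2],
            )
            ext = rng.uniform(*geo.lesion_extent_mm, size=3)
            peak = rng.uniform(*hu_range)
            semi = ext / 2.0
            z0 = max(0, int(np.floor((center[2] - semi[2]) / dz)))
            z1 = min(nz, int(np.ceil((center[2] + semi[2]) / dz)) + 1)
            y0 = max(0, int(np.floor((center[1] - semi[1]) / dy)))
            y1 = min(ny, int(np.ceil((center[1] + semi[1]) / dy)) + 1)
            x0 = max(0, int(np.floor((center[0] - semi[0]) / dx)))
            x1 = min(nx, int(np.ceil((center[0] + semi[0]) / dx)) + 1)
            if z0 >= z1 or y0 >= y1 or x0 >= x1:
                continue
            zl = (np.arange(z0, z1) * dz - center[2])[:, None, None] / semi[2]
            yl = (np.arange(y0, y1) * dy - center[1])[None, :, None] / semi[1]
            xl = (np.arange(x0, x1) * dx - center[0])[None, None, :] / semi[0]
            r2 = zl**2 + yl**2 + xl**2
            blob = np.rint(np.where(r2 <= 1.0, peak * (1.0 - 0.6 * r2), 0.0)).astype(np.int32)
            blob[blob < 0] = 0
            support = blob > 0
            if not support.any() or blob.max() < 150:
                continue  # too small at this grid, or peak quantized below 150 HU
            box = (slice(z0, z1), slice(y0, y1), slice(x0, x1))
            if not heart[box][support].all():
                continue  # partially outside the heart: resample position
            if (inserted[box][support] > 0).any():
                continue  # overlap with an earlier lesion
            inserted[box][support] += blob[support]
            truths_geom.append((lesion_id, center, tuple(ext), int(blob.max())))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place lesion {lesion_id} inside the heart after "
                f"{geo.max_placement_retries} retries"
            )

    calcium_mask = inserted > 0
    csct_arr = np.clip(np.rint(clean + inserted), HU_MIN, HU_MAX)
    csct = CTVolume(csct_arr, spacing, modality=Modality.CSCT, patient_id=case_id)

    # --- CTAC-like rest/stress volumes (differ only in the noise/seed draw)
    inplane, _ = _resample_inplane(csct_arr, spacing, geo.ctac_inplane_mm)
    base = CTVolume(
        inplane,
        (geo.ctac_inplane_mm, geo.ctac_inplane_mm, dz),
        modality=Modality.GENERIC,
        patient_id=case_id,
    )
    ctac_rest = degrade_to_ctac(
        base, geo.blur_sigma_mm, geo.noise_sd_hu, geo.ctac_slice_mm,
        seed=_subseed(seed, 1), modality=Modality.CTAC_REST,
    )
    ctac_stress = degrade_to_ctac(
        base, geo.blur_sigma_mm, geo.noise_sd_hu, geo.ctac_slice_mm,
        seed=_subseed(seed, 2), modality=Modality.CTAC_STRESS,
    )
    inserted_ctac = _degrade_field(
        inserted, spacing, geo.blur_sigma_mm, geo.ctac_slice_mm, geo.ctac_inplane_mm
    )
    heart_ctac = resample_mask(
        heart, spacing, (geo.ctac_inplane_mm, geo.ctac_inplane_mm, geo.ctac_slice_mm)
    )
    # the z box-average shortens the volume to a multiple of the factor
    heart_ctac = heart_ctac[: ctac_rest.n_slices]

    # --- ground-truth scores per lesion (computed on the clean CSCT grid)
    from .scoring import agatston_from_array  # local import: avoid cycle at import time

    voxvol = csct.voxel_volume_mm3
    labels, _ = ndimage.label(calcium_mask, structure=np.ones((3, 3, 3), dtype=int))
    truths = []
    for lesion_id, center, ext, peak in truths_geom:
        # map geometric lesion to its connected component via the centre voxel
        iz = int(round(center[2] / dz))
        iy = int(round(center[1] / dy))
        ix = int(round(center[0] / dx))
        lab = labels[min(iz, nz - 1), min(iy, ny - 1), min(ix, nx - 1)]
        comp = labels == lab if lab > 0 else None
        if comp is None or not comp.any():
            comp = calcium_mask  # degenerate fallback; never hit in practice
        mass = float(inserted[comp].sum() * voxvol)
        aga = agatston_from_array(
            np.where(comp, csct_arr, HU_MIN), spacing, np.ones(shape, dtype=bool)
        )
        truths.append(
            LesionTruth(
                lesion_id=lesion_id,
                center_mm=tuple(float(c) for c in center),
                extent_mm=tuple(float(e) for e in ext),
                peak_hu=int(peak),
                true_pseudomass=mass,
                true_agatston=float(aga),
            )
        )

    return PhantomCase(
        case_id=case_id,
        seed=seed,
        csct=csct,
        ctac_rest=ctac_rest,
        ctac_stress=ctac_stress,
        calcium_mask_csct=calcium_mask,
        inserted_hu_csct=inserted.astype(np.int32),
        lesion_truth=truths,
        heart_mask_csct=heart,
        heart_mask_ctac=heart_ctac,
        inserted_hu_ctac=inserted_ctac,
    )


def _subseed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31 - 1))


def true_scores(case: PhantomCase):
    """Ground-truth calcium scores for a phantom case.

    Pseudomass is the exact sum of inserted HU times voxel volume over the
    calcium mask; the Agatston score is computed by the scoring module on
    the clean (non-degraded) CSCT volume; volume is the calcium mask
    volume in mm^3.
    """
    from .scoring import CalciumScore, agatston

    voxvol = case.csct.voxel_volume_mm3
    mass = float(case.inserted_hu_csct.sum() * voxvol)
    vol = float(case.calcium_mask_csct.sum() * voxvol)
    aga = agatston(case.csct, case.heart_mask_csct)
    return CalciumScore(
        pseudomass=mass, agatston=float(aga), volume=vol,
        scan_id=case.case_id, method="ground_truth",
    )


def generate_cohort(
    n_cases: int,
    seed: int,
    lesion_rate: tuple[int, int] = (0, 5),
    hu_range=(150, 800),
    geometry: GeometryConfig | None = None,
) -> list[PhantomCase]:
    """Generate a cohort; lesion counts drawn uniformly from ``lesion_rate``."""
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_cases):
        n_les = int(rng.integers(lesion_rate[0], lesion_rate[1] + 1))
        cases.append(
            generate_case(
                seed=_subseed(seed, 100 + i),
                n_lesions=n_les,
                hu_range=hu_range,
                geometry=geometry,
                case_id=f"case{i:04d}",
            )
        )
    return cases


def lesion_table(cases: list[PhantomCase]) -> pd.DataFrame:
    """Lesion ground truth as a tidy table (one row per lesion)."""
    rows = []
    for case in cases:
        for t in case.lesion_truth:
            rows.append(
                {
                    "case_id": case.case_id,
                    "lesion_id": t.lesion_id,
                    "center_x": t.center_mm[0],
                    "center_y": t.center_mm[1],
                    "center_z": t.center_mm[2],
                    "peak_hu": t.peak_hu,
                    "true_pseudomass": t.true_pseudomass,
                    "true_agatston": t.true_agatston,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "case_id", "lesion_id", "center_x", "center_y", "center_z",
            "peak_hu", "true_pseudomass", "true_agatston",
        ],
    )
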