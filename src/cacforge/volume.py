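"""CT volume container, NIfTI/MetaImage I/O and grid resampling.

The in-memory contract used throughout the package:

* ``voxels`` is a 3-D integer HU array indexed ``(z, y, x)`` — axial slices
  along the first axis.
* ``spacing`` is ``(dx, dy, dz)`` in mm, i.e. stored in world-axis order,
  which is the *reverse* of the array axis order.
* world coordinate of voxel ``(k, j, i)`` is ``origin + (i*dx, j*dy, k*dz)``
  (0-based indices, no direction matrix — axis-aligned volumes only).

HU values are clipped to the 12-bit CT range [-1024, 3071] on construction
and after every interpolation step.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk
from scipy import ndimage

HU_MIN = -1024
HU_MAX = 3071

#: standard analysis grid: 1.0 mm in-plane, 1.5 mm slice spacing
STANDARD_SPACING = (1.0, 1.0, 1.5)


class Modality(str, enum.Enum):
    CSCT = "CSCT"
    CTAC_REST = "CTAC_REST"
    CTAC_STRESS = "CTAC_STRESS"
    GENERIC = "GENERIC"


@dataclass
class CTVolume:
    """A 3-D HU volume with grid metadata.

    Parameters
    ----------
    voxels:
        ``(nz, ny, nx)`` array of Hounsfield units, int16 range.
    spacing:
        ``(dx, dy, dz)`` voxel spacing in mm, strictly positive.
    origin:
        world position of voxel ``(0, 0, 0)`` in mm.
    modality:
        scan condition tag; analysis code only distinguishes CSCT-like
        (thin-slice reference) from CTAC-like (thick-slice) volumes.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: Modality = Modality.GENERIC
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3-D array, got shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        self.origin = tuple(float(v) for v in self.origin)
        if not isinstance(self.modality, Modality):
            self.modality = Modality(self.modality)
        if np.issubdtype(self.voxels.dtype, np.floating):
            self.voxels = np.rint(self.voxels)
        self.voxels = np.clip(self.voxels, HU_MIN, HU_MAX).astype(np.int16)

    # -- convenience ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def same_grid(self, other: "CTVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def with_voxels(self, voxels: np.ndarray) -> "CTVolume":
        return replace(self, voxels=voxels)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_METAIMAGE_SUFFIXES = (".mha", ".mhd")


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(_NIFTI_SUFFIXES):
        return "nifti"
    if name.endswith(_METAIMAGE_SUFFIXES):
        return "metaimage"
    raise ValueError(f"cannot infer volume format from file name {path.name!r}")


def read_volume(path, format: str | None = None, modality=Modality.GENERIC, patient_id: str = "") -> CTVolume:
    """Read a NIfTI or MetaImage volume into a :class:`CTVolume`.

    Spacing and origin are taken from the header; a header that does not
    provide a positive spacing is a hard error (never silently defaulted).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        try:
            img = nib.load(str(path))
            data = np.asanyarray(img.dataobj)
        except Exception as exc:  # nibabel raises several header error types
            raise ValueError(f"unreadable NIfTI file {path}: {exc}") from exc
        if data.ndim != 3:
            raise ValueError(f"{path}: expected 3-D volume, got shape {data.shape}")
        zooms = img.header.get_zooms()[:3]
        if any(not np.isfinite(z) or z <= 0 for z in zooms):
            raise ValueError(f"{path}: header lacks a valid voxel spacing: {zooms}")
        # nibabel axis order is (x, y, z); our array order is (z, y, x)
        voxels = np.transpose(data, (2, 1, 0))
        spacing = (float(zooms[0]), float(zooms[1]), float(zooms[2]))
        origin = tuple(float(v) for v in img.affine[:3, 3])
    elif fmt == "metaimage":
        try:
            img = sitk.ReadImage(str(path))
        except Exception as exc:
            raise ValueError(f"unreadable MetaImage file {path}: {exc}") from exc
        if img.GetDimension() != 3:
            raise ValueError(f"{path}: expected 3-D volume")
        spacing = tuple(float(s) for s in img.GetSpacing())
        if any(s <= 0 for s in spacing):
            raise ValueError(f"{path}: header lacks a valid voxel spacing: {spacing}")
        voxels = sitk.GetArrayFromImage(img)  # already (z, y, x)
        origin = tuple(float(v) for v in img.GetOrigin())
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'nifti' or 'metaimage'")
    return CTVolume(voxels=voxels, spacing=spacing, origin=origin, modality=modality, patient_id=patient_id)


def write_volume(volume: CTVolume, path, format: str | None = None, overwrite: bool = True) -> None:
    """Write a volume as NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd).

    Lossless for integer HU. With ``overwrite=False`` an existing file
    raises instead of being replaced.
    """
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(path)
    fmt = format or _infer_format(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "nifti":
        affine = np.diag([*volume.spacing, 1.0]).astype(float)
        affine[:3, 3] = volume.origin
        data = np.transpose(volume.voxels, (2, 1, 0))
        nib.save(nib.Nifti1Image(data.astype(np.int16), affine), str(path))
    elif fmt == "metaimage":
        img = sitk.GetImageFromArray(volume.voxels.astype(np.int16))
        img.SetSpacing(tuple(volume.spacing))
        img.SetOrigin(tuple(volume.origin))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'nifti' or 'metaimage'")


def write_mask(mask: np.ndarray, reference: CTVolume, path) -> None:
    """Write a binary mask on ``reference``'s grid as uint8 NIfTI."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*reference.spacing, 1.0]).astype(float)
    affine[:3, 3] = reference.origin
    data = np.transpose(np.asarray(mask).astype(np.uint8), (2, 1, 0))
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_mask(path) -> np.ndarray:
    img = nib.load(str(Path(path)))
    return (np.transpose(np.asanyarray(img.dataobj), (2, 1, 0)) > 0)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _target_shape(shape, spacing, target_spacing):
    # spacing is (dx, dy, dz), shape is (nz, ny, nx)
    nz, ny, nx = shape
    dx, dy, dz = spacing
    tx, ty, tz = target_spacing
    return (
        max(1, int(round(nz * dz / tz))),
        max(1, int(round(ny * dy / ty))),
        max(1, int(round(nx * dx / tx))),
    )


def _resample_array(arr, spacing, target_spacing, order):
    out_shape = _target_shape(arr.shape, spacing, target_spacing)
    if out_shape == arr.shape and np.allclose(spacing, target_spacing):
        return arr.copy()
    scale = (  # output index -> input index, per array axis (z, y, x)
        target_spacing[2] / spacing[2],
        target_spacing[1] / spacing[1],
        target_spacing[0] / spacing[0],
    )
    grids = np.meshgrid(
        *(np.arange(n) * s for n, s in zip(out_shape, scale)),
        indexing="ij",
    )
    coords = np.stack([g.ravel() for g in grids])
    out = ndimage.map_coordinates(arr.astype(np.float32), coords, order=order, mode="nearest")
    return out.reshape(out_shape)


def resample(volume: CTVolume, target_spacing=STANDARD_SPACING) -> CTVolume:
    """Resample onto a new isotropic-in-plane grid with trilinear interpolation.

    Output dimensions are ``round(n * spacing / target)`` per axis; the
    world origin is kept (grids are corner-aligned at voxel (0,0,0)).
    An input already on the target grid is returned voxel-identical.
    """
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    out = _resample_array(volume.voxels, volume.spacing, target_spacing, order=1)
    return CTVolume(
        voxels=np.clip(np.rint(out), HU_MIN, HU_MAX),
        spacing=target_spacing,
        origin=volume.origin,
        modality=volume.modality,
        patient_id=volume.patient_id,
    )


def resample_mask(mask: np.ndarray, spacing, target_spacing=STANDARD_SPACING) -> np.ndarray:
    """Nearest-neighbour resampling for binary masks."""
    out = _resample_array(np.asarray(mask).astype(np.float32), tuple(spacing), tuple(target_spacing), order=0)
    return out > 0.5
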