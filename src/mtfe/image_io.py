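"""3D microCT volume handling: reading/writing, densitometric calibration,
volume-of-interest cropping and bone mineral content.

Conventions
-----------
* ``VoxelImage.data`` is indexed ``[i, j, k]`` with the **third** index the
  longitudinal (z) axis, increasing from distal to proximal.
* ``spacing`` is the isotropic voxel edge length in **mm** (a typical in vivo
  microCT protocol uses 10.4 µm = 0.0104 mm).
* Tissue mineral density (TMD) is in mgHA/cc (= mg/cm³); bone mineral
  content (BMC) in mg.  Unit reconciliation happens in exactly one place,
  :func:`compute_bmc`.
* Voxel-corner physical position = ``origin + index * spacing`` (0-based).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "VoxelImage",
    "CalibrationLaw",
    "BMCReport",
    "read_image",
    "write_image",
    "attenuation_to_tmd",
    "crop_voi",
    "compute_bmc",
]

VALUE_KINDS = ("grey", "attenuation", "tmd", "mask")

#: relative tolerance above which per-axis spacings are considered anisotropic
_ANISO_RTOL = 1e-6


@dataclass
class VoxelImage:
    """A 3D scalar grid with isotropic spacing.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values; the third index is the longitudinal (z) axis.
    spacing : float
        Isotropic voxel edge length in mm.
    origin : ndarray, shape (3,)
        Physical position (mm) of the corner of voxel (0, 0, 0).
    value_kind : {"grey", "attenuation", "tmd", "mask"}
        What the scalar values mean.
    """

    data: np.ndarray
    spacing: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    value_kind: str = "grey"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("every axis must have at least one voxel")
        self.spacing = float(self.spacing)
        if not self.spacing > 0:
            raise ValueError(f"spacing must be > 0, got {self.spacing}")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(
                f"value_kind must be one of {VALUE_KINDS}, got {self.value_kind!r}"
            )
        if self.value_kind == "mask":
            vals = np.unique(self.data)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("mask images may contain only {0, 1}")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing ** 3

    def with_data(self, data, value_kind=None) -> "VoxelImage":
        """Copy carrying new data (and optionally a new value kind)."""
        return VoxelImage(
            data=data,
            spacing=self.spacing,
            origin=self.origin.copy(),
            value_kind=value_kind or self.value_kind,
        )


@dataclass(frozen=True)
class CalibrationLaw:
    """Scanner attenuation → TMD linear calibration.

    Coefficients are scanner-specific and periodically re-checked against a
    densitometric phantom, so they are always supplied by the user (never a
    package default).
    """

    slope: float  # mgHA/cc per attenuation unit
    intercept: float  # mgHA/cc

    def __post_init__(self):
        if not np.isfinite(self.slope) or self.slope == 0:
            raise ValueError("calibration slope must be finite and nonzero")

    def __call__(self, mu):
        return self.slope * np.asarray(mu, dtype=float) + self.intercept

    def inverse(self) -> "CalibrationLaw":
        return CalibrationLaw(1.0 / self.slope, -self.intercept / self.slope)


@dataclass(frozen=True)
class BMCReport:
    """Total bone mineral content and the masked TMD statistics behind it."""

    total_bmc: float  # mg
    n_bone_voxels: int
    mean_tmd: float  # mgHA/cc

    def to_json(self) -> str:
        return json.dumps(
            {
                "total_bmc_mg": self.total_bmc,
                "n_bone_voxels": self.n_bone_voxels,
                "mean_tmd_mgHAcc": self.mean_tmd,
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# reading / writing


def _check_isotropic(spacing3) -> float:
    s = np.asarray(spacing3, dtype=float)
    ref = s[0]
    if np.any(np.abs(s - ref) > _ANISO_RTOL * abs(ref)):
        raise ValueError(
            f"anisotropic voxel spacing {tuple(s)} is not supported; "
            "resample to isotropic voxels first"
        )
    return float(ref)


def read_image(path, kind: str = "grey", spacing: float | None = None) -> VoxelImage:
    """Read a 3D volume from MetaImage (.mhd), NIfTI (.nii/.nii.gz) or a
    directory of TIFF slices.

    Parameters
    ----------
    path : str or Path
        File (or, for TIFF stacks, directory) to read.
    kind : str
        The ``value_kind`` to stamp on the result.
    spacing : float, optional
        Required for TIFF stacks (mm); ignored for self-describing formats.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))

    if path.is_dir() or path.suffix.lower() in (".tif", ".tiff"):
        return _read_tiff(path, kind, spacing)

    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".mhd", ".mha")):
        return _read_sitk(path, kind)
    if suffixes.endswith((".nii", ".nii.gz")):
        return _read_nifti(path, kind)
    raise ValueError(f"unknown image format: {path.name}")


def _read_sitk(path, kind):
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    spacing = _check_isotropic(img.GetSpacing())
    # sitk arrays come back (z, y, x); transpose to (x, y, z)
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    origin = np.asarray(img.GetOrigin(), dtype=float)
    return VoxelImage(data, spacing, origin, kind)


def _read_nifti(path, kind):
    import nibabel as nib

    img = nib.load(str(path))
    spacing = _check_isotropic(img.header.get_zooms()[:3])
    data = np.asanyarray(img.dataobj)
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return VoxelImage(data, spacing, origin, kind)


def _read_tiff(path, kind, spacing):
    import tifffile

    path = Path(path)
    if spacing is None:
        raise ValueError("TIFF input needs an explicit voxel spacing (mm)")
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")
        )
        if not files:
            raise ValueError(f"no TIFF slices found in {path}")
        slices = [tifffile.imread(str(f)) for f in files]
        stack = np.stack(slices, axis=0)  # (z, y, x)
    else:
        stack = tifffile.imread(str(path))
        if stack.ndim == 2:
            stack = stack[None]
    data = stack.transpose(2, 1, 0)
    return VoxelImage(data, float(spacing), np.zeros(3), kind)


def write_image(img: VoxelImage, path) -> None:
    """Write a volume as MetaImage (.mhd+.raw), NIfTI or multipage TIFF."""
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".mhd", ".mha")):
        import SimpleITK as sitk

        out = sitk.GetImageFromArray(np.ascontiguousarray(img.data.transpose(2, 1, 0)))
        out.SetSpacing((img.spacing,) * 3)
        out.SetOrigin(tuple(img.origin))
        sitk.WriteImage(out, str(path))
    elif suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag([img.spacing] * 3 + [1.0])
        affine[:3, 3] = img.origin
        nib.save(nib.Nifti1Image(np.asarray(img.data), affine), str(path))
    elif suffixes.endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(str(path), np.ascontiguousarray(img.data.transpose(2, 1, 0)))
    else:
        raise ValueError(f"unknown output format: {path.name}")


# ---------------------------------------------------------------------------
# calibration, cropping, BMC


def attenuation_to_tmd(img: VoxelImage, law: CalibrationLaw) -> VoxelImage:
    """Convert attenuation values to tissue mineral density, voxel-wise."""
    if img.value_kind != "attenuation":
        raise ValueError(
            f"attenuation_to_tmd expects an attenuation image, got {img.value_kind!r}"
        )
    return img.with_data(law(img.data), value_kind="tmd")


def crop_voi(img: VoxelImage, z_lo_frac: float, z_hi_frac: float) -> VoxelImage:
    """Drop a fraction of slices from each longitudinal end.

    Mirrors excluding the resin-embedded extremities (10% of the length per
    end in the reference protocol).  ``floor(frac * nz)`` slices are removed
    from each end; the origin is shifted so retained voxels keep their
    physical coordinates.
    """
    if not (0 <= z_lo_frac < 1 and 0 <= z_hi_frac < 1 and z_lo_frac + z_hi_frac < 1):
        raise ValueError(
            f"invalid crop fractions ({z_lo_frac}, {z_hi_frac}): "
            "each must be in [0, 1) and sum to < 1"
        )
    nz = img.shape[2]
    lo = int(np.floor(z_lo_frac * nz))
    hi = int(np.floor(z_hi_frac * nz))
    if nz - lo - hi < 1:
        raise ValueError("crop fractions leave no slices")
    data = img.data[:, :, lo: nz - hi]
    origin = img.origin.copy()
    origin[2] += lo * img.spacing
    return VoxelImage(data, img.spacing, origin, img.value_kind)


def compute_bmc(tmd_img: VoxelImage, mask: VoxelImage) -> BMCReport:
    """Total BMC = Σ_bone TMD · voxel volume.

    TMD is mgHA/cc = mg/cm³, spacing is mm, so the voxel volume enters in
    cm³: ``(spacing/10)³``.
    """
    if tmd_img.value_kind != "tmd":
        raise ValueError(f"expected a TMD image, got {tmd_img.value_kind!r}")
    if mask.value_kind != "mask":
        raise ValueError(f"expected a mask image, got {mask.value_kind!r}")
    if tmd_img.shape != mask.shape:
        raise ValueError(f"shape mismatch: {tmd_img.shape} vs {mask.shape}")
    if abs(tmd_img.spacing - mask.spacing) > _ANISO_RTOL * tmd_img.spacing:
        raise ValueError("TMD image and mask have different spacings")

    sel = mask.data.astype(bool)
    n = int(sel.sum())
    if n == 0:
        return BMCReport(total_bmc=0.0, n_bone_voxels=0, mean_tmd=0.0)
    voxel_volume_cm3 = (tmd_img.spacing / 10.0) ** 3
    tmd_vals = tmd_img.data[sel].astype(float)
    return BMCReport(
        total_bmc=float(tmd_vals.sum() * voxel_volume_cm3),
        n_bone_voxels=n,
        mean_tmd=float(tmd_vals.mean()),
    )
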