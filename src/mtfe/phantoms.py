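"""Synthetic microCT phantoms with exact ground truth.

A phantom stands in for an in vivo scan of a long-bone diaphysis: a hollow
mineralized tube (or a solid rectangular prism) of known geometry and TMD
field, mapped to grey levels with a linear law, plus optional Gaussian
noise.  Voxelization is by voxel-*center* membership with no anti-aliasing,
so the returned mask is an unambiguous oracle for the segmentation chain.

The analytic axial stiffness S = E·A/L of the same geometries serves as the
bar-theory oracle for the solver (exact for ν = 0 prisms, asymptotic for
voxelized tubes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .image_io import VoxelImage

__all__ = ["PhantomSpec", "make_phantom", "analytic_axial_stiffness"]


@dataclass
class PhantomSpec:
    """Geometry, TMD field and imaging parameters of a synthetic scan.

    Attributes
    ----------
    shape : {"tube", "prism"}
        Hollow circular cylinder or solid rectangular prism.
    outer_size : float
        Tube: outer *diameter* (mm).  Prism: cross-section edge (mm).
    inner_size : float
        Tube: inner diameter (mm); 0 gives a solid cylinder.  Ignored for
        prisms.
    length : float
        Longitudinal extent (mm).
    spacing : float
        Voxel edge (mm); default 0.0104 mm as in the in vivo protocol.
    tmd : float or (float, float)
        Constant TMD (mgHA/cc), or (inner, outer) values of a radial linear
        gradient across the wall.
    background_grey, bone_grey_per_tmd : float
        Grey-level mapping: grey = background + bone_grey_per_tmd · TMD
        inside bone, background outside.
    noise_sd : float
        Additive Gaussian noise, grey levels.
    margin : int
        Air voxels padded around the shape on x/y (ends are flush so the
        loading surfaces are at the volume faces).
    seed : int
        Noise seed; same seed → identical image.
    """

    shape: str = "tube"
    outer_size: float = 0.4
    inner_size: float = 0.28
    length: float = 1.2
    spacing: float = 0.0104
    tmd: float | tuple = 1100.0
    background_grey: float = 50.0
    bone_grey_per_tmd: float = 0.2
    noise_sd: float = 0.0
    margin: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.shape not in ("tube", "prism"):
            raise ValueError(f"unknown phantom shape {self.shape!r}")
        if self.shape == "tube" and not self.inner_size < self.outer_size:
            raise ValueError("tube needs inner_size < outer_size")
        if self.length < 2 * self.spacing:
            raise ValueError("length must cover at least two voxels")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def bone_grey_mode(self) -> float:
        """Grey level of bone at the (mean) TMD — the histogram bone peak."""
        t = self.tmd
        tmid = 0.5 * (t[0] + t[1]) if isinstance(t, (tuple, list)) else t
        return self.background_grey + self.bone_grey_per_tmd * tmid


def make_phantom(spec: PhantomSpec):
    """Build (grey image, ground-truth mask, ground-truth TMD image).

    A voxel is bone iff its center lies inside the shape.  Grey level is
    ``background + bone_grey_per_tmd·TMD + N(0, noise_sd)`` with seeded,
    reproducible noise; the mask and TMD ground truth are noise-free.
    """
    h = spec.spacing
    nz = int(round(spec.length / h))
    if spec.shape == "tube":
        half = spec.outer_size / 2.0
        nxy = int(math.ceil(spec.outer_size / h)) + 2 * spec.margin
    else:
        half = spec.outer_size / 2.0
        nxy = int(math.ceil(spec.outer_size / h)) + 2 * spec.margin
    if nz < 2 or nxy < 1:
        raise ValueError("degenerate phantom geometry")

    # voxel centers, with the shape centered in x/y
    cx = nxy * h / 2.0
    xs = (np.arange(nxy) + 0.5) * h - cx
    X, Y = np.meshgrid(xs, xs, indexing="ij")

    if spec.shape == "tube":
        r = np.hypot(X, Y)
        r_o = spec.outer_size / 2.0
        r_i = spec.inner_size / 2.0
        inside2d = (r <= r_o) & (r >= r_i)
        # radial coordinate normalized across the wall, for TMD gradients
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.clip((r - r_i) / max(r_o - r_i, 1e-300), 0.0, 1.0)
    else:
        inside2d = (np.abs(X) <= half) & (np.abs(Y) <= half)
        frac = np.zeros_like(X)

    if isinstance(spec.tmd, (tuple, list)):
        t_in, t_out = spec.tmd
        tmd2d = t_in + (t_out - t_in) * frac
    else:
        tmd2d = np.full_like(X, float(spec.tmd))

    mask = np.repeat(inside2d[:, :, None], nz, axis=2).astype(np.uint8)
    tmd = np.where(inside2d, tmd2d, 0.0)[:, :, None] * np.ones(nz)[None, None, :]
    if mask.sum() == 0:
        raise ValueError("degenerate phantom geometry: no bone voxels")

    grey = spec.background_grey + spec.bone_grey_per_tmd * tmd * mask
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        grey = grey + rng.normal(0.0, spec.noise_sd, size=grey.shape)

    grey_img = VoxelImage(grey, h, value_kind="grey")
    mask_img = VoxelImage(mask, h, value_kind="mask")
    tmd_img = VoxelImage(tmd, h, value_kind="tmd")
    return grey_img, mask_img, tmd_img


def analytic_axial_stiffness(E, outer, inner, length, shape="tube"):
    """Bar-theory axial stiffness S = E·A/L in N/mm.

    ``E`` in MPa (= N/mm²), dimensions in mm.  Tube cross-section
    A = π(r_o² − r_i²); prism A = outer².  Exact for a ν = 0 prism whose
    voxelization is loss-free; a voxelized tube converges to this value as
    spacing → 0.
    """
    if min(E, outer, length) <= 0:
        raise ValueError("dimensions and modulus must be positive")
    if shape == "tube":
        r_o, r_i = outer / 2.0, inner / 2.0
        area = math.pi * (r_o ** 2 - r_i ** 2)
    elif shape == "prism":
        area = outer * outer
    else:
        raise ValueError(f"unknown shape {shape!r}")
    return E * area / length
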