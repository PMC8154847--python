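"""Tissue mineral density → Young's modulus mapping and the three material
assignment schemes used for whole-bone micro-FE:

* ``homo`` — one literature modulus for every element (default 14.8 GPa),
* ``homoTMD`` — one specimen-specific modulus from the specimen's mean TMD,
* ``hete`` — per-element moduli from a TMD→E law discretized into equal
  TMD bins (default 450 over 500–1800 mgHA/cc).

With the default endpoints (500 mgHA/cc ↔ 9 GPa, 1800 mgHA/cc ↔ 23 GPa) the
law is E[MPa] = 10.7692·TMD[mgHA/cc] + 3615.4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import VoxelImage

__all__ = [
    "ModulusLaw",
    "ElasticMaterial",
    "MaterialAssignment",
    "law_from_endpoints",
    "tmd_to_modulus",
    "assign_homogeneous",
    "assign_homo_tmd",
    "assign_heterogeneous",
    "DEFAULT_LAW",
    "DEFAULT_HOMOGENEOUS",
]


@dataclass(frozen=True)
class ModulusLaw:
    """Linear TMD→E calibration, evaluated after clamping TMD to
    [tmd_min, tmd_max]."""

    slope: float  # MPa per mgHA/cc
    intercept: float  # MPa
    tmd_min: float  # mgHA/cc
    tmd_max: float  # mgHA/cc

    def __post_init__(self):
        if not self.tmd_min < self.tmd_max:
            raise ValueError("need tmd_min < tmd_max")
        if self.slope * self.tmd_min + self.intercept <= 0:
            raise ValueError("law yields non-positive modulus at tmd_min")

    def __call__(self, tmd):
        t = np.clip(np.asarray(tmd, dtype=float), self.tmd_min, self.tmd_max)
        return self.slope * t + self.intercept


@dataclass(frozen=True)
class ElasticMaterial:
    """Isotropic linear-elastic material (E in MPa)."""

    E: float
    nu: float = 0.3

    def __post_init__(self):
        if not self.E > 0:
            raise ValueError("Young's modulus must be positive")
        if not -1.0 < self.nu < 0.5:
            raise ValueError("Poisson's ratio must lie in (-1, 0.5)")


@dataclass
class MaterialAssignment:
    """Per-element Young's moduli plus the shared Poisson's ratio."""

    element_E: np.ndarray  # (M,) MPa
    nu: float
    scheme: str  # {"homo", "homoTMD", "hete"}

    def __post_init__(self):
        self.element_E = np.asarray(self.element_E, dtype=float)
        if np.any(self.element_E <= 0):
            raise ValueError("all element moduli must be positive")
        if self.scheme in ("homo", "homoTMD") and self.n_materials != 1:
            raise ValueError(f"scheme {self.scheme!r} must have one material")

    @property
    def n_materials(self) -> int:
        return len(np.unique(self.element_E))


#: TMD→E law anchored at nanoindentation endpoints 9 GPa @ 500 mgHA/cc and
#: 23 GPa @ 1800 mgHA/cc (slope 10.7692 MPa/(mgHA/cc), intercept 3615.4 MPa)
def law_from_endpoints(tmd_min, E_min, tmd_max, E_max) -> ModulusLaw:
    """Build the linear law through (tmd_min, E_min) and (tmd_max, E_max)."""
    if not tmd_min < tmd_max:
        raise ValueError("need tmd_min < tmd_max")
    slope = (E_max - E_min) / (tmd_max - tmd_min)
    intercept = E_min - slope * tmd_min
    return ModulusLaw(slope=slope, intercept=intercept, tmd_min=tmd_min, tmd_max=tmd_max)


DEFAULT_LAW = law_from_endpoints(500.0, 9000.0, 1800.0, 23000.0)
DEFAULT_HOMOGENEOUS = ElasticMaterial(E=14800.0, nu=0.3)


def tmd_to_modulus(tmd, law: ModulusLaw = DEFAULT_LAW):
    """E = slope·clamp(TMD) + intercept, in MPa."""
    return law(tmd)


def assign_homogeneous(mesh, material: ElasticMaterial) -> MaterialAssignment:
    """Every element gets the same modulus (scheme ``homo``)."""
    return MaterialAssignment(
        element_E=np.full(mesh.n_elements, float(material.E)),
        nu=material.nu,
        scheme="homo",
    )


def assign_homo_tmd(
    mesh, tmd_img: VoxelImage, mask: VoxelImage,
    law: ModulusLaw = DEFAULT_LAW, nu: float = 0.3,
) -> MaterialAssignment:
    """One specimen-specific modulus from the mean TMD over bone voxels
    (scheme ``homoTMD``)."""
    sel = mask.data.astype(bool)
    if not sel.any():
        raise ValueError("empty mask: no voxels to average TMD over")
    E_spec = float(law(float(tmd_img.data[sel].mean())))
    return MaterialAssignment(
        element_E=np.full(mesh.n_elements, E_spec), nu=nu, scheme="homoTMD"
    )


def _bin_tmd(tmd, law: ModulusLaw, n_bins: int):
    """Clamp TMD into the law's range, bin into n_bins equal intervals and
    return the bin-center TMD (the representative value)."""
    t = np.clip(np.asarray(tmd, dtype=float), law.tmd_min, law.tmd_max)
    width = (law.tmd_max - law.tmd_min) / n_bins
    idx = np.minimum(((t - law.tmd_min) / width).astype(int), n_bins - 1)
    return law.tmd_min + (idx + 0.5) * width


def assign_heterogeneous(
    mesh, tmd_img: VoxelImage, mask: VoxelImage = None,
    law: ModulusLaw = DEFAULT_LAW, n_bins: int = 450, nu: float = 0.3,
) -> MaterialAssignment:
    """Per-element moduli from the TMD field (scheme ``hete``).

    Hex elements take the TMD of their source voxel; tet elements take the
    mean TMD of masked voxels whose centers fall inside the element, with a
    nearest-voxel fallback.  TMD is clamped into the law's range, binned
    into ``n_bins`` equal intervals, and E = law(bin center), so at most
    ``n_bins`` distinct materials are produced (≈450 for a tibia at the
    default binning).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    from .meshing import HexMesh, TetMesh

    if isinstance(mesh, HexMesh):
        if mesh.voxel_index_of_element is None:
            raise ValueError("hex mesh lacks voxel provenance")
        vi = mesh.voxel_index_of_element
        tmd_e = tmd_img.data[vi[:, 0], vi[:, 1], vi[:, 2]].astype(float)
    elif isinstance(mesh, TetMesh):
        if mesh.voxel_index_of_element is not None:
            # voxel-derived tets inherit their source voxel's TMD
            vi = mesh.voxel_index_of_element
            tmd_e = tmd_img.data[vi[:, 0], vi[:, 1], vi[:, 2]].astype(float)
        else:
            tmd_e = _tet_element_tmd(mesh, tmd_img, mask)
    else:
        raise TypeError(f"unsupported mesh type {type(mesh).__name__}")

    rep = _bin_tmd(tmd_e, law, n_bins)
    return MaterialAssignment(element_E=law(rep), nu=nu, scheme="hete")


def _tet_element_tmd(mesh, tmd_img: VoxelImage, mask: VoxelImage):
    """Mean TMD of masked voxel centers inside each tet (corner tetrahedron
    of the TET10), nearest masked voxel as fallback."""
    from scipy.spatial import cKDTree

    if mask is None:
        raise ValueError("tet TMD sampling needs the bone mask")
    sel = np.argwhere(mask.data.astype(bool))
    if len(sel) == 0:
        raise ValueError("empty mask")
    h = tmd_img.spacing
    centers = (sel + 0.5) * h + tmd_img.origin
    tmd_vals = tmd_img.data[sel[:, 0], sel[:, 1], sel[:, 2]].astype(float)
    tree = cKDTree(centers)

    p = mesh.nodes[mesh.elements[:, :4]]  # (M, 4, 3)
    tmd_e = np.empty(mesh.n_elements)
    for e in range(mesh.n_elements):
        a, b, c, d = p[e]
        # candidate voxels within the tet's bounding box
        lo = p[e].min(axis=0)
        hi = p[e].max(axis=0)
        rad = 0.5 * float(np.linalg.norm(hi - lo)) + h
        cand = tree.query_ball_point(0.5 * (lo + hi), rad)
        inside_vals = []
        if cand:
            T = np.column_stack([b - a, c - a, d - a])
            try:
                lam = np.linalg.solve(T, (centers[cand] - a).T).T
                ok = (lam >= -1e-12).all(axis=1) & (lam.sum(axis=1) <= 1 + 1e-12)
                inside_vals = tmd_vals[np.asarray(cand)[ok]]
            except np.linalg.LinAlgError:
                inside_vals = []
        if len(inside_vals):
            tmd_e[e] = float(np.mean(inside_vals))
        else:
            centroid = p[e].mean(axis=0)
            dist, j = tree.query(centroid)
            if dist > 2 * h:
                raise ValueError(
                    f"tet element {e} contains no voxels and has no masked "
                    f"voxel within 2 spacings (nearest at {dist:.3g} mm)"
                )
            tmd_e[e] = float(tmd_vals[j])
    return tmd_e
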